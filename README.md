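# periflow

Quantitative analysis of coronary capillary **no-reflow** — the failure of
capillary-level perfusion after an occluded upstream coronary artery is
re-opened.  After cardiac ischaemia and reperfusion, a large fraction of
capillaries remain blocked, and the blockages cluster near the somata of
contractile pericytes that constrict the vessel lumen.  `periflow`
implements the quantitative machinery needed to establish that claim from
vessel-level imaging data, together with a seeded synthetic-data generator
that emulates the measured structure of such a study.

The package is aimed at microvascular physiologists and image analysts who
have reduced confocal data to vessel-graph form (capillary polylines with
pericyte-soma and blockage annotations, lumen intensity profiles, regional
perfusion intensities) and want reproducible, tested statistics on top.

## What it computes

**Random-placement null model.**  For a blocked capillary of imaged length
*L*, if the blockage position were independent of pericyte locations it
would be uniform over the capillary's arc length.  The distance *x* to the
nearest visible pericyte soma then has an exactly computable distribution:
for a single soma a distance *A* from one end,

    p(x) dx = 2 dx / L   for x < A,
    p(x) dx =   dx / L   for A < x < L − A,
    p(x) dx = 0          beyond,

and in general the nearest-soma distance is piecewise affine with slope ±1
along the vessel, so each affine stretch of length ℓ contributes mass ℓ/L
uniformly over the distance range it sweeps.  `image_null_cdf` computes the
resulting piecewise-linear CDF exactly (branching vessels and truncation at
the image border included), `pool_cdfs` averages it over images, and
`equiprobability_sample` reduces the pooled CDF to *n* quantiles at
cumulative probabilities (i − ½)/n for comparison with an observed
*n*-point distribution.  The idealized limit — somata evenly spaced 60 μm
apart on an unbranched vessel — is a CDF rising linearly to 1 at 30 μm
(`linear_null`).

**Blockage analysis.**  `detect_block` localizes abrupt tracer
terminations on background-subtracted, plateau-normalized lumen intensity
profiles; `observed_distances` builds the empirical
blockage-to-nearest-soma distance distribution over a set of annotated
images; `compare_to_null` tests it against the pooled null with one- and
two-sample Kolmogorov–Smirnov statistics.

**Perfusion and diameters.**  `normalize_rois` / `risk_zone_deficit`
quantify perfused blood volume in 12 regions of interest around the left
ventricle (risk zone = ROIs 7–10), `blocked_fraction` summarizes transect
counts of filled vs unfilled capillaries, and `diameter_ratio_analysis`
compares the lumen diameter at pericyte somata with the diameter 10 μm
upstream (ratio r = d_soma / d_upstream).

**Statistics.**  `auto_compare` applies a Shapiro–Wilk normality gate, an
F-test variance gate and the resulting Student/Welch t or Mann–Whitney
test; `holm_correct` applies a sequential Bonferroni correction (smallest
of N p-values × N, next × N−1, …, clamped at 1); `min_sample_size`
inverts the noncentral-t power function of the two-sample t-test.

**Synthetic data.**  `StudyConfig` + `generate_bed` / `assign_condition` /
`generate_ventricle_map` / `generate_study` produce seeded datasets whose
population parameters are the study's printed values: 3% / 40% / 30% of
capillaries blocked under sham / ischaemia / ischaemia + adenosine, a 49%
risk-zone perfusion deficit with a 57% adenosine rescue, diameter ratios
1.058 (sham) and 0.822 (ischaemia), a 37% soma-site diameter reduction
with a 21% adenosine recovery, and blockage offsets with a 3.6 μm median.

## Worked example

```sh
periflow generate --out ds --seed 11
periflow analyse ds --out report
```

then, in Python:

```python
>>> import json
>>> s = json.load(open("report/summary.json"))
>>> {c: round(v["mean_pct"], 1)
...  for c, v in s["blocked_fraction"]["per_condition"].items()}
{'ischaemia': 39.7, 'ischaemia_adenosine': 30.8, 'sham': 2.1}
>>> round(s["perfusion"]["contrasts"]["ischaemia_vs_sham_deficit_pct"], 1)
50.1
>>> round(s["diameters"]["per_condition"]["ischaemia"]["ratio_mean"], 3)
0.832
>>> round(s["blockage_distances"]["ischaemia"]["observed_median"], 2)
4.02
>>> s["blockage_distances"]["ischaemia"]["p_one_sample"] < 1e-6
True
```

Reading: with the default (ischaemia-like) blockage model, ~40% of
capillaries crossing the central transect are blocked versus ~2% in sham;
risk-zone perfusion is down by ~50% relative to sham; the soma/upstream
diameter ratio is well below 1 after ischaemia; and the observed
blockage-to-soma distances (median ≈ 4 μm) are grossly incompatible with
random placement along the blocked capillaries (one-sample KS against the
pooled exact null).

All randomness flows from the single `--seed`; `periflow replay
ds/manifest.json --out ds2` regenerates the dataset byte-identically.

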