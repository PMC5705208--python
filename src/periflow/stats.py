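"""Gated test selection, multiple-comparison correction and power analysis.

The protocol mirrors common physiology practice: normality of each group
is assessed with Shapiro-Wilk; if both groups pass, equality of variances
is assessed with a two-sided F test and a Student or heteroscedastic
(Welch) t-test is used accordingly; if either group fails normality the
comparison falls back to a Mann-Whitney U test.  All tests are two-tailed.
Multiple comparisons within a reported family are corrected with a
sequential Bonferroni rule: the most significant of N p-values is
multiplied by N, the second most significant by N-1, and so on, with the
products clamped to 1.

Distributional routines (Shapiro-Wilk, the noncentral-t power function,
Kolmogorov-Smirnov p-values) are delegated to scipy; the selection
protocol, the correction rule and the minimal-sample-size search are
implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .null_model import DistanceCDF

__all__ = [
    "TestResult",
    "auto_compare",
    "one_sample_compare",
    "holm_correct",
    "ks_compare",
    "min_sample_size",
    "two_sample_t_power",
]


@dataclass
class TestResult:
    """A single hypothesis-test outcome with its selection trace."""

    test_name: str
    statistic: float
    p_raw: float
    p_corrected: float | None = None
    n_per_group: tuple[int, ...] = ()
    trace: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_raw": self.p_raw,
            "p_corrected": self.p_corrected,
            "n_per_group": list(self.n_per_group),
            "trace": list(self.trace),
        }


def _shapiro_gate(x: np.ndarray, label: str, alpha: float,
                  trace: list[str]) -> bool:
    """True when the sample is consistent with normality at the gate level.

    Samples with (near-)zero spread cannot be assessed and are treated as
    non-normal so that the comparison falls through to a rank test.
    """
    if np.ptp(x) < 1e-12 * max(1.0, abs(np.mean(x))):
        trace.append(f"shapiro[{label}]: degenerate (no spread) -> non-normal")
        return False
    p = float(sps.shapiro(x).pvalue)
    ok = p >= alpha
    trace.append(f"shapiro[{label}]: p={p:.4g} -> {'normal' if ok else 'non-normal'}")
    return ok


def auto_compare(group_a, group_b, alpha_gate: float = 0.05) -> TestResult:
    """Two-group comparison with normality- and variance-gated test choice.

    Shapiro-Wilk at ``p >= alpha_gate`` in *both* groups selects a t-test,
    whose flavour (Student vs Welch) is chosen by a two-sided F test on the
    variance ratio at the same gate; any normality failure selects
    Mann-Whitney.  Both groups need at least 3 observations.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("insufficient n for normality gate (need >= 3 per group)")
    trace: list[str] = []
    normal = _shapiro_gate(a, "a", alpha_gate, trace)
    normal &= _shapiro_gate(b, "b", alpha_gate, trace)
    if normal:
        va, vb = a.var(ddof=1), b.var(ddof=1)
        F = va / vb
        dfa, dfb = a.size - 1, b.size - 1
        p_f = 2.0 * min(sps.f.cdf(F, dfa, dfb), sps.f.sf(F, dfa, dfb))
        p_f = min(1.0, p_f)
        equal_var = p_f >= alpha_gate
        trace.append(f"f_test: F={F:.4g} p={p_f:.4g} -> "
                     f"{'equal' if equal_var else 'unequal'} variance")
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        name = "student_t" if equal_var else "welch_t"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney"
    trace.append(f"selected: {name}")
    return TestResult(name, float(res.statistic), float(res.pvalue),
                      n_per_group=(a.size, b.size), trace=trace)


def one_sample_compare(values, popmean: float = 1.0,
                       alpha_gate: float = 0.05) -> TestResult:
    """One-group comparison against a reference value (e.g. a ratio vs 1).

    Shapiro-Wilk gates between a one-sample t-test and a Wilcoxon
    signed-rank test.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("insufficient n for normality gate (need >= 3)")
    trace: list[str] = []
    diffs = x - popmean
    if _shapiro_gate(x, "x", alpha_gate, trace):
        res = sps.ttest_1samp(x, popmean)
        name = "one_sample_t"
    elif np.abs(diffs).max() < 1e-12 * max(1.0, abs(popmean)):
        # every observation sits exactly at the reference value
        trace.append("wilcoxon: all differences zero -> no evidence")
        trace.append("selected: wilcoxon")
        return TestResult("wilcoxon", 0.0, 1.0, n_per_group=(x.size,),
                          trace=trace)
    else:
        res = sps.wilcoxon(diffs)
        name = "wilcoxon"
    trace.append(f"selected: {name}")
    return TestResult(name, float(res.statistic), float(res.pvalue),
                      n_per_group=(x.size,), trace=trace)


def holm_correct(p_values, enforce_monotonic: bool = False) -> np.ndarray:
    """Sequential Bonferroni correction, order-preserving.

    The smallest of N p-values is multiplied by N, the next smallest by
    N - 1, ..., the largest by 1; products are clamped to 1.  With
    ``enforce_monotonic`` the corrected values are additionally made
    non-decreasing along the sorted order (the step-down refinement); the
    literal multiply-and-clamp rule is the default.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("invalid p: values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    mult = np.arange(n, 0, -1, dtype=float)
    corrected_sorted = p[order] * mult
    if enforce_monotonic:
        corrected_sorted = np.maximum.accumulate(corrected_sorted)
    corrected_sorted = np.minimum(corrected_sorted, 1.0)
    out = np.empty(n)
    out[order] = corrected_sorted
    return out


def ks_compare(sample_a, b) -> TestResult:
    """Kolmogorov-Smirnov comparison of cumulative distributions.

    ``b`` may be a second sample (two-sample KS) or a
    :class:`~periflow.null_model.DistanceCDF` (one-sample KS against the
    continuous CDF).  Two-sided p-values.
    """
    a = np.asarray(sample_a, dtype=float)
    if a.size == 0:
        raise ValueError("empty sample")
    trace: list[str] = []
    if isinstance(b, DistanceCDF):
        res = sps.kstest(a, b)
        trace.append("one-sample KS against continuous CDF")
        n = (a.size,)
    else:
        b_arr = np.asarray(b, dtype=float)
        if b_arr.size == 0:
            raise ValueError("empty sample")
        res = sps.ks_2samp(a, b_arr)
        trace.append("two-sample KS")
        n = (a.size, b_arr.size)
    return TestResult("ks", float(res.statistic), float(res.pvalue),
                      n_per_group=n, trace=trace)


def two_sample_t_power(n: int, delta: float, sd: float,
                       alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t-test with ``n`` per group,
    true mean difference ``delta`` and common standard deviation ``sd``,
    via the noncentral-t distribution."""
    if n < 2:
        return 0.0
    df = 2 * n - 2
    nc = (delta / sd) * np.sqrt(n / 2.0)
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(t_crit, df, nc) + sps.nct.cdf(-t_crit, df, nc))


def min_sample_size(delta: float, sd: float, alpha: float = 0.05,
                    power: float = 0.8, n_max: int = 1_000_000) -> int:
    """Smallest per-group n giving the target power for a two-sided
    two-sample t-test (equal n, equal sd).

    The floor is n = 2 per group (the smallest n with positive degrees of
    freedom).  Raises if the target is unreachable within ``n_max``.
    """
    if delta <= 0 or sd <= 0:
        raise ValueError("delta and sd must be positive")
    if not (0 < power < 1):
        raise ValueError("power must lie in (0, 1)")
    n = 2
    while n <= n_max:
        if two_sample_t_power(n, delta, sd, alpha) >= power:
            return n
        n += 1
    raise ValueError("target power unreachable within n_max")
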