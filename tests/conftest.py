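import logging

import numpy as np
import pytest

from periflow.geometry import CapillaryGraph, PointOnVessel, Soma
from periflow.synthetic_data import StudyConfig

# the expected no-reachable-soma warnings from mass simulations would
# otherwise drown test output
logging.getLogger("periflow.blockage_analysis").setLevel(logging.ERROR)
logging.getLogger("periflow.null_model").setLevel(logging.ERROR)


@pytest.fixture
def straight_capillary():
    """One unbranched 60 μm capillary along x with a soma at arc 10."""
    return CapillaryGraph(
        segments=[np.array([[0.0, 0.0], [60.0, 0.0]])],
        capillary_ids={0: "c"},
        somata=[Soma(0, 10.0)],
    )


@pytest.fixture
def y_graph():
    """Three 10 μm branches meeting at one node (a 'Y')."""
    return CapillaryGraph(
        segments=[
            np.array([[0.0, 0.0], [10.0, 0.0]]),
            np.array([[10.0, 0.0], [20.0, 0.0]]),
            np.array([[10.0, 0.0], [10.0, 10.0]]),
        ],
        adjacency=[((0, 1), (1, 0)), ((0, 1), (2, 0))],
        capillary_ids={0: "c", 1: "c", 2: "c"},
    )


@pytest.fixture
def default_config():
    return StudyConfig()


def random_test_graph(rng: np.random.Generator) -> CapillaryGraph:
    """A small random connected network (chain with optional spur) with
    random somata, for property tests.

    All coordinates and arc positions are recorded at 0.01 μm precision,
    the resolution at which annotations of confocal data are stored.
    """
    n_chain = int(rng.integers(1, 4))
    cuts = (np.sort(np.round(rng.uniform(10.0, 90.0, n_chain - 1), 2))
            if n_chain > 1 else np.array([]))
    xs = np.concatenate([[0.0], cuts, [100.0]])
    segments = [np.array([[x0, 0.0], [x1, 0.0]]) for x0, x1 in zip(xs, xs[1:])]
    adjacency = [((i, 1), (i + 1, 0)) for i in range(n_chain - 1)]
    capillary_ids = {i: "c" for i in range(n_chain)}
    if rng.random() < 0.5:  # orthogonal spur from an interior junction
        j = int(rng.integers(0, n_chain))
        x = float(segments[j][1, 0])
        sid = len(segments)
        segments.append(np.array([[x, 0.0],
                                  [x, np.round(rng.uniform(5.0, 30.0), 2)]]))
        adjacency.append(((j, 1), (sid, 0)))
        capillary_ids[sid] = "c"
    somata = []
    n_som = int(rng.integers(1, 5))
    for _ in range(n_som):
        sid = int(rng.integers(0, len(segments)))
        L = np.linalg.norm(np.diff(segments[sid], axis=0), axis=1).sum()
        somata.append(Soma(sid, float(np.round(rng.uniform(0.0, L), 2))))
    return CapillaryGraph(segments=segments, adjacency=adjacency,
                          capillary_ids=capillary_ids, somata=somata)


def random_point(rng: np.random.Generator, graph: CapillaryGraph) -> PointOnVessel:
    sid = int(rng.integers(0, len(graph.segments)))
    return PointOnVessel(sid, float(rng.uniform(0.0, graph.segment_length(sid))))
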