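import numpy as np
import pytest

from amprecon.align import ScoringParams
from amprecon.core import BreakpointGraph, GraphEdge, GraphSegment, LabelMap


@pytest.fixture
def params() -> ScoringParams:
    return ScoringParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_label_map(positions, length=None, map_id="m1") -> LabelMap:
    positions = np.asarray(positions, dtype=float)
    if length is None:
        length = (positions[-1] + 1000.0) if positions.size else 1000.0
    return LabelMap(map_id, float(length), positions)


@pytest.fixture
def toy_graph() -> BreakpointGraph:
    """Three contiguous segments on one chromosome with a cycle-closing edge."""
    segs = [
        GraphSegment(1, "chr1", 1, 100_000, 20),
        GraphSegment(2, "chr1", 100_001, 250_000, 20),
        GraphSegment(3, "chr1", 250_001, 300_000, 20),
    ]
    edges = [
        GraphEdge(1, "right", 2, "left", "concordant", 1),
        GraphEdge(2, "right", 3, "left", "concordant", 1),
        GraphEdge(3, "right", 1, "left", "discordant", 1),
    ]
    return BreakpointGraph(segs, edges)
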