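"""Core domain containers for optical-map-guided amplicon reconstruction.

Optical maps represent a DNA molecule or assembled contig as an ordered list of
label positions (bp) where a nicking/labeling enzyme recognition motif occurs.
Breakpoint graphs encode copy-number (CN) annotated genomic segments and the
oriented junctions (concordant = reference-adjacent, discordant = rearranged)
connecting them. Reconstructions are ordered, oriented walks through the graph
supported by alignments of in-silico-digested segments to optical map contigs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

Side = str  # "left" | "right"
Orientation = str  # "+" | "-"


@dataclass
class LabelMap:
    """Ordered label positions of one optical map (contig, segment or molecule).

    Positions are 1-based bp coordinates, strictly increasing, all within
    (0, length_bp]. A map with no labels is legal (e.g. an unlabeled viral
    insert) and carries only its length.
    """

    map_id: str
    length_bp: float
    positions: np.ndarray
    channel: int = 1

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.length_bp <= 0:
            raise ValueError(f"map {self.map_id}: non-positive length {self.length_bp}")
        if self.positions.size:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError(f"map {self.map_id}: positions not strictly increasing")
            if self.positions[0] <= 0 or self.positions[-1] > self.length_bp + 0.5:
                raise ValueError(f"map {self.map_id}: positions outside (0, length]")

    @property
    def n_labels(self) -> int:
        return int(self.positions.size)

    def reversed(self) -> "LabelMap":
        """The same map read from the other end (gap sequence reversed)."""
        pos = self.length_bp + 1 - self.positions[::-1] if self.positions.size else self.positions
        return LabelMap(self.map_id, self.length_bp, pos, self.channel)


@dataclass(frozen=True)
class GraphSegment:
    segment_id: int
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    copy_number: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"segment {self.segment_id}: start >= end")
        if self.copy_number < 0:
            raise ValueError(f"segment {self.segment_id}: negative copy number")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GraphEdge:
    """Oriented junction between two segment sides.

    ``side`` is the segment end the junction attaches to: traversing a segment
    in '+' orientation exits at its "right" side and enters at its "left".
    """

    seg_a: int
    side_a: Side
    seg_b: int
    side_b: Side
    edge_type: str  # "concordant" | "discordant"
    multiplicity: float = 1.0

    def key(self) -> frozenset:
        return frozenset([(self.seg_a, self.side_a), (self.seg_b, self.side_b)])


class BreakpointGraph:
    """CN-annotated genomic segments plus the junction edges connecting them."""

    def __init__(self, segments: Iterable[GraphSegment], edges: Iterable[GraphEdge] = ()):
        self.segments: dict[int, GraphSegment] = {s.segment_id: s for s in segments}
        self.edges: list[GraphEdge] = []
        for e in edges:
            self.add_edge(e)

    def add_edge(self, edge: GraphEdge) -> None:
        for sid, side in ((edge.seg_a, edge.side_a), (edge.seg_b, edge.side_b)):
            if sid not in self.segments:
                raise ValueError(f"edge references unknown segment {sid}")
            if side not in ("left", "right"):
                raise ValueError(f"bad segment side {side!r}")
        if edge.edge_type not in ("concordant", "discordant"):
            raise ValueError(f"bad edge type {edge.edge_type!r}")
        self.edges.append(edge)

    def copy_number(self, segment_id: int) -> float:
        return self.segments[segment_id].copy_number

    def adjacency(self) -> dict[tuple[int, Side], list[tuple[int, Side, GraphEdge]]]:
        """Map each (segment, side) node to the sides reachable through one edge."""
        adj: dict[tuple[int, Side], list[tuple[int, Side, GraphEdge]]] = {}
        for e in self.edges:
            adj.setdefault((e.seg_a, e.side_a), []).append((e.seg_b, e.side_b, e))
            if (e.seg_a, e.side_a) != (e.seg_b, e.side_b):
                adj.setdefault((e.seg_b, e.side_b), []).append((e.seg_a, e.side_a, e))
        return adj

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BreakpointGraph):
            return NotImplemented
        return self.segments == other.segments and sorted(
            (e.key(), e.edge_type, e.multiplicity) for e in self.edges
        ) == sorted((e.key(), e.edge_type, e.multiplicity) for e in other.edges)


@dataclass(frozen=True)
class OrientedSegment:
    segment_id: int
    orientation: Orientation

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    def flipped(self) -> "OrientedSegment":
        return OrientedSegment(self.segment_id, "-" if self.orientation == "+" else "+")

    def __str__(self) -> str:
        return f"{self.segment_id}{self.orientation}"


def reverse_path(elements: Sequence[OrientedSegment]) -> tuple[OrientedSegment, ...]:
    """The same walk traversed in the opposite direction."""
    return tuple(e.flipped() for e in reversed(elements))


@dataclass
class ReconstructedPath:
    """Ordered, oriented segment sequence with provenance.

    A cyclic path stores one lap of the cycle; the junction from the last back
    to the first element is implied by ``cyclic``.
    """

    elements: tuple[OrientedSegment, ...]
    cyclic: bool = False
    total_alignment_score: float = 0.0
    supporting_contigs: tuple[str, ...] = ()
    path_id: int = 0
    copy_count: float = 1.0

    def __post_init__(self) -> None:
        self.elements = tuple(self.elements)
        if not self.elements:
            raise ValueError("empty reconstruction path")

    def length_bp(self, graph: BreakpointGraph) -> int:
        return sum(graph.segments[e.segment_id].length for e in self.elements)

    def tokens(self) -> tuple[tuple[int, str], ...]:
        return tuple((e.segment_id, e.orientation) for e in self.elements)


@dataclass
class SegmentAlignment:
    """Scored label-pair correspondence between a digested segment and a contig.

    ``pairs`` holds (contig label index, segment label index) with segment
    indices in the segment's own forward coordinates; after orienting (reverse
    the segment for '-') both coordinates are strictly increasing.
    """

    segment_id: str
    contig_id: str
    orientation: Orientation
    pairs: tuple[tuple[int, int], ...]
    score: float
    mode: str = "semi-global"
    step_scores: tuple[float, ...] = ()
    contig_start_bp: float = 0.0
    contig_end_bp: float = 0.0

    def __post_init__(self) -> None:
        self.pairs = tuple((int(a), int(b)) for a, b in self.pairs)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def contig_label_range(self) -> tuple[int, int]:
        idx = [p[0] for p in self.pairs]
        return min(idx), max(idx)

    @property
    def mean_pair_score(self) -> float:
        return float(np.mean(self.step_scores)) if self.step_scores else 0.0

    @property
    def median_pair_score(self) -> float:
        return float(np.median(self.step_scores)) if self.step_scores else 0.0
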