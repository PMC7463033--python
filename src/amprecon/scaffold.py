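"""Scaffold construction and breakpoint-graph gap imputation.

The significant alignments on one contig form a scaffold: a directed acyclic
graph whose nodes are alignments ordered by contig coordinate. Adjacent
compatible alignments (at most one shared contig label) are joined by allowed
edges; overlapping alignments by forbidden edges. Gaps along a scaffold —
stretches of contig between two anchoring alignments — may hide breakpoint
graph segments too sparsely labeled to align on their own. Imputation
enumerates breakpoint-graph paths between the anchors' graph endpoints under
copy-number and length constraints, converts each candidate to a compound
label map, and keeps the candidate whose fitting alignment to the gap most
improves on the bare junction.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .align import ScoringParams, align
from .core import (
    BreakpointGraph,
    LabelMap,
    OrientedSegment,
    SegmentAlignment,
    Side,
)

MAX_GAP_BP = 400_000          # gaps wider than this are never imputed
DFS_CANDIDATE_CAP = 2 ** 10
BFS_CANDIDATE_CAP = 2 ** 16
MIN_CYCLE_SEGMENT_BP = 100    # segments shorter than this may not form trivial cycles
SLACK_PER_SEGMENT = 10_000
SLACK_CAP = 25_000


@dataclass
class CandidatePath:
    """An oriented interior segment sequence proposed to fill a scaffold gap."""

    elements: tuple[OrientedSegment, ...]
    bp_length: float
    fitting_score: float = float("-inf")

    @property
    def L_p(self) -> int:
        return len(self.elements)


@dataclass
class ScaffoldNode:
    node_id: int
    alignment: SegmentAlignment
    start_label: int      # first contig label index covered
    end_label: int        # last contig label index covered
    weight_bp: float      # path weight contribution (graph segment length)

    @property
    def oriented_segment(self) -> OrientedSegment:
        return OrientedSegment(int(self.alignment.segment_id), self.alignment.orientation)


@dataclass
class ScaffoldEdge:
    src: int
    dst: int
    kind: str             # "allowed" | "forbidden"
    gap_bp: float = 0.0
    gap_labels: int = 0
    imputed: CandidatePath | None = None


@dataclass
class ScaffoldDAG:
    contig_id: str
    nodes: list[ScaffoldNode] = field(default_factory=list)
    edges: list[ScaffoldEdge] = field(default_factory=list)

    def allowed_out(self, node_id: int):
        return [e for e in self.edges if e.src == node_id and e.kind == "allowed"]

    def to_json_dict(self) -> dict:
        return {
            "contig_id": self.contig_id,
            "nodes": [
                {
                    "id": n.node_id,
                    "segment": str(n.oriented_segment),
                    "start_label": n.start_label,
                    "end_label": n.end_label,
                    "score": n.alignment.score,
                }
                for n in self.nodes
            ],
            "edges": [
                {
                    "src": e.src,
                    "dst": e.dst,
                    "kind": e.kind,
                    "gap_bp": e.gap_bp,
                    "imputed": [str(o) for o in e.imputed.elements] if e.imputed else None,
                }
                for e in self.edges
            ],
        }


def build_scaffold(alignments: list[SegmentAlignment], contig: LabelMap,
                   segment_lengths: dict[int, float] | None = None) -> ScaffoldDAG:
    """Order one contig's alignments into a scaffold DAG.

    An allowed edge joins u -> v when v starts at or after u's last covered
    contig label (one or fewer labels of overlap); pairs overlapping by more
    than one label get a forbidden edge.
    """
    recs = []
    for a in alignments:
        lo, hi = a.contig_label_range
        recs.append((lo, hi, a))
    recs.sort(key=lambda r: (r[0], r[1]))
    dag = ScaffoldDAG(contig.map_id)
    for idx, (lo, hi, a) in enumerate(recs):
        if segment_lengths is not None:
            w = segment_lengths.get(int(a.segment_id), contig.positions[hi] - contig.positions[lo])
        else:
            w = contig.positions[hi] - contig.positions[lo]
        dag.nodes.append(ScaffoldNode(idx, a, lo, hi, float(w)))
    for u, v in itertools.combinations(dag.nodes, 2):
        overlap = u.end_label - v.start_label + 1
        if overlap <= 1:
            gap_bp = float(contig.positions[v.start_label] - contig.positions[u.end_label])
            dag.edges.append(
                ScaffoldEdge(u.node_id, v.node_id, "allowed", max(gap_bp, 0.0),
                             max(v.start_label - u.end_label - 1, 0))
            )
        else:
            dag.edges.append(ScaffoldEdge(u.node_id, v.node_id, "forbidden"))
    return dag


def detect_unaligned_regions(contigs: list[LabelMap], scaffolds: list[ScaffoldDAG],
                             min_labels: int = 20, max_labels: int = 500,
                             min_bp: float = 200_000.0, max_bp: float = 5_000_000.0):
    """Maximal unaligned label intervals worth searching against the reference.

    Only contigs carrying at least one graph-segment alignment are examined;
    intervals must satisfy both the label-count and the bp-length bounds.
    """
    by_id = {s.contig_id: s for s in scaffolds}
    out = []
    for contig in contigs:
        scaffold = by_id.get(contig.map_id)
        if scaffold is None or not scaffold.nodes:
            continue
        covered = np.zeros(contig.n_labels, dtype=bool)
        for node in scaffold.nodes:
            covered[node.start_label : node.end_label + 1] = True
        idx = np.flatnonzero(~covered)
        for _key, grp in itertools.groupby(enumerate(idx), key=lambda t: t[1] - t[0]):
            run = [g[1] for g in grp]
            n = len(run)
            span = float(contig.positions[run[-1]] - contig.positions[run[0]])
            if min_labels <= n <= max_labels and min_bp <= span <= max_bp:
                out.append((contig.map_id, (run[0], run[-1])))
    return out


# ---------------------------------------------------------------------------
# breakpoint-graph gap path enumeration


def alignment_exit_node(aln: SegmentAlignment) -> tuple[int, Side]:
    """Graph endpoint where the contig leaves this alignment (rightwards)."""
    sid = int(aln.segment_id)
    return (sid, "right") if aln.orientation == "+" else (sid, "left")


def alignment_entry_node(aln: SegmentAlignment) -> tuple[int, Side]:
    """Graph endpoint where the contig enters this alignment (from the left)."""
    sid = int(aln.segment_id)
    return (sid, "left") if aln.orientation == "+" else (sid, "right")


def _slack(L_p: int) -> float:
    return min(SLACK_CAP, SLACK_PER_SEGMENT * L_p)


class _CandidateCapExceeded(Exception):
    pass


def enumerate_gap_paths(graph: BreakpointGraph, source: tuple[int, Side],
                        dest: tuple[int, Side], expected_gap_bp: float,
                        multiplicity_budget: dict[int, int] | None = None) -> list[CandidatePath]:
    """All breakpoint-graph paths from source to dest that could fill the gap.

    Constraints: per-segment multiplicity within the path bounded by the graph
    copy number; completed paths no more than min(25000, 10000·L_p) shorter or
    longer than the expected gap; growth stops at the same upper bound; at most
    2^10 candidates by DFS, retried as BFS with a 2^16 cap; no trivial cycles
    through segments shorter than 100 bp. An empty list means no imputation.
    """
    adj = graph.adjacency()
    budget = {
        sid: (multiplicity_budget.get(sid, int(s.copy_number)) if multiplicity_budget
              else max(int(round(s.copy_number)), 0))
        for sid, s in graph.segments.items()
    }

    def other(side: Side) -> Side:
        return "left" if side == "right" else "right"

    def complete_ok(bp: float, L_p: int) -> bool:
        return abs(bp - expected_gap_bp) <= _slack(L_p)

    def dfs() -> list[CandidatePath]:
        found: list[CandidatePath] = []
        counts: dict[int, int] = {}
        expansions = [0]

        def recurse(node: tuple[int, Side], elements: list[OrientedSegment], bp: float) -> None:
            expansions[0] += 1
            if expansions[0] > 200_000:
                raise _CandidateCapExceeded
            for seg_b, side_b, _edge in adj.get(node, []):
                if (seg_b, side_b) == dest:
                    if complete_ok(bp, len(elements)):
                        found.append(CandidatePath(tuple(elements), bp))
                        if len(found) > DFS_CANDIDATE_CAP:
                            raise _CandidateCapExceeded
                seg = graph.segments[seg_b]
                if counts.get(seg_b, 0) + 1 > budget.get(seg_b, 0):
                    continue
                if seg.length < MIN_CYCLE_SEGMENT_BP and elements and elements[-1].segment_id == seg_b:
                    continue
                new_bp = bp + seg.length
                if new_bp > expected_gap_bp + _slack(len(elements) + 1):
                    continue
                counts[seg_b] = counts.get(seg_b, 0) + 1
                elements.append(OrientedSegment(seg_b, "+" if side_b == "left" else "-"))
                recurse((seg_b, other(side_b)), elements, new_bp)
                elements.pop()
                counts[seg_b] -= 1

        recurse(source, [], 0.0)
        return found

    def bfs() -> list[CandidatePath]:
        found: list[CandidatePath] = []
        queue: deque[tuple[tuple[int, Side], tuple[OrientedSegment, ...], float, dict[int, int]]]
        queue = deque([(source, (), 0.0, {})])
        expansions = 0
        while queue:
            expansions += 1
            if expansions > 500_000:
                return []  # both searches exceeded their caps: leave unimputed
            node, elements, bp, counts = queue.popleft()
            for seg_b, side_b, _edge in adj.get(node, []):
                if (seg_b, side_b) == dest and complete_ok(bp, len(elements)):
                    found.append(CandidatePath(elements, bp))
                    if len(found) > BFS_CANDIDATE_CAP:
                        return []
                seg = graph.segments[seg_b]
                if counts.get(seg_b, 0) + 1 > budget.get(seg_b, 0):
                    continue
                if seg.length < MIN_CYCLE_SEGMENT_BP and elements and elements[-1].segment_id == seg_b:
                    continue
                new_bp = bp + seg.length
                if new_bp > expected_gap_bp + _slack(len(elements) + 1):
                    continue
                nc = dict(counts)
                nc[seg_b] = nc.get(seg_b, 0) + 1
                queue.append(
                    ((seg_b, other(side_b)),
                     elements + (OrientedSegment(seg_b, "+" if side_b == "left" else "-"),),
                     new_bp, nc)
                )
        return found

    try:
        return dfs()
    except _CandidateCapExceeded:
        return bfs()


# ---------------------------------------------------------------------------
# candidate scoring


def _oriented_label_positions(lmap: LabelMap, orientation: str) -> np.ndarray:
    m = lmap if orientation == "+" else lmap.reversed()
    return m.positions


def build_compound_map(candidate: CandidatePath, source_aln: SegmentAlignment,
                       dest_aln: SegmentAlignment,
                       segment_maps: dict[int, LabelMap]) -> LabelMap:
    """Concatenate candidate segment digests between the two anchor labels.

    The compound map starts at the last aligned label of the source alignment
    and ends at the first aligned label of the destination alignment; interior
    segments are concatenated end-to-start with no inserted gap (breakpoint
    edges are direct adjacencies).
    """
    src_map = segment_maps[int(source_aln.segment_id)]
    dst_map = segment_maps[int(dest_aln.segment_id)]
    src_fidx = [q for _j, q in source_aln.pairs]
    dst_fidx = [q for _j, q in dest_aln.pairs]
    # anchor positions measured along the contig direction of each segment
    src_pos = _oriented_label_positions(src_map, source_aln.orientation)
    dst_pos = _oriented_label_positions(dst_map, dest_aln.orientation)
    n_src, n_dst = src_map.n_labels, dst_map.n_labels
    src_oriented_idx = max(
        (q if source_aln.orientation == "+" else n_src - 1 - q) for q in src_fidx
    )
    dst_oriented_idx = min(
        (q if dest_aln.orientation == "+" else n_dst - 1 - q) for q in dst_fidx
    )
    tail_s = src_map.length_bp - src_pos[src_oriented_idx]
    head_d = dst_pos[dst_oriented_idx]

    positions = [1.0]
    cum = tail_s + 1.0
    for elem in candidate.elements:
        seg_map = segment_maps[elem.segment_id]
        pos = _oriented_label_positions(seg_map, elem.orientation)
        positions.extend(cum + pos)
        cum += seg_map.length_bp
    positions.append(cum + head_d)
    length = cum + head_d + 1.0
    uniq = []
    for p in sorted(positions):
        if not uniq or p - uniq[-1] > 1e-6:
            uniq.append(p)
    return LabelMap("compound", float(length), np.asarray(uniq))


def gap_window(contig: LabelMap, source_aln: SegmentAlignment,
               dest_aln: SegmentAlignment) -> LabelMap | None:
    """The contig interval between the two anchoring alignment labels."""
    j_s = source_aln.contig_label_range[1]
    j_d = dest_aln.contig_label_range[0]
    if j_d <= j_s:
        return None
    pos = contig.positions[j_s : j_d + 1] - contig.positions[j_s] + 1.0
    length = float(pos[-1] + 1.0)
    return LabelMap(f"{contig.map_id}:gap", length, pos)


def score_gap_candidates(candidates: list[CandidatePath], contig: LabelMap,
                         source_aln: SegmentAlignment, dest_aln: SegmentAlignment,
                         segment_maps: dict[int, LabelMap],
                         params: ScoringParams | None = None) -> CandidatePath | None:
    """Pick the candidate whose fitting alignment most improves the junction.

    The baseline is the fitting score of the bare junction (the two anchor
    labels with no interior segments); a candidate is returned only if it
    scores strictly above that baseline.
    """
    params = params or ScoringParams()
    window = gap_window(contig, source_aln, dest_aln)
    if window is None or not candidates:
        return None

    def fit(candidate: CandidatePath) -> float:
        compound = build_compound_map(candidate, source_aln, dest_aln, segment_maps)
        aln = align(compound, window, mode="fitting", params=params)
        return aln.score if aln is not None else float("-inf")

    baseline = fit(CandidatePath((), 0.0))
    best: CandidatePath | None = None
    for cand in candidates:
        score = fit(cand)
        if score > baseline and (best is None or score > best.fitting_score):
            best = CandidatePath(cand.elements, cand.bp_length, score)
    return best
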