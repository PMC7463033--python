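"""Path extraction from scaffolds: heaviest paths, scaffold linking,
copy-number-ratio filtering, subsequence deduplication and cyclic
classification.

Each scaffold DAG contributes its maximum-weight source-to-sink path(s), where
a path's weight is the summed bp length of its aligned graph segments. Paths
from different contigs are linked wherever one path's endpoint sub-path
overlaps another's (the shared graph segment, aligned on both contigs, is the
physical evidence); because contigs are assembled in an arbitrary direction,
reverse-oriented overlaps also count. Linked candidates are then vetted
against the graph's copy numbers, deduplicated (no rotation of a kept path's
sequence may contain another candidate), and classified as cyclic when the
sequence returns to its starting scaffold element with more than two nodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .core import BreakpointGraph, OrientedSegment, ReconstructedPath, reverse_path
from .scaffold import ScaffoldDAG


@dataclass
class ScaffoldPath:
    """An oriented segment sequence read off one or more linked scaffolds."""

    tokens: tuple[OrientedSegment, ...]
    score: float
    supporting_contigs: tuple[str, ...]
    bp_length: float = 0.0

    def reversed(self) -> "ScaffoldPath":
        return ScaffoldPath(reverse_path(self.tokens), self.score, self.supporting_contigs,
                            self.bp_length)


@dataclass
class ScaffoldLink:
    path_a: int
    path_b: int
    b_reversed: bool
    overlap: int
    shared: tuple[OrientedSegment, ...]
    a_reversed: bool = False


@dataclass
class LinkedScaffoldGraph:
    paths: list[ScaffoldPath]
    links: list[ScaffoldLink] = field(default_factory=list)


# ---------------------------------------------------------------------------
# heaviest paths


def heaviest_scaffold_paths(dag: ScaffoldDAG, max_ties: int = 16) -> list[list[int]]:
    """All maximum-weight source-to-sink node paths over allowed edges."""
    n = len(dag.nodes)
    if n == 0:
        return []
    weight = {node.node_id: node.weight_bp for node in dag.nodes}
    preds: dict[int, list[int]] = {node.node_id: [] for node in dag.nodes}
    for e in dag.edges:
        if e.kind == "allowed":
            preds[e.dst].append(e.src)
    order = [node.node_id for node in dag.nodes]  # already sorted by contig coordinate
    best: dict[int, float] = {}
    back: dict[int, list[int | None]] = {}
    for v in order:
        options: list[tuple[float, int | None]] = [(weight[v], None)]
        for u in preds[v]:
            options.append((best[u] + weight[v], u))
        top = max(o[0] for o in options)
        best[v] = top
        back[v] = [o[1] for o in options if o[0] >= top - 1e-9]
    top_score = max(best.values())
    ends = [v for v in order if best[v] >= top_score - 1e-9]

    out: list[list[int]] = []

    def unwind(v: int, suffix: list[int]) -> None:
        if len(out) >= max_ties:
            return
        suffix = [v] + suffix
        parents = back[v]
        if None in parents:
            out.append(suffix)
        for u in parents:
            if u is not None:
                unwind(u, suffix)

    for v in ends:
        unwind(v, [])
    return out[:max_ties]


# ---------------------------------------------------------------------------
# linking


def _overlap_length(a: tuple, b: tuple) -> int:
    """Longest suffix of a equal to a prefix of b."""
    best = 0
    for o in range(1, min(len(a), len(b)) + 1):
        if a[-o:] == b[:o]:
            best = o
    return best


def link_scaffolds(paths: list[ScaffoldPath], min_overlap: int = 1) -> LinkedScaffoldGraph:
    """Find all endpoint sub-path overlaps between scaffold paths.

    Both assembly directions of each contig are considered: for every ordered
    pair (A, B) and for B in its given and reversed orientation, a suffix of
    A's token sequence matching a prefix of B's records a link.
    """
    graph = LinkedScaffoldGraph(list(paths))
    for ia, ib in itertools.permutations(range(len(paths)), 2):
        for a_rev, b_rev in itertools.product((False, True), repeat=2):
            a = paths[ia].reversed() if a_rev else paths[ia]
            b = paths[ib].reversed() if b_rev else paths[ib]
            o = _overlap_length(a.tokens, b.tokens)
            if o >= min_overlap and o < max(len(a.tokens), len(b.tokens)):
                graph.links.append(ScaffoldLink(ia, ib, b_rev, o, a.tokens[-o:], a_rev))
    return graph


def _is_closed_cycle(tokens: tuple[OrientedSegment, ...]) -> bool:
    n = len(tokens)
    return any(tokens[:k] == tokens[n - k :] and n - k > 2 for k in range(n // 2, 0, -1))


def merge_linked_paths(graph: LinkedScaffoldGraph, max_candidates: int = 256,
                       max_rounds: int = 8) -> list[ScaffoldPath]:
    """Merge scaffold paths through unambiguous endpoint overlaps.

    A path whose token sequence already returns to its own start is a complete
    cyclic reconstruction and is never extended. Among the rest, a merge
    A + B[overlap:] is made only when A's right end extends through exactly
    one partner and B's left end is reached from exactly one partner — an
    ambiguous junction (several variants sharing an endpoint segment, as in a
    heterogeneous mixture) is left unjoined and every branch stays a separate
    candidate. Duplicate sequences (up to reversal) are dropped.
    """
    pool: list[ScaffoldPath] = []
    seen: set[tuple] = set()
    for p in graph.paths:
        if p.tokens and p.tokens not in seen and reverse_path(p.tokens) not in seen:
            seen.add(p.tokens)
            pool.append(p)

    for _round in range(max_rounds):
        open_paths = [p for p in pool if not _is_closed_cycle(p.tokens)]
        # candidate joins: (a_idx, a_reversed, b_idx, b_reversed, overlap);
        # ambiguity is judged per physical path endpoint (head or tail)
        joins: list[tuple[int, bool, int, bool, int]] = []
        for ia, a0 in enumerate(open_paths):
            for ib, b0 in enumerate(open_paths):
                if ia == ib:
                    continue
                for a_rev, b_rev in itertools.product((False, True), repeat=2):
                    a = a0.reversed() if a_rev else a0
                    b = b0.reversed() if b_rev else b0
                    o = _overlap_length(a.tokens, b.tokens)
                    if 1 <= o < min(len(a.tokens), len(b.tokens)):
                        joins.append((ia, a_rev, ib, b_rev, o))
        out_deg: dict[tuple[int, bool], int] = {}
        in_deg: dict[tuple[int, bool], int] = {}
        for ia, a_rev, ib, b_rev, _o in joins:
            out_deg[(ia, a_rev)] = out_deg.get((ia, a_rev), 0) + 1
            in_deg[(ib, b_rev)] = in_deg.get((ib, b_rev), 0) + 1
        unambiguous = [j for j in joins
                       if out_deg[(j[0], j[1])] == 1 and in_deg[(j[2], j[3])] == 1]
        if not unambiguous or len(pool) >= max_candidates:
            break
        ia, a_rev, ib, b_rev, o = unambiguous[0]
        a0, b0 = open_paths[ia], open_paths[ib]
        a = a0.reversed() if a_rev else a0
        b = b0.reversed() if b_rev else b0
        merged = ScaffoldPath(
            a.tokens + b.tokens[o:],
            a.score + b.score,
            tuple(dict.fromkeys(a.supporting_contigs + b.supporting_contigs)),
            a.bp_length + b.bp_length,
        )
        pool = [p for p in pool if p is not a0 and p is not b0]
        if merged.tokens not in seen and reverse_path(merged.tokens) not in seen:
            seen.add(merged.tokens)
        pool.append(merged)
    return pool


# ---------------------------------------------------------------------------
# copy-number ratio check


def cn_ratio_check(path: list[OrientedSegment] | tuple[OrientedSegment, ...],
                   graph: BreakpointGraph) -> bool:
    """Does the path's per-segment multiplicity respect graph copy-number ratios?

    For each segment n with path multiplicity n_p and each level 0 < c < n_p
    realized by some path segment, with m_g the largest copy number among
    segments of multiplicity c, n_p may not exceed max(c, n_g / m_g) + 1.
    """
    mult: dict[int, int] = {}
    for e in path:
        mult[e.segment_id] = mult.get(e.segment_id, 0) + 1
    for sid in mult:
        if sid not in graph.segments:
            raise ValueError(f"path segment {sid} missing from graph")
    by_level: dict[int, list[float]] = {}
    for sid, m in mult.items():
        by_level.setdefault(m, []).append(graph.copy_number(sid))
    for sid, n_p in mult.items():
        n_g = graph.copy_number(sid)
        for c in range(1, n_p):
            if c not in by_level:
                continue
            m_g = max(by_level[c])
            if m_g <= 0:
                continue
            if n_p > max(c, n_g / m_g) + 1:
                return False
    return True


# ---------------------------------------------------------------------------
# subsequence filtering


def _rotations(tokens: tuple) -> list[tuple]:
    return [tokens[i:] + tokens[:i] for i in range(len(tokens))]


def _contains(sub: tuple, sup: tuple, sup_cyclic: bool = False, contiguous: bool = True) -> bool:
    if len(sub) > len(sup):
        return False
    hay = sup + sup if sup_cyclic else sup
    if contiguous:
        n = len(sub)
        return any(hay[i : i + n] == sub for i in range(len(hay) - n + 1))
    it = iter(hay)
    return all(tok in it for tok in sub)


def is_rotation_subsequence(candidate: tuple[OrientedSegment, ...],
                            kept: tuple[OrientedSegment, ...], kept_cyclic: bool = False,
                            contiguous: bool = True) -> bool:
    """Is any rotation of the candidate (or of its reversal) contained in kept?"""
    for form in (candidate, reverse_path(candidate)):
        for rot in _rotations(form):
            if _contains(rot, kept, kept_cyclic, contiguous):
                return True
    return False


def filter_subsequence_paths(sorted_paths: list[ReconstructedPath],
                             contiguous: bool = True) -> list[ReconstructedPath]:
    """Greedy keep of paths whose rotations are not contained in a kept path.

    ``sorted_paths`` must already be in descending total-alignment-score order;
    the caller's sort order decides which of two mutually redundant paths wins.
    """
    kept: list[ReconstructedPath] = []
    for p in sorted_paths:
        redundant = any(
            is_rotation_subsequence(p.elements, j.elements, j.cyclic, contiguous) for j in kept
        )
        if not redundant:
            kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# classification


def classify_path(tokens: tuple[OrientedSegment, ...]) -> tuple[tuple[OrientedSegment, ...], bool]:
    """Apply the cyclic rule: the path returns to its starting element(s) and
    has length > 2.

    A contig spanning a circular amplicon re-enters the structure, so the path
    repeats its opening run at the end; the longest such prefix/suffix overlap
    is the wrap-around. Singleton paths and two-element repeats (segmental
    tandem duplications) stay non-cyclic. For a cyclic path the duplicated
    wrap run is dropped, leaving one lap of the cycle.
    """
    n = len(tokens)
    for k in range(n // 2, 0, -1):
        if tokens[:k] == tokens[n - k :] and n - k > 2:
            return tokens[: n - k], True
    return tokens, False


def _cn_passing_windows(tokens: tuple[OrientedSegment, ...],
                        graph: BreakpointGraph) -> list[tuple[int, int]]:
    """Maximal contiguous sub-windows of a CN-violating path that pass the check.

    The path search admits every sub-path anchored at scaffold endpoints; when
    a full candidate exceeds the copy-number budget (e.g. reference flanks
    re-using amplicon segments), its longest copy-number-consistent stretches
    are still valid candidates.
    """
    n = len(tokens)
    out: list[tuple[int, int]] = []
    start = 0
    end = 0
    while end < n:
        if cn_ratio_check(tokens[start : end + 1], graph):
            end += 1
            continue
        if end > start:
            out.append((start, end))
        start += 1
        while start <= end and not cn_ratio_check(tokens[start : end + 1], graph):
            start += 1
        end = max(end, start)
    if end > start:
        out.append((start, end))
    return [w for w in out if not any(o != w and o[0] <= w[0] and w[1] >= o[0] and w[1] <= o[1] for o in out)]


def classify_and_emit(candidates: list[ScaffoldPath], graph: BreakpointGraph,
                      contiguous_subsequence: bool = True) -> list[ReconstructedPath]:
    """CN-check, deduplicate, classify and number candidate paths."""
    expanded: list[ScaffoldPath] = []
    for cand in candidates:
        if not cand.tokens:
            continue
        if cn_ratio_check(cand.tokens, graph):
            expanded.append(cand)
            continue
        total_bp = sum(graph.segments[t.segment_id].length for t in cand.tokens) or 1.0
        for i, j in _cn_passing_windows(cand.tokens, graph):
            sub = cand.tokens[i:j]
            bp = sum(graph.segments[t.segment_id].length for t in sub)
            expanded.append(
                ScaffoldPath(sub, cand.score * bp / total_bp, cand.supporting_contigs, bp)
            )
    recon: list[ReconstructedPath] = []
    for cand in expanded:
        tokens, cyclic = classify_path(cand.tokens)
        if not cn_ratio_check(tokens, graph):
            continue
        mult: dict[int, int] = {}
        for e in tokens:
            mult[e.segment_id] = mult.get(e.segment_id, 0) + 1
        copy_count = min(graph.copy_number(s) / m for s, m in mult.items())
        recon.append(
            ReconstructedPath(
                tokens,
                cyclic=cyclic,
                total_alignment_score=cand.score,
                supporting_contigs=cand.supporting_contigs,
                copy_count=max(copy_count, 0.0),
            )
        )
    recon.sort(key=lambda p: (-p.total_alignment_score, -p.length_bp(graph)))
    kept = filter_subsequence_paths(recon, contiguous_subsequence)
    for i, p in enumerate(kept, start=1):
        p.path_id = i
    return kept


# ---------------------------------------------------------------------------
# split-molecule integration clustering


def cluster_integration_points(junctions: list[tuple[float, float]],
                               tolerance_bp: float = 25_000.0,
                               min_molecules: int = 10) -> list[dict]:
    """Cluster split-alignment junctions supporting the same integration point.

    Each junction carries the breakpoint coordinate of its inside-amplicon and
    outside-amplicon partial alignments. Single-linkage joins two junctions
    when both coordinates agree within the tolerance; clusters of at least
    ``min_molecules`` are reported with median coordinates.
    """
    n = len(junctions)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        a, b = junctions[i], junctions[j]
        if abs(a[0] - b[0]) <= tolerance_bp and abs(a[1] - b[1]) <= tolerance_bp:
            parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        if len(members) < min_molecules:
            continue
        ins = np.median([junctions[i][0] for i in members])
        outs = np.median([junctions[i][1] for i in members])
        out.append({"n_molecules": len(members), "inside_bp": float(ins),
                    "outside_bp": float(outs), "members": sorted(members)})
    out.sort(key=lambda c: (-c["n_molecules"], c["inside_bp"]))
    return out
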