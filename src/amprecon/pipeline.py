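"""End-to-end reconstruction: digestion -> alignment -> scaffolding ->
imputation -> pathfinding.

`reconstruct` takes a breakpoint graph, its digested segment label maps and a
set of optical map contigs, and emits copy-number-consistent reconstructed
paths. Each stage is the corresponding module's public API; this file only
sequences them and carries bookkeeping between stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import ScoringParams, filter_alignments, iterative_align
from .core import BreakpointGraph, LabelMap, OrientedSegment, ReconstructedPath, SegmentAlignment
from .paths import (
    ScaffoldPath,
    classify_and_emit,
    heaviest_scaffold_paths,
    link_scaffolds,
    merge_linked_paths,
)
from .scaffold import (
    MAX_GAP_BP,
    CandidatePath,
    ScaffoldDAG,
    alignment_entry_node,
    alignment_exit_node,
    build_scaffold,
    enumerate_gap_paths,
    score_gap_candidates,
)

MIN_IMPUTE_GAP_BP = 1_000.0


@dataclass
class ReconstructionResult:
    paths: list[ReconstructedPath]
    scaffolds: list[ScaffoldDAG] = field(default_factory=list)
    alignments: list[SegmentAlignment] = field(default_factory=list)
    scaffold_paths: list[ScaffoldPath] = field(default_factory=list)


def align_segments_to_contigs(segment_maps: dict[int, LabelMap], contigs: list[LabelMap],
                              params: ScoringParams) -> dict[str, list[SegmentAlignment]]:
    """Significant alignments of every graph segment against every contig."""
    by_contig: dict[str, list[SegmentAlignment]] = {c.map_id: [] for c in contigs}
    for contig in contigs:
        for _sid, seg_map in sorted(segment_maps.items()):
            if seg_map.n_labels < params.min_labels:
                continue
            found = iterative_align(seg_map, contig, "semi-global", params)
            by_contig[contig.map_id].extend(filter_alignments(found, params))
    return by_contig


def _anchor_tails(source_aln: SegmentAlignment, dest_aln: SegmentAlignment,
                  segment_maps: dict[int, LabelMap]) -> tuple[float, float]:
    """Unaligned bp beyond the two anchor labels, along the contig direction."""
    src_map = segment_maps[int(source_aln.segment_id)]
    dst_map = segment_maps[int(dest_aln.segment_id)]
    n_src, n_dst = src_map.n_labels, dst_map.n_labels
    src_pos = src_map.positions if source_aln.orientation == "+" else src_map.reversed().positions
    dst_pos = dst_map.positions if dest_aln.orientation == "+" else dst_map.reversed().positions
    src_idx = max((q if source_aln.orientation == "+" else n_src - 1 - q)
                  for _j, q in source_aln.pairs)
    dst_idx = min((q if dest_aln.orientation == "+" else n_dst - 1 - q)
                  for _j, q in dest_aln.pairs)
    return float(src_map.length_bp - src_pos[src_idx]), float(dst_pos[dst_idx])


UNEXPLAINED_GAP_BP = 25_000.0


def impute_path_gaps(dag: ScaffoldDAG, node_path: list[int], graph: BreakpointGraph,
                     contig: LabelMap, segment_maps: dict[int, LabelMap],
                     params: ScoringParams) -> list[tuple[list[OrientedSegment], float]]:
    """Expand a heaviest scaffold node path into oriented segment chunks.

    For every consecutive pair of anchors with an imputable gap (< 400 kbp),
    candidate breakpoint-graph paths are enumerated and the best-fitting one
    (if it improves on the bare junction) is spliced in between the anchors.
    A junction whose gap clearly contains unexplained structure (more interior
    bp than the imputation slack) but for which no candidate was accepted
    splits the path: asserting that adjacency would fabricate a junction the
    data does not support. Returns (token chunk, imputation score) pairs.
    """
    nodes = {n.node_id: n for n in dag.nodes}
    chunks: list[tuple[list[OrientedSegment], float]] = []
    tokens: list[OrientedSegment] = []
    fit_score = 0.0
    for idx, nid in enumerate(node_path):
        node = nodes[nid]
        tokens.append(node.oriented_segment)
        fit_score += node.alignment.score
        if idx + 1 >= len(node_path):
            break
        nxt = nodes[node_path[idx + 1]]
        gap_bp = float(contig.positions[nxt.start_label] - contig.positions[node.end_label])
        tail_s, head_d = _anchor_tails(node.alignment, nxt.alignment, segment_maps)
        expected_interior = gap_bp - tail_s - head_d
        best = None
        if MIN_IMPUTE_GAP_BP <= gap_bp < MAX_GAP_BP and expected_interior > 0:
            source = alignment_exit_node(node.alignment)
            dest = alignment_entry_node(nxt.alignment)
            candidates = enumerate_gap_paths(graph, source, dest, expected_interior)
            best = score_gap_candidates(candidates, contig, node.alignment, nxt.alignment,
                                        segment_maps, params)
        if best is not None:
            tokens.extend(best.elements)
            fit_score += max(best.fitting_score, 0.0)
        elif expected_interior > UNEXPLAINED_GAP_BP:
            chunks.append((tokens, fit_score))
            tokens, fit_score = [], 0.0
    chunks.append((tokens, fit_score))
    return chunks


def reconstruct(graph: BreakpointGraph, contigs: list[LabelMap],
                segment_maps: dict[int, LabelMap],
                params: ScoringParams | None = None,
                impute: bool = True,
                link: bool = True,
                max_paths: int = 64) -> ReconstructionResult:
    """Reconstruct amplicon paths from a breakpoint graph and OM contigs."""
    params = params or ScoringParams()
    segment_lengths = {sid: float(s.length) for sid, s in graph.segments.items()}
    by_contig = align_segments_to_contigs(segment_maps, contigs, params)

    scaffolds: list[ScaffoldDAG] = []
    scaffold_paths: list[ScaffoldPath] = []
    contig_by_id = {c.map_id: c for c in contigs}
    for contig_id, alns in by_contig.items():
        if not alns:
            continue
        contig = contig_by_id[contig_id]
        dag = build_scaffold(alns, contig, segment_lengths)
        scaffolds.append(dag)
        nodes = {n.node_id: n for n in dag.nodes}
        for node_path in heaviest_scaffold_paths(dag):
            if impute:
                chunks = impute_path_gaps(dag, node_path, graph, contig,
                                          segment_maps, params)
            else:
                chunks = [
                    ([nodes[nid].oriented_segment for nid in node_path],
                     sum(nodes[nid].alignment.score for nid in node_path))
                ]
            for tokens, score in chunks:
                if not tokens:
                    continue
                bp = sum(segment_lengths.get(t.segment_id, 0.0) for t in tokens)
                scaffold_paths.append(ScaffoldPath(tuple(tokens), score, (contig_id,), bp))

    if link:
        linked = link_scaffolds(scaffold_paths)
        candidates = merge_linked_paths(linked, max_candidates=max(4 * max_paths, 64))
    else:
        candidates = scaffold_paths
    emitted = classify_and_emit(candidates, graph)[:max_paths]
    all_alns = [a for alns in by_contig.values() for a in alns]
    return ReconstructionResult(emitted, scaffolds, all_alns, scaffold_paths)
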