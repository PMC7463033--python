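"""Reconstruction accuracy scoring against ground truth.

Agreement between a reconstructed path and the true structure is the longest
common substring (LCS) of their oriented-segment token sequences — contiguous,
orientation-aware, with cyclic paths compared over all rotations and either
path allowed in reversed (orientation-flipped) form. The LCS is measured under
one of three path measures:

* ``length_bp``  — summed segment lengths (bp);
* ``nsegs``      — number of segments;
* ``breakpoint`` — number of junctions (elements − 1, or elements for a cycle).

and precision = M(LCS)/M(reconstruction), recall = M(LCS)/M(truth). Cohorts
are summarized by the mean F1 over amplicons (F1 of a (0, 0) pair is 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import BreakpointGraph, OrientedSegment, ReconstructedPath

METRICS = ("length_bp", "nsegs", "breakpoint")

Token = tuple[int, str]


def _tokens(path: ReconstructedPath | Sequence[OrientedSegment]) -> tuple[Token, ...]:
    elems = path.elements if isinstance(path, ReconstructedPath) else tuple(path)
    return tuple((e.segment_id, e.orientation) for e in elems)


def path_measure(tokens: Sequence[Token], metric: str, graph: BreakpointGraph | None = None,
                 cyclic: bool = False) -> float:
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    n = len(tokens)
    if metric == "nsegs":
        return float(n)
    if metric == "breakpoint":
        return float(n if cyclic else max(n - 1, 0))
    if graph is None:
        raise ValueError("length_bp measure needs the breakpoint graph")
    return float(sum(graph.segments[sid].length for sid, _o in tokens))


def _reverse_tokens(tokens: tuple[Token, ...]) -> tuple[Token, ...]:
    return tuple((sid, "-" if o == "+" else "+") for sid, o in reversed(tokens))


def _best_common_run(a: tuple[Token, ...], b: tuple[Token, ...], cyclic_a: bool,
                     cyclic_b: bool, measure) -> tuple[Token, ...]:
    """Longest (by ``measure``) common substring; cyclic inputs are doubled."""
    la, lb = len(a), len(b)
    aa = a + a if cyclic_a and la else a
    bb = b + b if cyclic_b and lb else b
    best: tuple[Token, ...] = ()
    best_val = 0.0
    run = np.zeros((len(aa) + 1, len(bb) + 1), dtype=np.int32)
    for i in range(1, len(aa) + 1):
        for j in range(1, len(bb) + 1):
            if aa[i - 1] == bb[j - 1]:
                L = run[i, j] = run[i - 1, j - 1] + 1
                Lcap = min(int(L), la, lb)
                cand = aa[i - Lcap : i]
                val = measure(cand)
                if val > best_val or (val == best_val and len(cand) > len(best)):
                    best, best_val = cand, val
    return best


def lcs(path_a, path_b, cyclic_a: bool | None = None, cyclic_b: bool | None = None,
        allow_reverse: bool = True, measure=None) -> list[OrientedSegment]:
    """Longest common substring of two oriented-segment paths.

    ``path_b`` is also compared in its orientation-reversed form; rotations of
    cyclic paths all count. ``measure`` (tokens -> value) selects among common
    substrings; by default the element count. Ties go to the run found first.
    """
    a, b = _tokens(path_a), _tokens(path_b)
    if cyclic_a is None:
        cyclic_a = getattr(path_a, "cyclic", False)
    if cyclic_b is None:
        cyclic_b = getattr(path_b, "cyclic", False)
    measure = measure or len
    best = _best_common_run(a, b, cyclic_a, cyclic_b, measure)
    if allow_reverse:
        alt = _best_common_run(a, _reverse_tokens(b), cyclic_a, cyclic_b, measure)
        if measure(alt) > measure(best):
            best = alt
    return [OrientedSegment(sid, o) for sid, o in best]


@dataclass
class EvalResult:
    precision: float
    recall: float
    f1: float
    metric: str
    lcs_elements: list[OrientedSegment]

    def __iter__(self):
        yield self.precision
        yield self.recall


def f1_score(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def trim_trivial_ends(recon: ReconstructedPath, truth: ReconstructedPath,
                      graph: BreakpointGraph) -> ReconstructedPath:
    """Strip terminal runs that merely follow the reference and lack truth support.

    Assembled contigs extend into the native genome beyond the amplicon; a
    reconstructed path can therefore end with reference-adjacent segments the
    true structure never uses. Such junctions are removed from both ends
    before scoring. Cyclic reconstructions have no ends to trim.
    """
    if recon.cyclic or len(recon.elements) < 2:
        return recon

    def junction_key(a: OrientedSegment, b: OrientedSegment):
        return frozenset([(a.segment_id, a.orientation, "out"), (b.segment_id, b.orientation, "in")])

    truth_junctions = set()
    pairs = list(zip(truth.elements, truth.elements[1:]))
    if truth.cyclic:
        pairs.append((truth.elements[-1], truth.elements[0]))
    for a, b in pairs:
        truth_junctions.add(junction_key(a, b))
        truth_junctions.add(junction_key(b.flipped(), a.flipped()))

    def reference_adjacent(a: OrientedSegment, b: OrientedSegment) -> bool:
        sa, sb = graph.segments[a.segment_id], graph.segments[b.segment_id]
        if sa.chrom != sb.chrom or a.orientation != b.orientation:
            return False
        if a.orientation == "+":
            return sb.start == sa.end + 1
        return sa.start == sb.end + 1

    elems = list(recon.elements)
    changed = True
    while changed and len(elems) > 1:
        changed = False
        if reference_adjacent(elems[-2], elems[-1]) and junction_key(elems[-2], elems[-1]) not in truth_junctions:
            elems.pop()
            changed = True
        if len(elems) > 1 and reference_adjacent(elems[0], elems[1]) and junction_key(elems[0], elems[1]) not in truth_junctions:
            elems.pop(0)
            changed = True
    return ReconstructedPath(tuple(elems), cyclic=False,
                             total_alignment_score=recon.total_alignment_score,
                             supporting_contigs=recon.supporting_contigs)


def precision_recall(truth: ReconstructedPath, recon: ReconstructedPath, metric: str,
                     graph: BreakpointGraph | None = None) -> EvalResult:
    """Precision and recall of one reconstruction under one path measure."""
    if not truth.elements:
        raise ValueError("empty truth path")
    meas = lambda toks: path_measure(toks, metric, graph)  # noqa: E731
    common = lcs(truth, recon, measure=meas)
    common_tokens = _tokens(common)
    m_lcs = path_measure(common_tokens, metric, graph,
                         cyclic=(truth.cyclic and len(common) == len(truth.elements)
                                 and recon.cyclic and len(common) == len(recon.elements)))
    m_truth = path_measure(_tokens(truth), metric, graph, cyclic=truth.cyclic)
    m_recon = path_measure(_tokens(recon), metric, graph, cyclic=recon.cyclic)
    precision = m_lcs / m_recon if m_recon > 0 else 0.0
    recall = m_lcs / m_truth if m_truth > 0 else 0.0
    precision = min(precision, 1.0)
    recall = min(recall, 1.0)
    return EvalResult(precision, recall, f1_score(precision, recall), metric, common)


def score_reconstructions(truth: ReconstructedPath, recons: list[ReconstructedPath],
                          metric: str, graph: BreakpointGraph,
                          trim: bool = True) -> EvalResult:
    """Score the reconstruction sharing the longest common substring with truth.

    Among several emitted paths only the path having the (measure-maximal) LCS
    with the truth is scored; ties go to the pair yielding the better F1.
    """
    if not recons:
        return EvalResult(0.0, 0.0, 0.0, metric, [])
    best: EvalResult | None = None
    best_key = None
    for r in recons:
        r2 = trim_trivial_ends(r, truth, graph) if trim else r
        res = precision_recall(truth, r2, metric, graph)
        m_lcs = path_measure(_tokens(res.lcs_elements), metric, graph)
        key = (m_lcs, res.f1)
        if best is None or key > best_key:
            best, best_key = res, key
    return best


def mean_f1(results: Sequence[EvalResult | tuple[float, float]]) -> float:
    """Mean F1 over amplicons; each element is an EvalResult or (P, R) pair."""
    if len(results) == 0:
        raise ValueError("mean F1 of an empty cohort")
    vals = []
    for r in results:
        p, rc = (r.precision, r.recall) if isinstance(r, EvalResult) else (r[0], r[1])
        vals.append(f1_score(p, rc))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# duplications


def find_duplicated_blocks(truth: ReconstructedPath) -> list[tuple[tuple[Token, ...], int]]:
    """Maximal contiguous blocks occurring at least twice in the truth path."""
    toks = _tokens(truth)
    n = len(toks)
    hay = toks + toks if truth.cyclic else toks

    def count(block: tuple[Token, ...]) -> int:
        L = len(block)
        limit = n if truth.cyclic else n - L + 1
        return sum(1 for i in range(max(limit, 0)) if hay[i : i + L] == block)

    blocks: dict[tuple[Token, ...], int] = {}
    for L in range(n, 0, -1):
        for i in range(n):
            if i + L > len(hay):
                break
            block = hay[i : i + L]
            if block in blocks:
                continue
            cnt = count(block)
            if cnt >= 2:
                if any(len(b) > L and _contains_run(b, block) for b in blocks):
                    continue
                blocks[block] = cnt
    return sorted(blocks.items(), key=lambda kv: (-len(kv[0]), kv[0]))


def _contains_run(sup: tuple, sub: tuple) -> bool:
    L = len(sub)
    return any(sup[i : i + L] == sub for i in range(len(sup) - L + 1))


def duplication_resolved(truth: ReconstructedPath, recon: ReconstructedPath) -> dict[tuple, bool]:
    """Per duplicated block: does the reconstruction resolve it?

    Resolved means the block appears in the reconstruction at the truth
    multiplicity with truth-consistent flanking context: every context window
    (previous element + block + next element, where the ends exist) seen in
    the truth appears at least as often in the reconstruction. Reversed and
    rotated forms of the reconstruction count.
    """
    out: dict[tuple, bool] = {}
    t = _tokens(truth)
    t_hay = t + t if truth.cyclic else t
    r = _tokens(recon)
    r_forms = []
    for form in (r, _reverse_tokens(r)):
        r_forms.append(form + form if recon.cyclic else form)

    def occurrences(hay: tuple, block: tuple, limit: int) -> list[int]:
        L = len(block)
        return [i for i in range(max(limit, 0)) if hay[i : i + L] == block]

    def flank(hay: tuple, i: int, L: int, cyclic: bool, base_len: int):
        prev = hay[i - 1] if (i - 1 >= 0 or cyclic) and i - 1 < len(hay) and i > 0 else None
        nxt = hay[i + L] if i + L < len(hay) else None
        if cyclic:
            prev = hay[(i - 1) % base_len]
            nxt = hay[(i + L) % base_len]
        return prev, nxt

    for block, multiplicity in find_duplicated_blocks(truth):
        L = len(block)
        t_limit = len(t) if truth.cyclic else len(t) - L + 1
        truth_flanks = [
            flank(t_hay, i, L, truth.cyclic, len(t))
            for i in occurrences(t_hay, block, t_limit)
        ]
        ok = False
        for hay in r_forms:
            r_limit = len(r) if recon.cyclic else len(hay) - L + 1
            consistent = 0
            for i in occurrences(hay, block, r_limit):
                prev, nxt = flank(hay, i, L, recon.cyclic, len(r))
                if any(
                    (prev is None or tp is None or prev == tp)
                    and (nxt is None or tn is None or nxt == tn)
                    for tp, tn in truth_flanks
                ):
                    consistent += 1
            if consistent >= multiplicity:
                ok = True
                break
        out[block] = ok
    return out
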