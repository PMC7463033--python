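"""Ground-truth amplicon simulation: structures, breakpoint graphs and noisy
optical maps.

The generator emulates the data a reconstruction run consumes, end to end:

1. a toy reference chromosome of i.i.d. random bases (which carries the
   labeling motif at realistic density, ~one site per 8 kbp for GCTCTTC);
2. a rearranged amplicon structure — a window of the reference partitioned
   into segments, then shuffled by inversions, duplications and
   translocations — together with the breakpoint graph that structure implies
   (copy numbers = path multiplicity × amplicon copy number; concordant edges
   for reference adjacencies, discordant edges for rearranged junctions);
3. consensus optical map contigs and raw molecules digested from the
   rearranged sequence, with the three dominant optical-map error modes
   applied: missing labels, collapse of labels closer than ~2 kbp, and
   per-interval sizing error.

All randomness flows through a single numpy Generator derived from the
configured seed, so outputs are bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .align import ScoringParams, merge_probability
from .core import (
    BreakpointGraph,
    GraphEdge,
    GraphSegment,
    LabelMap,
    OrientedSegment,
    ReconstructedPath,
)
from .om_io import MOTIFS, digest_sequence, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def rng_from(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class SimConfig:
    """Study conditions for one simulated sample."""

    seed: int = 0
    n_segments: int | None = None          # None: coupled to total_bp (~120 kbp/segment)
    total_bp_range: tuple[float, float] = (300_000.0, 2_800_000.0)
    cyclic: bool = False
    copy_number: int = 20
    label_miss_rate: float = 0.05
    sizing_sd_fraction: float = 0.02       # per-interval Gaussian sd as fraction of length
    collapse: bool = True                  # apply the ~2 kbp label-collapse model
    false_label_rate: float = 5e-6         # spurious labels per bp
    coverage: float = 40.0
    contig_break_rate: float = 0.0         # breaks per Mbp of contig
    false_edge_fraction: float = 0.0
    mixture_cns: tuple[int, ...] | None = None
    motif: str = MOTIFS["BspQI"]
    min_segment_bp: float = 20_000.0
    flank_bp: float = 100_000.0            # native reference flank on linear contigs
    cyclic_wrap_bp: float = 300_000.0      # wrap-around overlap on cyclic contigs
    molecule_length_median: float = 244_000.0
    molecule_length_sigma: float = 0.45
    scoring: ScoringParams = field(default_factory=ScoringParams)

    def __post_init__(self) -> None:
        for p in (self.label_miss_rate,):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def toy_reference(length_bp: int, seed, chrom: str = "chr1") -> dict[str, str]:
    """A synthetic chromosome of i.i.d. bases (packaged-genome stand-in)."""
    rng = rng_from(seed)
    arr = _BASES[rng.integers(0, 4, size=int(length_bp))]
    return {chrom: arr.tobytes().decode()}


# ---------------------------------------------------------------------------
# structures


def _rearrange(tokens: list[OrientedSegment], rng: np.random.Generator,
               n_ops: int) -> list[OrientedSegment]:
    for _ in range(n_ops):
        if len(tokens) < 2:
            break
        op = rng.choice(["invert", "duplicate", "translocate"])
        n = len(tokens)
        i = int(rng.integers(0, n))
        j = int(min(n, i + 1 + rng.integers(0, max(1, n // 3))))
        run = tokens[i:j]
        if op == "invert":
            tokens[i:j] = [t.flipped() for t in reversed(run)]
        elif op == "duplicate":
            run = tokens[i : min(j, i + 3)]
            if rng.random() < 0.3:
                run = [t.flipped() for t in reversed(run)]
            k = min(j, i + 3) if rng.random() < 0.5 else int(rng.integers(0, len(tokens) + 1))
            tokens[k:k] = list(run)
        else:
            rest = tokens[:i] + tokens[j:]
            k = int(rng.integers(0, len(rest) + 1))
            tokens = rest[:k] + run + rest[k:]
    return tokens


def _junction(a: OrientedSegment, b: OrientedSegment, segments: dict[int, GraphSegment]):
    sa, sb = segments[a.segment_id], segments[b.segment_id]
    exit_side = "right" if a.orientation == "+" else "left"
    entry_side = "left" if b.orientation == "+" else "right"
    concordant = (
        sa.chrom == sb.chrom
        and (
            (a.orientation == b.orientation == "+" and sb.start == sa.end + 1)
            or (a.orientation == b.orientation == "-" and sa.start == sb.end + 1)
        )
    )
    return (a.segment_id, exit_side, b.segment_id, entry_side,
            "concordant" if concordant else "discordant")


def graph_from_path(truth: ReconstructedPath, segments: dict[int, GraphSegment],
                    copy_number: float) -> BreakpointGraph:
    """The breakpoint graph a truth path implies.

    Segment CN = path multiplicity × amplicon copy number. Junction edges get
    their path multiplicity; concordant reference adjacencies between graph
    segments are always present (read pairs spanning an amplified reference
    junction support them whether or not the path uses them).
    """
    mult: dict[int, int] = {}
    for e in truth.elements:
        mult[e.segment_id] = mult.get(e.segment_id, 0) + 1
    graph_segments = [
        GraphSegment(sid, s.chrom, s.start, s.end, mult.get(sid, 0) * copy_number)
        for sid, s in segments.items()
        if sid in mult
    ]
    graph = BreakpointGraph(graph_segments)
    edge_counts: dict[frozenset, list] = {}
    pairs = list(zip(truth.elements, truth.elements[1:]))
    if truth.cyclic and len(truth.elements) > 1:
        pairs.append((truth.elements[-1], truth.elements[0]))
    elif truth.cyclic and len(truth.elements) == 1:
        pairs.append((truth.elements[0], truth.elements[0]))
    for a, b in pairs:
        sa, ea, sb, eb, etype = _junction(a, b, segments)
        key = frozenset([(sa, ea), (sb, eb)]) if (sa, ea) != (sb, eb) else frozenset([(sa, ea), ("self", eb)])
        rec = edge_counts.setdefault(key, [sa, ea, sb, eb, etype, 0])
        rec[5] += 1
    for rec in edge_counts.values():
        graph.add_edge(GraphEdge(rec[0], rec[1], rec[2], rec[3], rec[4], rec[5]))
    present = sorted(mult)
    for sid_a, sid_b in zip(present, present[1:]):
        a, b = graph.segments[sid_a], graph.segments[sid_b]
        if a.chrom == b.chrom and b.start == a.end + 1:
            key = frozenset([(sid_a, "right"), (sid_b, "left")])
            if key not in edge_counts:
                graph.add_edge(GraphEdge(sid_a, "right", sid_b, "left", "concordant", 1.0))
    return graph


def simulate_amplicon_structure(config: SimConfig, reference: dict[str, str],
                                rng: np.random.Generator | None = None,
                                duplication_block_bp: float | None = None,
                                ) -> tuple[ReconstructedPath, BreakpointGraph]:
    """Draw a rearranged amplicon structure and its implied breakpoint graph.

    A contiguous window of the reference is partitioned into segments whose
    count tracks the drawn length (~120 kbp per segment when ``n_segments`` is
    unset, matching the ~100 kbp median graph-segment length of real focal
    amplifications); the segment order is then shuffled by inversion,
    duplication and translocation events. With ``duplication_block_bp`` set, a
    block of 1-3 segments near that total length is tandem-duplicated.
    """
    rng = rng or rng_from(config.seed)
    chrom = next(iter(reference))
    ref_len = len(reference[chrom])
    total = float(rng.uniform(*config.total_bp_range))
    margin = 2 * config.flank_bp
    if total + margin > ref_len:
        raise ValueError(f"amplicon of {total:.0f} bp does not fit the {ref_len} bp reference")
    if config.n_segments is not None:
        n = int(config.n_segments)
    else:
        n = int(np.clip(round(total / 120_000.0 * rng.lognormal(0.0, 0.25)), 3, 20))
    if n * config.min_segment_bp > total:
        n = max(1, int(total // config.min_segment_bp))
    lengths = config.min_segment_bp + rng.dirichlet(np.full(n, 2.0)) * (total - n * config.min_segment_bp)
    lengths = np.round(lengths).astype(int)
    start = int(rng.integers(config.flank_bp, ref_len - total - config.flank_bp))
    segments: dict[int, GraphSegment] = {}
    pos = start
    for sid, L in enumerate(lengths, start=1):
        segments[sid] = GraphSegment(sid, chrom, pos, pos + int(L) - 1, 0.0)
        pos += int(L)
    tokens = [OrientedSegment(sid, "+") for sid in sorted(segments)]
    n_ops = max(1, round(n / 3))
    tokens = _rearrange(tokens, rng, n_ops)
    if duplication_block_bp is not None:
        best_run, best_err = (0, 1), float("inf")
        m = len(tokens)
        for i in range(m):
            for j in range(i + 1, min(m, i + 3) + 1):
                err = abs(sum(segments[t.segment_id].length for t in tokens[i:j]) - duplication_block_bp)
                if err < best_err:
                    best_run, best_err = (i, j), err
        i, j = best_run
        tokens[j:j] = tokens[i:j]
    truth = ReconstructedPath(tuple(tokens), cyclic=config.cyclic)
    graph = graph_from_path(truth, segments, config.copy_number)
    return truth, graph


def simulate_related_structures(config: SimConfig, reference: dict[str, str],
                                cns: tuple[int, ...],
                                rng: np.random.Generator | None = None,
                                ) -> list[tuple[ReconstructedPath, BreakpointGraph]]:
    """Heterogeneous amplicon variants sharing one genomic region.

    One window of the reference is partitioned into segments once; each
    variant independently keeps a large contiguous subset of the segments and
    rearranges it, emulating related amplicon species co-existing in a sample
    at different copy numbers (``cns``).
    """
    rng = rng or rng_from(config.seed)
    chrom = next(iter(reference))
    ref_len = len(reference[chrom])
    total = float(rng.uniform(*config.total_bp_range))
    if total + 2 * config.flank_bp > ref_len:
        raise ValueError("window does not fit the reference")
    if config.n_segments is not None:
        n = int(config.n_segments)
    else:
        n = int(np.clip(round(total / 120_000.0 * rng.lognormal(0.0, 0.25)), 3, 20))
    lengths = config.min_segment_bp + rng.dirichlet(np.full(n, 2.0)) * (total - n * config.min_segment_bp)
    lengths = np.round(lengths).astype(int)
    start = int(rng.integers(config.flank_bp, ref_len - total - config.flank_bp))
    segments: dict[int, GraphSegment] = {}
    pos = start
    for sid, L in enumerate(lengths, start=1):
        segments[sid] = GraphSegment(sid, chrom, pos, pos + int(L) - 1, 0.0)
        pos += int(L)
    out = []
    for cn in cns:
        keep = max(2, int(round(n * rng.uniform(0.7, 1.0))))
        lo = int(rng.integers(0, n - keep + 1))
        tokens = [OrientedSegment(sid, "+") for sid in sorted(segments)[lo : lo + keep]]
        tokens = _rearrange(tokens, rng, max(1, round(keep / 3)))
        truth = ReconstructedPath(tuple(tokens), cyclic=config.cyclic)
        out.append((truth, graph_from_path(truth, segments, cn)))
    return out


def truth_sequence(truth: ReconstructedPath, graph: BreakpointGraph,
                   reference: dict[str, str]) -> str:
    parts = []
    for e in truth.elements:
        s = graph.segments[e.segment_id]
        seq = reference[s.chrom][s.start - 1 : s.end]
        parts.append(seq if e.orientation == "+" else reverse_complement(seq))
    return "".join(parts)


# ---------------------------------------------------------------------------
# optical-map noise


def apply_map_noise(lmap: LabelMap, config: SimConfig, rng: np.random.Generator) -> LabelMap:
    """Label miss, label collapse, spurious labels and per-interval sizing error."""
    pos = lmap.positions.copy()
    if config.collapse and pos.size > 1:
        kept = [float(pos[0])]
        for p in pos[1:]:
            gap = p - kept[-1]
            if rng.random() < merge_probability(gap, config.scoring):
                # the merged pair is imaged as one label at one of the two sites
                if rng.random() < 0.5:
                    kept[-1] = float(p)
            else:
                kept.append(float(p))
        pos = np.asarray(kept)
    if config.label_miss_rate > 0 and pos.size:
        pos = pos[rng.random(pos.size) >= config.label_miss_rate]
    if config.false_label_rate > 0:
        n_false = rng.poisson(config.false_label_rate * lmap.length_bp)
        if n_false:
            pos = np.unique(np.concatenate([pos, rng.uniform(1, lmap.length_bp, n_false)]))
    if config.sizing_sd_fraction > 0:
        bounds = np.concatenate([[0.0], pos, [lmap.length_bp]])
        intervals = np.diff(bounds)
        factors = np.clip(rng.normal(1.0, config.sizing_sd_fraction, intervals.size), 0.05, None)
        newb = np.cumsum(intervals * factors)
        pos = newb[:-1][: pos.size] if pos.size else pos
        length = float(newb[-1])
    else:
        length = lmap.length_bp
    pos = np.unique(pos)
    pos = pos[(pos > 0) & (pos <= length)]
    return LabelMap(lmap.map_id, length, pos)


def simulate_contigs(truth: ReconstructedPath, graph: BreakpointGraph,
                     reference: dict[str, str], config: SimConfig,
                     rng: np.random.Generator | None = None) -> list[LabelMap]:
    """Noisy consensus contigs covering the truth structure.

    Cyclic structures yield one linear contig spanning a full lap plus a
    wrap-around overlap (so the repeated entry segment evidences circularity);
    linear structures get native reference flanks on both sides. A positive
    ``contig_break_rate`` splits the spanning contig into fragments, emulating
    assembly failure.
    """
    rng = rng or rng_from(config.seed)
    seq = truth_sequence(truth, graph, reference)
    if truth.cyclic:
        wrap = []
        acc = 0.0
        for e in truth.elements:
            if acc >= config.cyclic_wrap_bp:
                break
            wrap.append(e)
            acc += graph.segments[e.segment_id].length
        seq = seq + truth_sequence(ReconstructedPath(tuple(wrap), cyclic=False), graph, reference)
    else:
        first, last = truth.elements[0], truth.elements[-1]
        seq = (_flank(first, graph, reference, config, "left")
               + seq
               + _flank(last, graph, reference, config, "right"))
    digest = digest_sequence(seq, config.motif, map_id="contig_1")
    noisy = apply_map_noise(digest, config, rng)
    if config.contig_break_rate <= 0:
        return [noisy]
    n_breaks = rng.poisson(config.contig_break_rate * noisy.length_bp / 1e6)
    cuts = np.sort(rng.uniform(0, noisy.length_bp, n_breaks))
    bounds = np.concatenate([[0.0], cuts, [noisy.length_bp]])
    out = []
    for i, (lo, hi) in enumerate(zip(bounds, bounds[1:]), start=1):
        if hi - lo < 1.0:
            continue
        pos = noisy.positions[(noisy.positions > lo) & (noisy.positions <= hi)] - lo
        out.append(LabelMap(f"contig_{i}", float(hi - lo), pos))
    return out


def _flank(elem: OrientedSegment, graph: BreakpointGraph, reference: dict[str, str],
           config: SimConfig, side: str) -> str:
    s = graph.segments[elem.segment_id]
    chrom_seq = reference[s.chrom]
    fl = int(config.flank_bp)
    upstream = elem.orientation == "+" if side == "left" else elem.orientation == "-"
    if upstream:
        lo = max(0, s.start - 1 - fl)
        seq = chrom_seq[lo : s.start - 1]
        return seq if elem.orientation == "+" else reverse_complement(seq)
    hi = min(len(chrom_seq), s.end + fl)
    seq = chrom_seq[s.end : hi]
    return seq if elem.orientation == "+" else reverse_complement(seq)


def simulate_molecules(truth: ReconstructedPath, graph: BreakpointGraph,
                       reference: dict[str, str], config: SimConfig,
                       rng: np.random.Generator | None = None) -> list[LabelMap]:
    """Noisy single molecules sampled from the truth structure at given coverage."""
    rng = rng or rng_from(config.seed)
    seq_len_arr = [graph.segments[e.segment_id].length for e in truth.elements]
    total = float(sum(seq_len_arr))
    digest = digest_sequence(truth_sequence(truth, graph, reference), config.motif, "truth")
    if config.coverage <= 0:
        return []
    mu = np.log(config.molecule_length_median)
    out: list[LabelMap] = []
    covered = 0.0
    i = 0
    while covered < config.coverage * total:
        L = float(np.exp(rng.normal(mu, config.molecule_length_sigma)))
        L = min(L, total)
        start = float(rng.uniform(0, total))
        i += 1
        if truth.cyclic:
            pos = (digest.positions - start) % total
            pos = np.sort(pos[pos < L])
            pos = pos + 1.0
        else:
            if start + L > total:
                start = total - L
            pos = digest.positions[(digest.positions > start) & (digest.positions <= start + L)] - start
        mol = LabelMap(f"mol_{i}", L, np.unique(pos[(pos > 0) & (pos <= L)]))
        out.append(apply_map_noise(mol, config, rng))
        covered += L
    return out


# ---------------------------------------------------------------------------
# graph corruption, mixtures, unlabeled inserts


def inject_false_edges(graph: BreakpointGraph, fraction: float, seed) -> BreakpointGraph:
    """Add random discordant edges, round(fraction × |edges|) of them, none
    duplicating an existing junction."""
    if fraction < 0:
        raise ValueError("fraction must be non-negative")
    rng = rng_from(seed)
    n_false = int(round(fraction * len(graph.edges)))
    out = BreakpointGraph(list(graph.segments.values()), list(graph.edges))
    if n_false == 0:
        return out
    endpoints = [(sid, side) for sid in sorted(graph.segments) for side in ("left", "right")]
    existing = {e.key() for e in graph.edges}
    candidates = [
        (a, b)
        for i, a in enumerate(endpoints)
        for b in endpoints[i + 1 :]
        if frozenset([a, b]) not in existing
    ]
    if len(candidates) < n_false:
        raise ValueError("not enough distinct endpoint pairs for requested false edges")
    idx = rng.choice(len(candidates), size=n_false, replace=False)
    for i in idx:
        (sa, ea), (sb, eb) = candidates[int(i)]
        out.add_edge(GraphEdge(sa, ea, sb, eb, "discordant", 1.0))
    return out


def merge_graphs(graphs: list[BreakpointGraph]) -> BreakpointGraph:
    """Union of related breakpoint graphs (shared segments keep the summed CN)."""
    cn: dict[int, float] = {}
    segs: dict[int, GraphSegment] = {}
    for g in graphs:
        for sid, s in g.segments.items():
            segs[sid] = s
            cn[sid] = cn.get(sid, 0.0) + s.copy_number
    merged = BreakpointGraph(
        [GraphSegment(sid, s.chrom, s.start, s.end, cn[sid]) for sid, s in segs.items()]
    )
    seen = set()
    for g in graphs:
        for e in g.edges:
            k = (e.key(), e.edge_type)
            if k not in seen:
                seen.add(k)
                merged.add_edge(e)
    return merged


def make_mixture(truths: list[tuple[ReconstructedPath, BreakpointGraph]],
                 cns: tuple[int, ...], reference: dict[str, str], config: SimConfig,
                 rng: np.random.Generator | None = None,
                 molecules: bool = False) -> tuple[list[LabelMap], BreakpointGraph]:
    """Pool per-amplicon optical map data downsampled in proportion to copy number.

    Molecule pools are generated at coverage scaled by cn_i / max(cns); contig
    pools keep each amplicon's consensus contig (every mixture member here is
    amplified enough to assemble). Returns (pooled maps, merged graph).
    """
    rng = rng or rng_from(config.seed)
    top = max(cns)
    pool: list[LabelMap] = []
    for idx, ((truth, graph), cn) in enumerate(zip(truths, cns), start=1):
        if molecules:
            sub = replace(config, coverage=config.coverage * cn / top)
            maps = simulate_molecules(truth, graph, reference, sub, rng)
        else:
            maps = simulate_contigs(truth, graph, reference, config, rng)
        for m in maps:
            pool.append(LabelMap(f"a{idx}_{m.map_id}", m.length_bp, m.positions))
    merged = merge_graphs([g for _t, g in truths])
    return pool, merged


def unlabeled_sequence(length_bp: int, motif: str, seed) -> str:
    """Random sequence guaranteed to carry no labeling site on either strand."""
    rng = rng_from(seed)
    seq = list(toy_reference(length_bp, rng)["chr1"])
    rc = reverse_complement(motif)
    changed = True
    while changed:
        changed = False
        s = "".join(seq)
        for m in (motif, rc):
            i = s.find(m)
            while i >= 0:
                j = i + len(m) // 2
                seq[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[j]]
                changed = True
                s = "".join(seq)
                i = s.find(m, i + 1)
    return "".join(seq)


def insert_unlabeled_element(truth: ReconstructedPath, graph: BreakpointGraph,
                             reference: dict[str, str], insert_length_bp: int, seed,
                             chrom: str = "viral") -> tuple[ReconstructedPath, BreakpointGraph, dict[str, str]]:
    """Insert an unlabeled element (e.g. a viral genome) at a random junction.

    Returns the modified truth path, a graph extended with the zero-label
    segment, and the reference augmented with the insert's sequence. The
    element leaves no label of its own; its only optical-map signature is an
    inter-label gap grown by its length.
    """
    rng = rng_from(seed)
    if insert_length_bp == 0:
        return truth, graph, dict(reference)
    sid = max(graph.segments) + 1
    ref = dict(reference)
    motif = MOTIFS["BspQI"]
    ref[chrom] = unlabeled_sequence(insert_length_bp, motif, rng)
    seg = GraphSegment(sid, chrom, 1, insert_length_bp, max(s.copy_number for s in graph.segments.values()))
    k = int(rng.integers(1, len(truth.elements))) if len(truth.elements) > 1 else 1
    elements = truth.elements[:k] + (OrientedSegment(sid, "+"),) + truth.elements[k:]
    new_truth = ReconstructedPath(elements, cyclic=truth.cyclic)
    segs = dict(graph.segments)
    segs[sid] = seg
    cn = {s.segment_id: s.copy_number for s in graph.segments.values()}
    new_graph = graph_from_path(new_truth, segs, 1.0)
    # keep the original CN scale rather than multiplicity alone
    rescaled = [
        GraphSegment(s.segment_id, s.chrom, s.start, s.end,
                     cn.get(s.segment_id, seg.copy_number))
        for s in new_graph.segments.values()
    ]
    final = BreakpointGraph(rescaled, new_graph.edges)
    return new_truth, final, ref
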