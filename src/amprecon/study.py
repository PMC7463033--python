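"""Cohort-level simulation studies.

These drivers reproduce the simulation conditions under which reconstruction
accuracy is benchmarked: cohorts of seeded rearranged amplicons (cyclic and
linear, 0.3-2.8 Mbp), graphs corrupted with false edges, heterogeneous
three-amplicon mixtures, de novo circular ecDNA cohorts, and amplicons
carrying a large (~280 kbp) duplicated block. Every cohort flows end to end
through digestion, alignment, scaffolding, imputation and pathfinding, and is
scored with the LCS length (bp) measure.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .align import ScoringParams
from .evaluate import duplication_resolved, mean_f1, score_reconstructions
from .om_io import digest_graph_segments
from .pipeline import reconstruct
from .simulate import (
    SimConfig,
    make_mixture,
    inject_false_edges,
    simulate_amplicon_structure,
    simulate_contigs,
    simulate_related_structures,
    toy_reference,
)

REFERENCE_BP = 3_600_000
CYCLIC_FRACTION = 0.44  # cyclic share of the benchmark structures (37/85)


def _child_seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_single_amplicon_cohort(seed: int, n_amplicons: int = 20,
                               false_edge_fraction: float = 0.0,
                               config: SimConfig | None = None,
                               params: ScoringParams | None = None,
                               metric: str = "length_bp") -> dict:
    """Reconstruction accuracy over a cohort of single rearranged amplicons.

    Each case draws a structure (3-20 segments coupled to its 0.3-2.8 Mbp
    length), builds its breakpoint graph (optionally corrupted with false
    discordant edges), simulates one noisy spanning consensus contig and runs
    the full pipeline.
    """
    base = config or SimConfig()
    results = []
    for i, rng in enumerate(_child_seeds(seed, n_amplicons)):
        cfg = replace(base, cyclic=(i < round(CYCLIC_FRACTION * n_amplicons)))
        ref = toy_reference(REFERENCE_BP, rng)
        truth, graph = simulate_amplicon_structure(cfg, ref, rng)
        run_graph = (
            inject_false_edges(graph, false_edge_fraction, rng)
            if false_edge_fraction > 0 else graph
        )
        segmaps = digest_graph_segments(run_graph, ref, cfg.motif)
        contigs = simulate_contigs(truth, graph, ref, cfg, rng)
        recon = reconstruct(run_graph, contigs, segmaps, params)
        results.append(score_reconstructions(truth, recon.paths, metric, run_graph))
    return {"mean_f1": mean_f1(results), "results": results, "n": n_amplicons}


def run_mixture_cohort(seed: int, n_samples: int = 10,
                       cns: tuple[int, int, int] = (20, 15, 10),
                       config: SimConfig | None = None,
                       params: ScoringParams | None = None,
                       metric: str = "length_bp") -> dict:
    """Accuracy on pooled three-amplicon heterogeneous mixtures.

    Per sample, three related structures share one genomic region and are
    simulated at the given copy numbers; the pooled contigs are reconstructed
    against the merged breakpoint graph and each truth is scored against its
    best-LCS reconstruction.
    """
    base = config or SimConfig(total_bp_range=(800_000.0, 1_800_000.0))
    results = []
    for i, rng in enumerate(_child_seeds(seed, n_samples)):
        cfg = replace(base, cyclic=(i % 2 == 0))
        ref = toy_reference(REFERENCE_BP, rng)
        trio = simulate_related_structures(cfg, ref, cns, rng)
        pool, merged = make_mixture(trio, cns, ref, cfg, rng)
        segmaps = digest_graph_segments(merged, ref, cfg.motif)
        recon = reconstruct(merged, pool, segmaps, params)
        for truth, _graph in trio:
            results.append(score_reconstructions(truth, recon.paths, metric, merged))
    return {"mean_f1": mean_f1(results), "results": results, "n": n_samples * len(cns)}


def run_circular_cohort(seed: int, n_amplicons: int = 20,
                        config: SimConfig | None = None,
                        params: ScoringParams | None = None,
                        metric: str = "length_bp") -> dict:
    """Accuracy on de novo circular ecDNA structures (~2 Mbp, ~9 segments)."""
    base = config or SimConfig(total_bp_range=(1_600_000.0, 2_400_000.0), cyclic=True)
    results = []
    for rng in _child_seeds(seed, n_amplicons):
        n_segs = int(np.clip(rng.poisson(9), 4, 16))
        cfg = replace(base, n_segments=n_segs, cyclic=True)
        ref = toy_reference(REFERENCE_BP, rng)
        truth, graph = simulate_amplicon_structure(cfg, ref, rng)
        segmaps = digest_graph_segments(graph, ref, cfg.motif)
        contigs = simulate_contigs(truth, graph, ref, cfg, rng)
        recon = reconstruct(graph, contigs, segmaps, params)
        results.append(score_reconstructions(truth, recon.paths, metric, graph))
    return {"mean_f1": mean_f1(results), "results": results, "n": n_amplicons}


def run_duplication_cohort(seed: int, n_amplicons: int = 20,
                           duplication_block_bp: float = 280_000.0,
                           min_block_bp: float = 150_000.0,
                           config: SimConfig | None = None,
                           params: ScoringParams | None = None) -> dict:
    """Fraction of large intra-amplicon duplications resolved at multiplicity.

    Each amplicon carries a tandem-duplicated block of 1-3 segments totaling
    ~280 kbp; a duplication counts as resolved when some emitted path contains
    the block at the truth multiplicity with truth-consistent flanks. Only
    large blocks (>= ``min_block_bp``) enter the denominator, mirroring the
    focus on duplications long enough to be structurally challenging.
    """
    base = config or SimConfig(total_bp_range=(1_000_000.0, 2_000_000.0))
    n_resolved = 0
    n_total = 0
    for i, rng in enumerate(_child_seeds(seed, n_amplicons)):
        cfg = replace(base, cyclic=(i % 2 == 0))
        ref = toy_reference(REFERENCE_BP, rng)
        truth, graph = simulate_amplicon_structure(
            cfg, ref, rng, duplication_block_bp=duplication_block_bp
        )
        segmaps = digest_graph_segments(graph, ref, cfg.motif)
        contigs = simulate_contigs(truth, graph, ref, cfg, rng)
        recon = reconstruct(graph, contigs, segmaps, params)
        per_block: dict[tuple, bool] = {}
        for p in recon.paths:
            for blk, ok in duplication_resolved(truth, p).items():
                bp = sum(graph.segments[sid].length for sid, _o in blk)
                if bp < min_block_bp:
                    continue
                per_block[blk] = per_block.get(blk, False) or ok
        n_total += len(per_block)
        n_resolved += sum(per_block.values())
    frac = n_resolved / n_total if n_total else 0.0
    return {"fraction_resolved": frac, "n_resolved": n_resolved, "n_total": n_total,
            "n": n_amplicons}
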