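"""Determinism, noise statistics and graph consistency of the simulator."""

import numpy as np
import pytest

from amprecon.core import LabelMap, OrientedSegment, ReconstructedPath
from amprecon.om_io import digest_sequence
from amprecon.simulate import (
    SimConfig,
    apply_map_noise,
    graph_from_path,
    inject_false_edges,
    insert_unlabeled_element,
    make_mixture,
    simulate_amplicon_structure,
    simulate_contigs,
    simulate_molecules,
    simulate_related_structures,
    toy_reference,
    truth_sequence,
    unlabeled_sequence,
)


@pytest.fixture(scope="module")
def reference():
    return toy_reference(2_500_000, 777)


def _cfg(**kw):
    base = dict(seed=5, total_bp_range=(400_000.0, 900_000.0))
    base.update(kw)
    return SimConfig(**base)


# ---------------------------------------------------------------------------
# structures


def test_single_linear_segment_has_no_discordant_edges(reference):
    cfg = _cfg(n_segments=1, cyclic=False)
    truth, graph = simulate_amplicon_structure(cfg, reference)
    # rearrangement ops on one segment can at most flip it
    assert len({e.segment_id for e in truth.elements}) == 1
    assert all(e.edge_type == "concordant" for e in graph.edges) or not graph.edges


def test_cyclic_structure_contains_closing_edge(reference):
    cfg = _cfg(n_segments=4, cyclic=True)
    truth, graph = simulate_amplicon_structure(cfg, reference)
    assert truth.cyclic
    first, last = truth.elements[0], truth.elements[-1]
    closing = [e for e in graph.edges
               if {e.seg_a, e.seg_b} >= {first.segment_id, last.segment_id}
               or e.seg_a == e.seg_b]
    assert len(graph.edges) >= len(truth.elements)


def test_graph_cn_equals_multiplicity_times_copy_number(reference, rng):
    cfg = _cfg(copy_number=20)
    truth, graph = simulate_amplicon_structure(cfg, reference, rng)
    mult = {}
    for e in truth.elements:
        mult[e.segment_id] = mult.get(e.segment_id, 0) + 1
    for sid, seg in graph.segments.items():
        assert seg.copy_number == mult[sid] * 20


def test_every_truth_junction_is_a_graph_edge(reference, rng):
    cfg = _cfg(n_segments=8, cyclic=True)
    truth, graph = simulate_amplicon_structure(cfg, reference, rng)
    adj = graph.adjacency()
    pairs = list(zip(truth.elements, truth.elements[1:])) + [
        (truth.elements[-1], truth.elements[0])
    ]
    for a, b in pairs:
        exit_node = (a.segment_id, "right" if a.orientation == "+" else "left")
        entry = (b.segment_id, "left" if b.orientation == "+" else "right")
        assert entry in [(s, side) for s, side, _e in adj.get(exit_node, [])]


def test_structure_infeasible_for_reference_raises():
    ref = toy_reference(100_000, 1)
    with pytest.raises(ValueError):
        simulate_amplicon_structure(_cfg(total_bp_range=(500_000.0, 500_001.0)), ref)


def test_forced_duplication_block_present(reference, rng):
    cfg = _cfg(total_bp_range=(1_200_000.0, 1_600_000.0))
    truth, graph = simulate_amplicon_structure(cfg, reference, rng,
                                               duplication_block_bp=280_000)
    from amprecon.evaluate import find_duplicated_blocks

    blocks = find_duplicated_blocks(truth)
    big = [b for b, _m in blocks
           if sum(graph.segments[s].length for s, _o in b) >= 150_000]
    assert big


# ---------------------------------------------------------------------------
# determinism


def test_full_determinism_under_fixed_seed(reference):
    def run():
        rng = np.random.default_rng(99)
        cfg = _cfg(seed=99)
        truth, graph = simulate_amplicon_structure(cfg, reference, rng)
        contigs = simulate_contigs(truth, graph, reference, cfg, rng)
        return truth, contigs

    t1, c1 = run()
    t2, c2 = run()
    assert t1.elements == t2.elements
    for a, b in zip(c1, c2):
        np.testing.assert_array_equal(a.positions, b.positions)
        assert a.length_bp == b.length_bp


# ---------------------------------------------------------------------------
# noise model


def test_zero_noise_contig_equals_truth_digest(reference, rng):
    cfg = _cfg(label_miss_rate=0.0, sizing_sd_fraction=0.0, collapse=False,
               false_label_rate=0.0, flank_bp=0.0)
    truth, graph = simulate_amplicon_structure(cfg, reference, rng)
    contigs = simulate_contigs(truth, graph, reference, cfg, rng)
    assert len(contigs) == 1
    expected = digest_sequence(truth_sequence(truth, graph, reference), cfg.motif)
    np.testing.assert_allclose(contigs[0].positions, expected.positions)


def test_total_miss_rate_removes_all_labels(rng):
    cfg = _cfg(label_miss_rate=1.0, collapse=False, false_label_rate=0.0)
    lmap = LabelMap("m", 100_000.0, np.arange(1, 11) * 9_000.0)
    noisy = apply_map_noise(lmap, cfg, rng)
    assert noisy.n_labels == 0


def test_observed_miss_fraction_within_binomial_error(rng):
    rate = 0.08
    cfg = _cfg(label_miss_rate=rate, collapse=False, sizing_sd_fraction=0.0,
               false_label_rate=0.0)
    n = 10_000
    lmap = LabelMap("m", float(9_000 * (n + 1)), np.arange(1, n + 1) * 9_000.0)
    noisy = apply_map_noise(lmap, cfg, rng)
    missed = n - noisy.n_labels
    sigma = np.sqrt(n * rate * (1 - rate))
    assert abs(missed - n * rate) < 3 * sigma


def test_close_label_pairs_collapse_to_single_label(rng):
    cfg = _cfg(label_miss_rate=0.0, sizing_sd_fraction=0.0, false_label_rate=0.0)
    # pairs 200 bp apart merge with probability 1-(0.1)^2 = 0.99
    pos = np.sort(np.concatenate([np.arange(1, 201) * 50_000.0,
                                  np.arange(1, 201) * 50_000.0 + 200.0]))
    noisy = apply_map_noise(LabelMap("m", 1.2e7, pos), cfg, rng)
    assert noisy.n_labels < 250  # nearly all 200 pairs merged


def test_sizing_error_preserves_label_order(rng):
    cfg = _cfg(label_miss_rate=0.0, collapse=False, false_label_rate=0.0,
               sizing_sd_fraction=0.1)
    lmap = LabelMap("m", 500_000.0, np.arange(1, 50) * 10_000.0)
    noisy = apply_map_noise(lmap, cfg, rng)
    assert np.all(np.diff(noisy.positions) > 0)


def test_contig_break_rate_fragments_contig(reference, rng):
    cfg = _cfg(contig_break_rate=5.0)  # ~5 breaks per Mbp
    truth, graph = simulate_amplicon_structure(cfg, reference, rng)
    contigs = simulate_contigs(truth, graph, reference, cfg, rng)
    assert len(contigs) > 1
    total = sum(c.length_bp for c in contigs)
    assert total == pytest.approx(
        sum(graph.segments[e.segment_id].length for e in truth.elements)
        * (1 if truth.cyclic else 1)  # flanks included below
        + (0 if truth.cyclic else 2 * cfg.flank_bp),
        rel=0.15,
    )


# ---------------------------------------------------------------------------
# molecules


def test_molecule_count_tracks_coverage(reference, rng):
    cfg = _cfg(coverage=40.0, molecule_length_sigma=1e-9,
               molecule_length_median=100_000.0)
    truth, graph = simulate_amplicon_structure(cfg, reference, rng)
    mols = simulate_molecules(truth, graph, reference, cfg, rng)
    total = sum(graph.segments[e.segment_id].length for e in truth.elements)
    expected = 40.0 * total / 100_000.0
    assert len(mols) == pytest.approx(expected, rel=0.05)


def test_zero_coverage_gives_no_molecules(reference, rng):
    cfg = _cfg(coverage=0.0)
    truth, graph = simulate_amplicon_structure(cfg, reference, rng)
    assert simulate_molecules(truth, graph, reference, cfg, rng) == []


def test_junction_spanning_molecule_carries_both_flanks(reference):
    cfg = _cfg(n_segments=2, label_miss_rate=0.0, collapse=False,
               sizing_sd_fraction=0.0, false_label_rate=0.0,
               molecule_length_median=300_000.0, molecule_length_sigma=1e-9,
               coverage=60.0)
    rng = np.random.default_rng(4)
    truth, graph = simulate_amplicon_structure(cfg, reference, rng)
    digest = digest_sequence(truth_sequence(truth, graph, reference), cfg.motif)
    mols = simulate_molecules(truth, graph, reference, cfg, rng)
    len1 = graph.segments[truth.elements[0].segment_id].length
    spanning = [m for m in mols if m.n_labels > 6]
    assert spanning  # long molecules relative to segments must span the junction


# ---------------------------------------------------------------------------
# false edges, mixtures, unlabeled inserts


def test_inject_zero_fraction_is_identity(toy_graph):
    out = inject_false_edges(toy_graph, 0.0, 1)
    assert out == toy_graph


def test_inject_full_fraction_doubles_edges(toy_graph):
    out = inject_false_edges(toy_graph, 1.0, 1)
    assert len(out.edges) == 2 * len(toy_graph.edges)
    new = [e for e in out.edges if e not in toy_graph.edges]
    assert all(e.edge_type == "discordant" for e in new)


def test_injected_edges_disjoint_from_true_edges(toy_graph, rng):
    out = inject_false_edges(toy_graph, 1.0, rng)
    true_keys = {e.key() for e in toy_graph.edges}
    injected = [e for e in out.edges][len(toy_graph.edges):]
    assert all(e.key() not in true_keys for e in injected)


def test_inject_more_edges_than_pairs_raises():
    from amprecon.core import BreakpointGraph, GraphSegment

    g = BreakpointGraph([GraphSegment(1, "chr1", 1, 1000, 1)])
    g.add_edge(__import__("amprecon.core", fromlist=["GraphEdge"]).GraphEdge(
        1, "left", 1, "right", "concordant"))
    with pytest.raises(ValueError):
        inject_false_edges(g, 10.0, 1)


def test_mixture_molecule_counts_scale_with_cn(reference):
    rng = np.random.default_rng(21)
    cfg = _cfg(total_bp_range=(600_000.0, 900_000.0), coverage=10.0,
               molecule_length_sigma=1e-9, molecule_length_median=100_000.0)
    trio = simulate_related_structures(cfg, reference, (20, 2, 2), rng)
    pool, merged = make_mixture(trio, (20, 2, 2), reference, cfg, rng, molecules=True)
    counts = {}
    for m in pool:
        counts[m.map_id.split("_")[0]] = counts.get(m.map_id.split("_")[0], 0) + 1
    totals = [sum(g.segments[e.segment_id].length for e in t.elements) for t, g in trio]
    # per-bp molecule density should follow the 10:1:1 copy-number ratio
    dens = [counts[f"a{i+1}"] / totals[i] for i in range(3)]
    assert dens[0] / dens[1] == pytest.approx(10.0, rel=0.35)
    assert dens[0] / dens[2] == pytest.approx(10.0, rel=0.35)


def test_mixture_pool_size_is_sum_of_parts(reference):
    rng = np.random.default_rng(22)
    cfg = _cfg(total_bp_range=(600_000.0, 900_000.0))
    trio = simulate_related_structures(cfg, reference, (20, 15, 10), rng)
    pool, merged = make_mixture(trio, (20, 15, 10), reference, cfg, rng)
    assert len(pool) == 3  # one spanning contig per amplicon
    assert set(merged.segments) == set().union(*[g.segments for _t, g in trio])


def test_unlabeled_sequence_has_no_sites():
    seq = unlabeled_sequence(7_900, "GCTCTTC", 3)
    assert digest_sequence(seq, "GCTCTTC").n_labels == 0
    assert len(seq) == 7_900


def test_insert_zero_length_is_identity(reference, rng):
    cfg = _cfg()
    truth, graph = simulate_amplicon_structure(cfg, reference, rng)
    t2, g2, ref2 = insert_unlabeled_element(truth, graph, reference, 0, 1)
    assert t2.elements == truth.elements


def test_insert_grows_interlabel_gap_by_insert_length(reference):
    rng = np.random.default_rng(8)
    cfg = _cfg(n_segments=3)
    truth, graph = simulate_amplicon_structure(cfg, reference, rng)
    t2, g2, ref2 = insert_unlabeled_element(truth, graph, reference, 7_900, 9)
    assert len(t2.elements) == len(truth.elements) + 1
    d_before = digest_sequence(truth_sequence(truth, graph, reference), cfg.motif)
    d_after = digest_sequence(truth_sequence(t2, g2, ref2), cfg.motif)
    assert d_after.length_bp == pytest.approx(d_before.length_bp + 7_900)
    assert d_after.n_labels == d_before.n_labels
    # sequence-level oracle: digest of modified truth equals digest of the
    # literally modified sequence (same construction path, so exact)
    gaps_before = np.diff(d_before.positions)
    gaps_after = np.diff(d_after.positions)
    grown = np.flatnonzero(~np.isin(np.round(gaps_after, 3), np.round(gaps_before, 3)))
    assert any(gaps_after[i] - 7_900 in np.round(gaps_before, 6) for i in grown)
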