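"""Scoring model, banded DP alignment and E-value calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amprecon.align import (
    CollapseMap,
    EValueModel,
    ScoringParams,
    align,
    calibrate_evalue,
    fallback_cutoff,
    filter_alignments,
    iterative_align,
    merge_probability,
    score_cutoff,
    score_matching_region,
)
from amprecon.core import LabelMap, SegmentAlignment

from conftest import make_label_map


def no_trim_params(**kw) -> ScoringParams:
    return ScoringParams(end_trim_min=-math.inf, **kw)


# ---------------------------------------------------------------------------
# merge probability and collapse map


def test_merge_probability_boundary_values(params):
    assert merge_probability(0.0, params) == 1.0
    assert merge_probability(params.w, params) == 0.0
    assert merge_probability(3 * params.w, params) == 0.0
    p = ScoringParams(t=2.0)
    assert merge_probability(p.w / 2, p) == pytest.approx(0.75)


def test_merge_probability_monotone_non_increasing(params):
    deltas = np.linspace(0, 2 * params.w, 50)
    vals = merge_probability(deltas, params)
    assert np.all(np.diff(vals) <= 1e-12)


def test_merge_probability_rejects_negative(params):
    with pytest.raises(ValueError):
        merge_probability(-1.0, params)


def naive_collapse_map(x, p, q, params):
    """Direct double-loop evaluation of the expected-observable sum."""
    if q <= p + 1 or x[q] - x[p] < params.eta:
        return 0.0
    total = 0.0
    for k in range(p + 1, q):
        left = x[k] - x[k - 1]
        right = x[k + 1] - x[k] if k + 1 < len(x) else math.inf
        obs_l = 1.0 if math.isinf(left) else 1.0 - merge_probability(left, params)
        obs_r = 1.0 if math.isinf(right) else 1.0 - merge_probability(right, params)
        total += obs_l * obs_r
    return total


def test_collapse_map_trivial_cases(params):
    from amprecon.align import build_collapse_map

    seg = make_label_map([1000.0, 9000.0, 17000.0])
    M = build_collapse_map(seg, params)
    assert M(0, 1) == 0.0                      # adjacent labels: empty sum
    assert M(0, 2) == pytest.approx(1.0)       # well-separated interior label


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 10**6))
def test_collapse_map_matches_naive_double_loop(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 15))
    x = np.cumsum(rng.uniform(200, 12_000, n))
    params = ScoringParams()
    seg = make_label_map(x)
    M = CollapseMap(seg, params)
    for p in range(n):
        for q in range(p + 1, n):
            assert M(p, q) == pytest.approx(naive_collapse_map(x, p, q, params), abs=1e-9)
            assert 0.0 <= M(p, q) <= q - p - 1 + 1e-9


# ---------------------------------------------------------------------------
# matching-region score


def test_score_perfect_step_is_2c(params):
    b = np.array([1_000.0, 11_000.0])
    x = np.array([1_000.0, 11_000.0])
    M = CollapseMap(make_label_map(x), params)
    s = score_matching_region(b, x, 0, 1, 0, 1, M, params)
    assert s.total == pytest.approx(2 * params.c)
    assert (s.f_n, s.f_p, s.delta) == (0.0, 0.0, 0.0)


def test_score_one_skipped_contig_label_costs_c(params):
    b = np.array([1_000.0, 5_000.0, 11_000.0])
    x = np.array([1_000.0, 11_000.0])
    M = CollapseMap(make_label_map(x), params)
    s = score_matching_region(b, x, 0, 2, 0, 1, M, params)
    assert s.total == pytest.approx(params.c)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10**6))
def test_score_matches_independent_formula(seed):
    rng = np.random.default_rng(seed)
    params = ScoringParams()
    b = np.cumsum(rng.uniform(500, 15_000, 10))
    x = np.cumsum(rng.uniform(500, 15_000, 8))
    M = CollapseMap(make_label_map(x), params)
    i, j = sorted(rng.choice(10, 2, replace=False))
    p, q = sorted(rng.choice(8, 2, replace=False))
    s = score_matching_region(b, x, i, j, p, q, M, params)
    expected = (2 * params.c
                - params.c * (j - i - 1)
                - params.c * naive_collapse_map(x, p, q, params)
                - abs((b[j] - b[i]) - (x[q] - x[p])) ** params.k)
    assert s.total == pytest.approx(expected)


def test_score_index_order_violation_raises(params):
    b = x = np.array([500.0, 1500.0])
    M = CollapseMap(make_label_map(x), params)
    with pytest.raises(ValueError):
        score_matching_region(b, x, 1, 0, 0, 1, M, params)


# ---------------------------------------------------------------------------
# banded DP


def _sparse_segment(rng, n, lo=4_000, hi=15_000, map_id="seg"):
    return make_label_map(np.cumsum(rng.uniform(lo, hi, n)) + 500.0, map_id=map_id)


def test_noiseless_self_alignment_is_perfect(rng, params):
    seg = _sparse_segment(rng, 12)
    contig = make_label_map(seg.positions.copy(), map_id="ctg")
    a = align(seg, contig, "semi-global", params)
    assert a is not None
    assert a.score == pytest.approx(2 * params.c * (seg.n_labels - 1))
    assert a.pairs == tuple((i, i) for i in range(seg.n_labels))


def exhaustive_dp(b, x, params):
    """Unbanded quadratic DP oracle (all predecessors, same base case)."""
    m, n = len(b), len(x)
    M = CollapseMap(make_label_map(np.asarray(x, float)), params)
    S = np.full((m, n), -np.inf)
    S[:, 0] = 0.0
    for j in range(1, m):
        for q in range(1, n):
            for i in range(j):
                for p in range(q):
                    cand = S[i, p] + score_matching_region(b, x, i, j, p, q, M, params).total
                    if cand > S[j, q]:
                        S[j, q] = cand
    return S[:, 1:].max() if n > 1 else -np.inf


@settings(max_examples=15, deadline=None)
@given(st.integers(0, 10**6))
def test_banded_dp_equals_exhaustive_on_small_instances(seed):
    rng = np.random.default_rng(seed)
    params = no_trim_params(d=12, min_labels=2)
    n = int(rng.integers(4, 9))
    seg = _sparse_segment(rng, n)
    # contig: the segment plus noise, one deleted label, flanking decoys
    pos = seg.positions.copy() + rng.normal(0, 150, n)
    drop = int(rng.integers(1, n - 1))
    pos = np.delete(pos, drop)
    pos = np.sort(np.concatenate([pos, pos[-1] + np.cumsum(rng.uniform(5_000, 9_000, 3))]))
    contig = make_label_map(pos, map_id="ctg")
    best = align(seg, contig, "semi-global", params)
    oracle = exhaustive_dp(contig.positions, seg.positions, params)
    oracle_rev = exhaustive_dp(contig.positions, seg.reversed().positions, params)
    assert best is not None
    assert best.score == pytest.approx(max(oracle, oracle_rev), rel=1e-9)


def test_deleted_interior_label_is_skipped(rng, params):
    seg = _sparse_segment(rng, 12)
    pos = np.delete(seg.positions.copy(), 5)
    contig = make_label_map(pos, map_id="ctg")
    a = align(seg, contig, "semi-global", no_trim_params())
    seg_idx = {q for _j, q in a.pairs}
    assert 5 not in seg_idx
    assert len(a.pairs) == 11


def test_alignment_invariant_to_global_shift_and_reversal(rng, params):
    seg = _sparse_segment(rng, 10)
    contig = make_label_map(np.sort(np.concatenate(
        [seg.positions + rng.normal(0, 100, 10), [seg.positions[-1] + 8_000]])), map_id="c")
    base = align(seg, contig, "semi-global", params).score
    shift_seg = LabelMap("seg", seg.length_bp + 5_000, seg.positions + 5_000)
    shift_ctg = LabelMap("c", contig.length_bp + 5_000, contig.positions + 5_000)
    assert align(shift_seg, shift_ctg, "semi-global", params).score == pytest.approx(base)
    assert align(seg.reversed(), contig.reversed(), "semi-global", params).score == pytest.approx(base)


def test_reverse_orientation_detected(rng, params):
    seg = _sparse_segment(rng, 11)
    contig = make_label_map(seg.reversed().positions, map_id="ctg")
    a = align(seg, contig, "semi-global", params)
    assert a.orientation == "-"
    assert a.score == pytest.approx(2 * params.c * 10)


def test_segment_below_mode_minimum_returns_none(rng, params):
    seg = _sparse_segment(rng, 5)  # below the 10-label floor
    contig = make_label_map(seg.positions.copy(), map_id="ctg")
    assert align(seg, contig, "semi-global", params) is None
    # but fitting mode only needs two endpoint labels
    assert align(seg, contig, "fitting", params) is not None


def test_used_pair_masking_yields_different_alignment(rng, params):
    seg = _sparse_segment(rng, 12)
    gap = seg.positions[-1] + 9_000
    two_copies = np.concatenate([seg.positions, seg.positions + gap])
    contig = make_label_map(two_copies, map_id="ctg")
    first = align(seg, contig, "semi-global", params)
    second = align(seg, contig, "semi-global", params, U=set(first.pairs))
    assert second is not None
    assert not set(second.pairs) & set(first.pairs)
    assert second.score == pytest.approx(first.score)


def test_iterative_align_finds_both_copies(rng, params):
    seg = _sparse_segment(rng, 12)
    gap = seg.positions[-1] + 9_000
    contig = make_label_map(np.concatenate([seg.positions, seg.positions + gap]), map_id="c")
    alns = iterative_align(seg, contig, "semi-global", params)
    assert len(alns) == 2
    loci = sorted(a.contig_label_range for a in alns)
    assert loci[0][1] < loci[1][0]


def test_iterative_align_no_copy_gives_empty(rng, params):
    seg = _sparse_segment(rng, 12)
    decoy = make_label_map(np.cumsum(rng.uniform(2_000, 20_000, 40)), map_id="c")
    assert iterative_align(seg, decoy, "semi-global", params) == []


def test_iterative_align_capped_at_twelve(rng, params):
    seg = _sparse_segment(rng, 12)
    unit = seg.positions[-1] + 9_000
    tandem = np.concatenate([seg.positions + i * unit for i in range(15)])
    contig = make_label_map(tandem, map_id="c")
    alns = iterative_align(seg, contig, "semi-global", params)
    assert len(alns) == params.max_alignments_per_pair == 12


def test_fitting_mode_anchors_both_ends(rng, params):
    seg = _sparse_segment(rng, 6)
    contig = make_label_map(seg.positions.copy(), map_id="c")
    a = align(seg, contig, "fitting", params)
    assert a.pairs[0] == (0, 0)
    assert a.pairs[-1] == (seg.n_labels - 1, seg.n_labels - 1)


# ---------------------------------------------------------------------------
# significance


def test_fallback_cutoff_accounts_for_collapse(params):
    sparse = make_label_map(np.arange(1, 11) * 9_000.0)
    dense = make_label_map(np.arange(1, 11) * 800.0)
    assert fallback_cutoff(params, 10, sparse) == pytest.approx(
        params.fallback_cutoff_fraction * 2 * params.c * 9)
    assert fallback_cutoff(params, 10, dense) < fallback_cutoff(params, 10, sparse)


def test_calibrate_exact_linear_data_recovers_parameters():
    K, lam, m, n_r = 3e-7, 1.5e-3, 5_000, 30
    ranks = np.arange(1, 201, dtype=float)
    scores = (math.log(K * m * n_r) - np.log(ranks)) / lam
    planted_true = np.full(25, scores.max() + 1e5)
    model = calibrate_evalue(np.concatenate([planted_true, scores]), m, n_r)
    assert not model.degenerate
    assert model.lam == pytest.approx(lam, rel=1e-6)
    assert model.K == pytest.approx(K, rel=1e-6)


def test_calibrate_equal_scores_is_degenerate():
    model = calibrate_evalue(np.full(100, 1234.0), 1000, 10)
    assert model.degenerate


def test_calibrate_too_few_scores_is_degenerate():
    model = calibrate_evalue(np.arange(20, dtype=float), 1000, 10)
    assert model.degenerate


def test_lambda_recovery_on_exponential_tail_nulls():
    """Mean fitted slope over replicate 200-contig samples within 15% of truth.

    A single 200-contig draw leaves ~30 tail points, so individual fits carry
    ~20% sampling spread; the estimator's central tendency is what the model
    needs to be right.
    """
    lam = 2e-3
    fits = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        null = 5_000.0 + rng.exponential(1 / lam, size=200)
        planted_true = np.full(25, null.max() + 1e5)
        model = calibrate_evalue(np.concatenate([planted_true, null]), 1000, 20)
        assert not model.degenerate
        fits.append(model.lam)
    assert np.mean(fits) == pytest.approx(lam, rel=0.15)


def test_score_cutoff_monotone_and_inverts():
    model = EValueModel(K=2e-6, lam=1.2e-3, m=4_000, n_r=25)
    s4 = score_cutoff(model, 1e-4)
    s6 = score_cutoff(model, 1e-6)
    assert s6 > s4
    for p in (1e-4, 1e-6, 1e-9):
        s = score_cutoff(model, p)
        assert 1 - math.exp(-model.evalue(s)) == pytest.approx(p, abs=1e-9)


def test_score_cutoff_unit_case():
    model = EValueModel(K=1.0, lam=1.0, m=1, n_r=1)
    p = 1 - math.exp(-1.0)
    assert score_cutoff(model, p) == pytest.approx(0.0, abs=1e-12)


def test_score_cutoff_rejects_bad_p():
    model = EValueModel(K=1.0, lam=1.0, m=1, n_r=1)
    for p in (0.0, 1.0, -0.5, 2.0):
        with pytest.raises(ValueError):
            score_cutoff(model, p)


def _aln_with_steps(steps):
    pairs = tuple((i, i) for i in range(len(steps) + 1))
    return SegmentAlignment("1", "c", "+", pairs, float(sum(steps)), step_scores=tuple(steps))


def test_filter_alignments_matches_direct_oracle(rng):
    params = ScoringParams()
    mean_min = median_min = 1.55 * params.c
    alns = []
    for _ in range(40):
        steps = rng.uniform(0, 2 * params.c, size=int(rng.integers(2, 12)))
        alns.append(_aln_with_steps(steps))
    kept = filter_alignments(alns, params)
    expected = [a for a in alns
                if np.mean(a.step_scores) >= mean_min and np.median(a.step_scores) >= median_min]
    assert kept == expected


def test_filter_keeps_perfect_and_drops_weak(params):
    perfect = _aln_with_steps([2 * params.c] * 8)
    weak = _aln_with_steps([0.5 * params.c] * 8)
    assert filter_alignments([perfect, weak], params) == [perfect]
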