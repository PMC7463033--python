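"""Segment-to-contig optical map alignment by banded dynamic programming.

A digested graph segment (label list ``x``) is aligned against an optical map
contig (label list ``b``). The score of extending an alignment from pair
(i, p) to pair (j, q) combines four terms::

    f_n   = c * (j - (i + 1))       # skipped contig labels
    e_ref = M(p, q)                 # expected observable skipped segment labels
    f_p   = c * e_ref
    delta = |(b[j]-b[i]) - (x[q]-x[p])| ** k
    step  = 2c - (f_n + f_p + delta)

``M`` discounts segment labels that are unlikely to be imaged as separate
labels: two labels closer than the collapse scale ``w`` (~2 kbp) tend to merge
into one. The recurrence is banded (band width ``d`` labels on both axes), and
next-best alignments are found by masking the label pairings of prior
alignments and re-running the DP.

Alignment significance follows a BLAST-like empirical E-value model
E = K·m·n_r·exp(-λS) whose slope and scale are fit by linear regression on the
tail of best-per-contig score distributions. When too few contigs exist to
calibrate the model, a conservative fixed cutoff of 0.6·(2c·(n_r-1)) — 60% of
a perfect full-length score — stands in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .core import LabelMap, SegmentAlignment

MODES = ("semi-global", "fitting", "overlap", "detection")

DEFAULT_P_VALUES = {"semi-global": 1e-4, "fitting": 1e-4, "overlap": 1e-6, "detection": 1e-9}


@dataclass
class ScoringParams:
    """Scoring-model parameters (see docs/methods.md for the defaults' rationale)."""

    c: float = 3000.0           # missing-label score (score units)
    k: float = 1.05             # length-difference exponent
    w: float = 2000.0           # collapse length scale (bp)
    t: float = 2.0              # collapse shape exponent
    eta: float = 2000.0         # minimum span gate for the collapse map (bp)
    d: int = 6                  # band width (labels)
    max_alignments_per_pair: int = 12
    min_labels: int = 10        # 10 Irys / 12 Saphyr
    instrument: str = "irys"
    mean_step_min: float | None = None    # default 1.55·c (~78% of a perfect step)
    median_step_min: float | None = None  # default 1.55·c
    end_trim_min: float | None = None     # terminal DP steps below this are trimmed; default c
    printed_collapse_formula: bool = False  # literal (increasing) form of the merge model
    fallback_cutoff_fraction: float = 0.6
    min_hsps: int = 10
    p_values: dict = field(default_factory=lambda: dict(DEFAULT_P_VALUES))

    def __post_init__(self) -> None:
        if min(self.c, self.k, self.w, self.t) <= 0 or self.eta < 0 or self.d < 1:
            raise ValueError("invalid scoring parameters")


def saphyr_params(**overrides) -> ScoringParams:
    return replace(ScoringParams(), instrument="saphyr", min_labels=12, **overrides)


# ---------------------------------------------------------------------------
# collapse model


def merge_probability(delta_bp, params: ScoringParams):
    """Probability that two labels ``delta_bp`` apart are imaged as one."""
    delta = np.asarray(delta_bp, dtype=float)
    if np.any(delta < 0):
        raise ValueError("negative label-to-label distance")
    core = np.minimum(1.0, (delta / params.w) ** params.t)
    out = core if params.printed_collapse_formula else 1.0 - core
    return float(out) if np.isscalar(delta_bp) else out


class CollapseMap:
    """M(p, q): expected number of observable labels strictly between p and q.

    A label is observable when it merges with neither neighbor; boundary labels
    have an infinitely distant missing neighbor on the open side. The span gate
    zeroes M when x[q] - x[p] < eta.
    """

    def __init__(self, segment: LabelMap, params: ScoringParams):
        x = segment.positions
        n = x.size
        self.x = x
        self.eta = params.eta
        if n == 0:
            self._cum = np.zeros(1)
            return
        left_gap = np.full(n, np.inf)
        right_gap = np.full(n, np.inf)
        if n > 1:
            gaps = np.diff(x)
            left_gap[1:] = gaps
            right_gap[:-1] = gaps

        def observable_side(gap: np.ndarray) -> np.ndarray:
            # a missing neighbor (infinite gap) never merges, under either formula
            finite = np.where(np.isinf(gap), params.w, gap)
            return np.where(np.isinf(gap), 1.0, 1.0 - merge_probability(finite, params))

        self._obs = observable_side(left_gap) * observable_side(right_gap)
        self._cum = np.concatenate([[0.0], np.cumsum(self._obs)])

    def __call__(self, p: int, q: int) -> float:
        if q <= p + 1:
            return 0.0
        if self.x[q] - self.x[p] < self.eta:
            return 0.0
        return float(self._cum[q] - self._cum[p + 1])

    def band_matrix(self, d: int) -> np.ndarray:
        """Mband[dp-1, q] = M(q-dp, q) for dp in 1..d (inf-gated cells are 0)."""
        n = self.x.size
        out = np.zeros((d, n))
        for dp in range(1, d + 1):
            for q in range(dp, n):
                out[dp - 1, q] = self(q - dp, q)
        return out


def build_collapse_map(segment: LabelMap, params: ScoringParams | None = None) -> CollapseMap:
    """Precompute the expected-observable-label map M for one digested segment."""
    return CollapseMap(segment, params or ScoringParams())


@dataclass(frozen=True)
class ScoreBreakdown:
    f_n: float
    e_ref: float
    f_p: float
    delta: float
    total: float


def score_matching_region(b, x, i: int, j: int, p: int, q: int, M: CollapseMap,
                          params: ScoringParams) -> ScoreBreakdown:
    """Score of one matching region (the DP step from pair (i,p) to (j,q))."""
    if not (i < j and p < q):
        raise ValueError("matching region requires i < j and p < q")
    f_n = params.c * (j - (i + 1))
    e_ref = M(p, q)
    f_p = params.c * e_ref
    delta = abs((b[j] - b[i]) - (x[q] - x[p])) ** params.k
    return ScoreBreakdown(f_n, e_ref, f_p, delta, 2 * params.c - (f_n + f_p + delta))


# ---------------------------------------------------------------------------
# banded DP

NEG = -1e18


def _oriented(segment: LabelMap, orientation: str) -> LabelMap:
    return segment if orientation == "+" else segment.reversed()


def _forward_index(q: int, n: int, orientation: str) -> int:
    return q if orientation == "+" else n - 1 - q


def _run_dp(b: np.ndarray, x: np.ndarray, M: CollapseMap, params: ScoringParams, mode: str,
            masked: set[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Fill the banded score matrix S and a flat backtrack matrix.

    BT[j, q] = di * (d+1) + dp for the chosen predecessor (j-di, q-dp);
    0 marks a chain start (base case), -1 an unreachable cell.
    """
    m, n = b.size, x.size
    d = params.d
    c, k = params.c, params.k

    Mband = M.band_matrix(d)
    Xband = np.full((d, n), np.inf)
    for dp in range(1, d + 1):
        if n > dp:
            Xband[dp - 1, dp:] = x[dp:] - x[:-dp]

    S = np.full((m, n), NEG)
    BT = np.full((m, n), -1, dtype=np.int32)
    for j in range(m):
        if (j, 0) not in masked:
            S[j, 0] = 0.0
            BT[j, 0] = 0
    if mode == "overlap" and m > 0:
        for q in range(n):
            if (0, q) not in masked and S[0, q] < 0.0:
                S[0, q] = 0.0
                BT[0, q] = 0

    if n < 2 or m < 2:
        return S, BT

    shifted: dict[int, np.ndarray] = {}

    def shifts_of(row: np.ndarray) -> np.ndarray:
        sh = np.full((d, n), NEG)
        for dp in range(1, d + 1):
            sh[dp - 1, dp:] = row[:-dp]
        return sh

    shifted[0] = shifts_of(S[0])
    for j in range(1, m):
        dd = min(d, j)
        best = S[j].copy()          # keeps base-case values
        arg = BT[j].copy()
        for di in range(1, dd + 1):
            sh = shifted[j - di]
            delta = np.abs((b[j] - b[j - di]) - Xband)
            cand = sh + (2 * c - c * (di - 1)) - c * Mband - delta ** k
            a2 = cand.argmax(axis=0)
            m2 = cand[a2, np.arange(n)]
            upd = m2 > best
            best[upd] = m2[upd]
            arg[upd] = di * (d + 1) + (a2[upd] + 1)
        if masked:
            for q in range(1, n):
                if (j, q) in masked:
                    best[q] = NEG
                    arg[q] = -1
        S[j] = best
        BT[j] = arg
        shifted[j] = shifts_of(best)
        shifted.pop(j - d, None)
    return S, BT


def _backtrack(S, BT, j: int, q: int, d: int) -> list[tuple[int, int]]:
    pairs = [(j, q)]
    while BT[j, q] > 0:
        code = BT[j, q]
        di, dp = divmod(code, d + 1)
        j, q = j - di, q - dp
        pairs.append((j, q))
    return pairs[::-1]


def align(segment: LabelMap, contig: LabelMap, mode: str = "semi-global",
          params: ScoringParams | None = None,
          U: set[tuple[int, int]] | None = None) -> SegmentAlignment | None:
    """Best alignment of a segment to a contig over both orientations.

    Returns None (never raises) when the segment is too short for the mode or
    no chain of at least two label pairs exists outside the used-pair set
    ``U`` (pairs given as (contig label index, segment forward label index)).
    """
    params = params or ScoringParams()
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    n = segment.n_labels
    min_labels = 2 if mode == "fitting" else params.min_labels
    if n < min_labels or contig.n_labels < 2:
        return None
    U = U or set()
    b = contig.positions
    best: SegmentAlignment | None = None
    for orientation in ("+", "-"):
        oriented = _oriented(segment, orientation)
        x = oriented.positions
        masked = {(j, _forward_index(qf, n, orientation)) for (j, qf) in U}
        M = CollapseMap(oriented, params)
        S, BT = _run_dp(b, x, M, params, mode, masked)
        if mode == "fitting":
            j, q = b.size - 1, n - 1
        else:
            jj, qq = np.unravel_index(int(np.argmax(S[:, 1:])), S[:, 1:].shape)
            j, q = int(jj), int(qq) + 1
        if S[j, q] <= NEG / 2 or q == 0:
            continue
        chain = _backtrack(S, BT, j, q, params.d)
        if len(chain) < 2:
            continue
        steps = [
            score_matching_region(b, x, i0, j1, p0, q1, M, params).total
            for (i0, p0), (j1, q1) in zip(chain, chain[1:])
        ]
        if mode != "fitting":
            # weak terminal steps reach into neighboring structure; trim them
            trim_min = params.c if params.end_trim_min is None else params.end_trim_min
            while steps and steps[-1] < trim_min:
                steps.pop()
                chain.pop()
            while steps and steps[0] < trim_min:
                steps.pop(0)
                chain.pop(0)
            if len(chain) < 2:
                continue
        steps = tuple(steps)
        pairs = tuple((jj, _forward_index(qq, n, orientation)) for jj, qq in chain)
        aln = SegmentAlignment(
            segment_id=segment.map_id,
            contig_id=contig.map_id,
            orientation=orientation,
            pairs=pairs,
            score=float(sum(steps)),
            mode=mode,
            step_scores=steps,
            contig_start_bp=float(b[chain[0][0]]),
            contig_end_bp=float(b[chain[-1][0]]),
        )
        if best is None or aln.score > best.score:
            best = aln
    return best


def fallback_cutoff(params: ScoringParams, n_labels: int,
                    segment: LabelMap | None = None) -> float:
    """Conservative score cutoff when the E-value model is degenerate.

    The cutoff is a fixed fraction of the score a perfect full-length
    alignment could reach. When the segment's label map is given, the
    reachable label count is its expected observable count under the collapse
    model (labels imaged on top of a near neighbor can never contribute their
    base matching score), so dense segments are not held to an unreachable
    bar.
    """
    n_eff = float(max(n_labels, 1))
    if segment is not None and segment.n_labels >= 2:
        M = CollapseMap(segment, params)
        n_eff = 2.0 + M(0, segment.n_labels - 1)
    return params.fallback_cutoff_fraction * (2 * params.c * max(n_eff - 1, 1.0))


def iterative_align(segment: LabelMap, contig: LabelMap, mode: str = "semi-global",
                    params: ScoringParams | None = None,
                    cutoff: float | None = None) -> list[SegmentAlignment]:
    """All significant alignments of a segment to one contig.

    The label pairings of each emitted alignment are masked and the DP re-run,
    until the next best alignment falls below the significance cutoff or the
    per-pair cap (default 12) is reached.
    """
    params = params or ScoringParams()
    if cutoff is None:
        cutoff = fallback_cutoff(params, segment.n_labels, segment)
    out: list[SegmentAlignment] = []
    U: set[tuple[int, int]] = set()
    while len(out) < params.max_alignments_per_pair:
        aln = align(segment, contig, mode, params, U)
        if aln is None or aln.score < cutoff:
            break
        out.append(aln)
        U.update(aln.pairs)
    return out


# ---------------------------------------------------------------------------
# E-value model


@dataclass
class EValueModel:
    K: float
    lam: float
    m: int
    n_r: int
    degenerate: bool = False

    def evalue(self, score: float) -> float:
        return self.K * self.m * self.n_r * math.exp(-self.lam * score)


def calibrate_evalue(best_scores_per_contig, m: int, n_r: int,
                     params: ScoringParams | None = None,
                     drop_top: int = 25, hsp_percentile: float = 85.0) -> EValueModel:
    """Fit the empirical E-value model from best-per-contig alignment scores.

    The top ``drop_top`` scores (possible true alignments) are removed; scores
    at or above the 85th percentile of the remainder form the HSP set; each HSP
    gets empirical E-value equal to its descending rank (best = 1), and
    log(E) = log(K·m·n_r) - λS is fit by linear regression.
    """
    params = params or ScoringParams()
    scores = np.sort(np.asarray(list(best_scores_per_contig), dtype=float))[::-1]
    scores = scores[drop_top:]
    degenerate = EValueModel(1.0, 1.0, m, n_r, degenerate=True)
    if scores.size == 0:
        return degenerate
    thresh = np.percentile(scores, hsp_percentile)
    hsps = np.sort(scores[scores >= thresh])[::-1]
    if hsps.size < params.min_hsps or np.allclose(hsps, hsps[0]):
        return degenerate
    ranks = np.arange(1, hsps.size + 1, dtype=float)
    fit = stats.linregress(hsps, np.log(ranks))
    lam = -fit.slope
    if lam <= 0:
        return degenerate
    K = math.exp(fit.intercept) / (m * n_r)
    return EValueModel(K, lam, m, n_r)


def score_cutoff(model: EValueModel, p_value: float) -> float:
    """Score S* at which the chance of ≥1 random alignment scoring ≥ S* is p."""
    if not (0.0 < p_value < 1.0):
        raise ValueError("p-value must lie in (0, 1)")
    if model.degenerate:
        raise ValueError("degenerate E-value model has no score cutoff")
    E = -math.log(1.0 - p_value)
    return -math.log(E / (model.K * model.m * model.n_r)) / model.lam


def filter_alignments(alignments, params: ScoringParams | None = None):
    """Drop alignments whose mean or median per-pair step score is too low.

    Random placements that sneak over the total-score cutoff are built from
    mediocre steps throughout, while genuine alignments keep most steps near
    the perfect 2c; thresholds at ~78% of a perfect step separate the two.
    """
    params = params or ScoringParams()
    mean_min = 1.55 * params.c if params.mean_step_min is None else params.mean_step_min
    median_min = 1.55 * params.c if params.median_step_min is None else params.median_step_min
    return [
        a for a in alignments
        if a.mean_pair_score >= mean_min and a.median_pair_score >= median_min
    ]
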