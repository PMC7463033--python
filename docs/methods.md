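# Methods

This note documents the models implemented in `amprecon`, the parameters that
matter, what the simulator does and does not emulate, and the numerical and
design choices made where the design was genuinely open.

## 1. Optical map alignment

### Scoring model

A digested breakpoint-graph segment (`x`, sorted label positions in bp) is
aligned to an optical map contig (`b`) by scoring *matching regions*: the
stretch between two paired labels on each map. Extending an alignment from
pair `(i, p)` to `(j, q)` contributes

```
Score(i,j,p,q) = 2c − ( f_n + f_p + Δ )
f_n = c·(j − (i+1))          # contig labels skipped inside the region
f_p = c·M(p, q)              # expected observable segment labels skipped
Δ   = |(b[j]−b[i]) − (x[q]−x[p])|^k
```

`2c` is the base reward for pairing two labels, so a perfect full-length
alignment of an `n`-label segment scores `2c·(n−1)`. The DP is banded: only
predecessors within `d` labels on both axes are considered, giving
`O(m·n·d²)` time; backtracking starts at the global argmax (semi-global and
detection modes) or at the corner cell (fitting mode, used for imputation,
which requires only two endpoint labels). Both segment orientations are
always tried; the reverse alignment reverses the segment's gap sequence,
never the contig.

### Label collapse

Labels closer than roughly 2 kbp are frequently imaged as one spot. The merge
probability for two labels `Δ` apart is `P_merge(Δ) = 1 − min(1, (Δ/w)^t)`:
1 at Δ=0, 0 beyond the collapse scale `w`. A segment label is *observable*
when it merges with neither neighbor, and `M(p,q)` sums the observability of
the labels strictly between `p` and `q` (zero when the span is below the gate
`η`, and for adjacent labels). `M` is precomputed from cumulative sums, so
each lookup is O(1). The merge model's sign follows the physical statement
that *closer* labels merge *more* often; a flag (`printed_collapse_formula`)
selects the opposite (increasing) convention for comparison.

### Parameter defaults and rationale

| parameter | default | units | rationale |
|---|---|---|---|
| `c` | 3000 | score | sets the miss/sizing penalty ratio: at 2% per-interval sizing error the typical Δ-penalty (~200–1000) stays well below one missed label (c), while a mispairing (Δ of several kbp) exceeds the 2c base reward |
| `k` | 1.05 | — | mildly superlinear length-difference scaling: tolerant of proportional sizing noise, steeply punitive for multi-kbp mismatches |
| `w` | 2000 | bp | the ~2 kbp collapse scale of the imaging process |
| `t` | 2.0 | — | quadratic decay of the merge probability with distance |
| `η` | 2000 | bp | spans shorter than the collapse scale carry no observable-label expectation |
| `d` | 6 | labels | band width; larger than any plausible run of consecutive missed labels |
| min labels | 10 (Irys) / 12 (Saphyr) | — | segments below this cannot be placed confidently and are recovered by imputation instead |

`c` and `k` were chosen by a coarse grid search on the in-repo simulator
(`scripts/calibrate_scoring.py`): a parameter set is good when known-true
placements score far above the significance cutoff, shuffled decoys stay
below it, and end-to-end cohort F1 is maximal. The grid is deliberately
coarse; accuracy is flat over a broad region around the defaults.

### Significance

Following the BLAST logic, the best score of a segment against each contig
forms an empirical null once the top 25 values (possible true alignments) are
removed; scores at or above the 85th percentile of the remainder are the
high-scoring segment pairs (HSPs). Assigning each HSP the E-value equal to
its descending rank and regressing `log E = log(K·m·n_r) − λS` yields `K` and
`λ`; the score cutoff for significance level `P` is
`S* = −log(−log(1−P)/(K·m·n_r))/λ`. With fewer than 10 HSPs (or a
non-positive slope) the model is degenerate and a fixed conservative cutoff
applies: 60% of the best attainable score, `0.6·2c·(n_eff−1)`, where `n_eff`
is the segment's *expected observable* label count `2 + M(0, n−1)`. Using the
observable count rather than the raw count keeps densely labeled segments —
whose collapsed labels can never earn their base reward — from being held to
an unreachable bar. Desk-scale runs (one to a few contigs) always use the
fallback; calibration is exercised directly in the test suite on synthetic
exponential-tailed nulls.

Two further filters remove residual spurious placements:

* **Step-score filter.** True alignments keep most steps near the perfect
  `2c`; chance placements that clear the total-score bar are built from
  mediocre steps throughout. Alignments whose mean or median per-step score
  falls below `1.55·c` (~78% of perfect) are dropped. On simulated data the
  two populations separate cleanly (true medians ≥ 0.95·2c, spurious ≤
  0.78·2c).
* **End trimming.** A marginal terminal DP step (score < `c`) is trimmed:
  such steps tend to annex the first label of the *next* segment on the
  contig, manufacturing a forbidden overlap with the adjacent anchor.

## 2. Scaffolding and imputation

Alignments on one contig, ordered by coordinate, form a DAG whose allowed
edges connect pairs with at most one shared contig label and whose forbidden
edges mark larger overlaps. Maximum-weight source-to-sink paths (weight =
summed graph-segment bp, ties retained) are the scaffolds.

For each consecutive anchor pair on a scaffold with gap below 400 kbp, the
expected interior length is the label-to-label contig distance minus the
anchors' unaligned tails (both measured on in-silico digests, excluding the
anchoring labels). Candidate graph paths between the source's exit node and
the destination's entry node are enumerated by DFS under five constraints:
per-segment multiplicity ≤ graph CN; completed length within
`min(25000, 10000·L_p)` of the expected gap (and growth capped by the same
bound); at most 2^10 candidates (BFS retry with 2^16, else the junction stays
unimputed); and no immediate cycles through segments shorter than 100 bp.
Each candidate becomes a *compound map* — the source anchor label, the
concatenated candidate digests (end-to-start, zero inserted gap, since
breakpoint edges are direct adjacencies), and the destination anchor label —
and is scored by fitting alignment against the contig window between the
anchors. The baseline is the same fitting score for the empty candidate (the
two anchor labels adjacent); only a candidate that beats it is spliced in.
This is how segments too sparsely labeled to align — including completely
unlabeled elements such as an integrated viral genome, whose only signature
is a grown inter-label gap — enter the reconstruction.

When no candidate is accepted but the gap clearly contains unexplained
structure (expected interior above the 25 kbp slack cap), the scaffold path
is split at that junction rather than asserting an unsupported adjacency.
Unaligned contig regions of 20–500 labels spanning 200 kbp–5 Mbp on contigs
that carry at least one graph alignment are reported for detection-mode
search against the reference, so unannotated segments can be added to the
graph.

## 3. Pathfinding

Because graph segments contain no interior breakpoints, the same segment
aligned at the ends of two contigs licenses a link between their scaffolds;
all endpoint sub-path overlaps are searched in both assembly directions of
each contig. Merging is deliberately conservative: a scaffold path that
already returns to its own start is a complete cyclic candidate and is never
extended, and a merge is performed only when both physical endpoints have
exactly one partner. An ambiguous junction — typical when heterogeneous
amplicon variants share an endpoint segment — leaves every branch as a
separate candidate instead of fabricating a chimera that would later absorb
the true paths in the greedy uniqueness filter.

Candidates are vetted by the copy-number ratio check: for each segment `n`
with path multiplicity `n_p` and each realized level `0 < c < n_p` with
`m_g = max{ i_g : i_p = c }`, require `n_p ≤ max(c, n_g/m_g) + 1` (the ratio
compared as a real number, one copy of slack). A candidate failing the check
is replaced by its maximal contiguous passing windows — the search space is
all endpoint-anchored subpaths, and reference flanks that reuse amplicon
segments would otherwise disqualify whole paths. Surviving candidates are
sorted by total alignment score (ties by bp length) and greedily kept unless
some rotation of the candidate, or of its orientation-reversed form, is a
contiguous substring of an already-kept path ("subsequence" is read as
contiguous, matching the longest-common-substring machinery; a flag selects
non-contiguous semantics). A path is cyclic when it returns to its starting
element(s) with more than two nodes; singletons and two-element repeats
(tandem duplications) stay linear. Output goes to the cycles dialect with
`0+` sentinels marking linear endpoints.

Split-molecule junction clustering (for chromosomal integration points)
single-links junctions whose inside- and outside-amplicon coordinates both
agree within 25 kbp and reports clusters of at least 10 molecules with median
coordinates.

## 4. Simulator

The generator emulates the inputs the pipeline consumes:

* **Reference**: i.i.d. random bases, which carry the 7-mer motif at ~1 per
  8.2 kbp on two strands — close to the real-genome density of Nt.BspQI.
* **Structures**: a window (0.3–2.8 Mbp) is partitioned into segments whose
  count tracks length (~120 kbp per segment, clipped to 3–20) so the median
  segment matches the ~100 kbp typical of real amplicon graphs; the order is
  then shuffled by inversions, duplications and translocations (~1 op per 3
  segments). The implied graph carries CN = path multiplicity × amplicon copy
  number, junction edges with multiplicities, and all reference adjacencies
  as concordant edges.
* **Consensus contigs**: the rearranged sequence is digested and subjected to
  the three dominant OM error modes — per-label Bernoulli miss (default 5%),
  collapse by the same merge model used in scoring (a merged pair keeps the
  position of one randomly chosen member, so downstream matching-region
  lengths telescope consistently), spurious labels (0.5 per 100 kbp), and
  per-interval Gaussian sizing error (2% of interval length, order-
  preserving). Cyclic structures yield a linear contig spanning one lap plus
  a ~300 kbp wrap so circularity is evidenced by the repeated entry segments;
  linear structures get ~100 kbp native reference flanks. A break rate
  (breaks/Mbp) optionally fragments the contig, emulating assembly failure.
* **Molecules**: random substrings (log-normal length, median 244 kbp) at a
  configured coverage with the same noise model, for molecule-level analyses
  such as integration clustering; mixture pools downsample per-amplicon
  coverage in proportion to copy number.

Everything is driven by one numpy Generator, so outputs are bit-identical
under a fixed seed.

What the simulator does *not* emulate: the consensus-building process itself
(contigs receive one draw of consensus-level noise rather than being
assembled from molecules), molecular chimerism and scan artifacts, diploid
background genomes, and CN-estimation error in the graph (segment CNs are
exact multiples of the amplicon copy number). Passing cohort benchmarks
therefore demonstrate the correctness and noise-robustness of the
reconstruction machinery under a faithful OM error model — not performance
under assembler pathologies or mis-segmented graphs, which on real data are
the dominant failure modes.

## 5. Evaluation

The longest common substring over `(segment, orientation)` tokens — rotations
allowed for cyclic paths (sequences doubled, runs capped at one lap), the
reconstruction also compared in orientation-reversed form — is measured in bp
(summed segment lengths), segments, or junctions (`len−1`, or `len` for a
full cycle). Precision divides by the reconstruction's measure, recall by the
truth's; cohorts report the mean F1, with F1(0,0) defined as 0. Among several
emitted paths, the one with the measure-maximal LCS is scored; ties resolve
toward the better F1 (equivalently the tighter path — preferring the longer
of two equal-LCS paths would only lower precision). Before scoring, terminal
runs that merely follow the reference and are unsupported by the truth are
trimmed — assembled contigs extend into the native genome, and those trivial
extensions say nothing about the rearrangement. A duplicated block is
*resolved* when the reconstruction contains it at the truth multiplicity with
flanks consistent with the truth (path ends tolerated; rotations and the
reversed form count).

## 6. Benchmark problem sizes

The packaged cohort studies use 20 amplicons per single-amplicon condition,
10 three-amplicon samples per mixture condition, and one spanning consensus
contig per amplicon, on per-sample 3.6 Mbp synthetic references. These sizes
give stable cohort means (the spread of mean F1 across seeds is ~0.02) while
keeping a full five-cohort run to a few minutes on one CPU.

## 7. Known limitations

* Terminal segments with fewer than the minimum alignable labels cannot be
  recovered: imputation needs an anchor on both sides. This bounds recall on
  structures ending in short segments and is shared with the anchored-
  alignment strategy generally.
* Runs of consecutive sub-alignable segments exceeding the 400 kbp gap cap
  stay unimputed and split the scaffold.
* Palindromic arrangements (e.g. `5+ 5- 5-`) can be orientation-ambiguous at
  the label level; the aligner may report either orientation where both score
  equally.
* The E-value calibration needs tens of contigs; below that the fixed
  fallback cutoff governs, which is conservative for long segments and is the
  reason short (<10 label) segments are excluded from direct alignment.
* The CN-ratio check assumes graph copy numbers on a common scale; merged
  graphs from mixtures sum CNs across variants, which loosens the check
  slightly for shared segments.
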