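# amprecon

Reconstruction of focal copy-number amplifications (fCNAs) — extrachromosomal
DNA (ecDNA), breakage–fusion–bridge products and other complex rearrangements
— by integrating an NGS-derived **breakpoint graph** with **optical mapping
(OM)** contigs.

Oncogene amplification in cancer is frequently carried on large (0.3–3 Mbp)
rearranged structures. Short-read sequencing yields a breakpoint graph: copy-
number (CN) annotated genomic segments joined by concordant (reference) and
discordant (rearranged) junction edges. The graph alone rarely determines the
amplicon's architecture — the order, orientation and multiplicity of its
segments. Optical maps provide the missing long-range information: ordered
positions of fluorescent labels at a sequence motif (e.g. Nt.BspQI, `GCTCTTC`)
along DNA fragments of hundreds of kbp. `amprecon` aligns in-silico-digested
graph segments to OM contigs, scaffolds the alignments, fills gaps with graph
paths, and emits CN-consistent reconstructions. A first-class simulator and an
LCS-based evaluator make the whole pipeline testable without external data.

Intended users: cancer-genomics methods developers and analysts working with
Bionano-style consensus maps and AmpliconArchitect-style breakpoint graphs.

## The model

**Alignment.** A digested segment with label positions `x` is aligned to a
contig with label positions `b` by banded dynamic programming,

```
S[j][q] = max over (j-d <= i < j, q-d <= p < q) of S[i][p] + Score(i, j, p, q)
Score   = 2c − ( c·(j−i−1) + c·M(p,q) + |(b[j]−b[i]) − (x[q]−x[p])|^k )
```

where `c` is the missing-label score, `k` the length-difference exponent, `d`
the band width (6), and `M(p,q)` the expected number of *observable* segment
labels strictly between `p` and `q` under the label-collapse model: two labels
`Δ` apart are imaged as one with probability `P_merge(Δ) = 1 − min(1, (Δ/w)^t)`
(`w ≈ 2 kbp`). Next-best alignments are found by masking used label pairings
and re-running the DP (at most 12 per segment/contig pair). Significance uses
a BLAST-like empirical E-value model `E = K·m·n_r·e^(−λS)` fit by linear
regression on the tail of best-per-contig scores; with too few contigs to
calibrate, a conservative fixed cutoff (60% of the perfect attainable score)
applies. Default significance p-values are 1e−4 (semi-global), 1e−6
(overlap) and 1e−9 (detection).

**Scaffolding and imputation.** Per contig, significant alignments ordered by
coordinate form a DAG (allowed edges for ≤1 label of overlap, forbidden edges
otherwise). Maximum-weight paths (weight = summed segment bp) become
scaffolds. For each scaffold junction with a gap under 400 kbp, breakpoint-
graph paths between the anchors' graph endpoints are enumerated by constrained
DFS (multiplicity ≤ CN, length within `min(25000, 10000·L_p)` of the expected
gap, ≤ 2^10 candidates, BFS fallback at 2^16); each candidate becomes a
compound label map scored by fitting alignment, and the best candidate is
spliced in if it beats the bare junction.

**Pathfinding.** Scaffolds from different contigs are linked through shared
endpoint-segment alignments (either assembly direction); candidates must pass
the CN-ratio test `n_p ≤ max(c, n_g/m_g) + 1` for every multiplicity level,
are greedily deduplicated (no rotation of a kept path's sequence, or of its
reversal, may contain a candidate), and are classified cyclic when the path
returns to its starting element with more than two nodes.

**Evaluation.** A reconstruction is compared with the truth by the longest
common substring (LCS) of oriented segment tokens (rotation-aware for cycles,
reversal-aware), measured in bp, segments, or junctions:
`precision = M(LCS)/M(recon)`, `recall = M(LCS)/M(truth)`, summarized as the
mean F1 over a cohort.

## Worked example

`examples/03_reconstruct_end_to_end.py` simulates a cyclic 3.4 Mbp amplicon
(17 segments, copy number 20), generates one noisy spanning consensus contig
(5% label miss, ~2 kbp collapse, 2% sizing error), reconstructs it and scores
the result:

```
truth: 8+ 1+ 2+ 6+ 7+ 5+ 3+ 8- 5+ 3+ 4+ 15+ 9+ 10+ 11+ 12+ 13+ 14+ 16+ 17+ (cyclic)
path 1 (cyclic, score 1279388): 8+ 1+ 2+ 6+ 7+ 5+ 3+ 8- 5+ 3+ 4+ 15+ 9+ 10+ 11+ 12+ 13+ 14+ 16+ 17+
 length_bp: precision 1.000  recall 1.000  F1 1.000
     nsegs: precision 1.000  recall 1.000  F1 1.000
breakpoint: precision 1.000  recall 1.000  F1 1.000
```

The emitted path reproduces the simulated truth exactly (up to rotation of
the cycle), including the duplicated block `5+ 3+` and the inverted `8-`.
Other examples cover digestion and alignment (`01`), simulation (`02`), gap
imputation of sub-alignable segments (`04`), heterogeneous mixtures and
integration-point clustering (`05`), unlabeled viral inserts (`06`) and the
text formats (`07`). A thin CLI wraps the same stages:

```bash
amprecon simulate --seed 5 --outdir sim/
amprecon reconstruct --graph sim/graph.txt --contigs sim/contigs.cmap \
    --segments sim/segments.cmap --outdir rec/
amprecon evaluate --truth sim/truth_cycles.txt --recon rec/reconstruction_cycles.txt
```

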