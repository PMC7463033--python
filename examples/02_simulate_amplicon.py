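"""Simulate a rearranged amplicon, its breakpoint graph and noisy contigs.

The generator partitions a reference window into segments, shuffles them with
inversions/duplications/translocations, derives the implied breakpoint graph
(copy numbers and junction edges), and digests the rearranged sequence into a
consensus optical map with realistic error modes.
"""

import numpy as np

from amprecon import SimConfig, simulate_amplicon_structure, simulate_contigs, toy_reference
from amprecon.om_io import digest_graph_segments

rng = np.random.default_rng(11)
ref = toy_reference(3_600_000, rng)
cfg = SimConfig(total_bp_range=(800_000.0, 1_500_000.0), cyclic=True, copy_number=20)

truth, graph = simulate_amplicon_structure(cfg, ref, rng)
segmaps = digest_graph_segments(graph, ref)
contigs = simulate_contigs(truth, graph, ref, cfg, rng)

print("truth path (cyclic):", " ".join(str(e) for e in truth.elements))
print(f"{len(graph.segments)} graph segments, {len(graph.edges)} junction edges "
      f"({sum(1 for e in graph.edges if e.edge_type == 'discordant')} discordant)")
for sid in sorted(graph.segments):
    s = graph.segments[sid]
    print(f"  segment {sid}: {s.length/1e3:7.1f} kbp  CN {s.copy_number:4.0f}  "
          f"{segmaps[sid].n_labels} labels")
print(f"contig: {contigs[0].n_labels} labels over {contigs[0].length_bp/1e6:.2f} Mbp")
# Each segment's CN is its path multiplicity x the amplicon copy number; the
# contig spans one full lap of the cycle plus a wrap-around overlap.
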