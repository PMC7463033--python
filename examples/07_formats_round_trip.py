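"""Read and write the optical-map and breakpoint-graph text formats.

Demonstrates the CMAP (consensus maps), XMAP (alignments), breakpoint-graph
and cycles (reconstructions) dialects on a small simulated dataset.
"""

import tempfile
from pathlib import Path

import numpy as np

from amprecon import (
    SimConfig,
    om_io,
    reconstruct,
    simulate_amplicon_structure,
    simulate_contigs,
    toy_reference,
)
from amprecon.pipeline import align_segments_to_contigs
from amprecon.align import ScoringParams

rng = np.random.default_rng(9)
ref = toy_reference(2_500_000, rng)
cfg = SimConfig(total_bp_range=(500_000.0, 900_000.0))
truth, graph = simulate_amplicon_structure(cfg, ref, rng)
segmaps = om_io.digest_graph_segments(graph, ref)
contigs = simulate_contigs(truth, graph, ref, cfg, rng)

out = Path(tempfile.mkdtemp(prefix="omformats_"))
om_io.write_cmap(contigs, out / "contigs.cmap")
om_io.write_breakpoint_graph(graph, out / "graph.txt")
alns = [a for g in align_segments_to_contigs(segmaps, contigs, ScoringParams()).values()
        for a in g]
om_io.write_xmap(alns, out / "alignments.xmap")
paths = reconstruct(graph, contigs, segmaps).paths
om_io.write_cycles(paths, graph.segments, out / "cycles.txt")

print(f"wrote 4 files to {out}")
print("contigs.cmap  ->", len(om_io.read_cmap(out / "contigs.cmap")), "map(s)")
print("graph.txt     ->", len(om_io.read_breakpoint_graph(out / "graph.txt").segments),
      "segments (round-trips exactly)")
print("alignments.xmap ->", len(om_io.read_xmap(out / "alignments.xmap")), "alignments")
rt_paths, rt_segs = om_io.read_cycles(out / "cycles.txt")
print("cycles.txt    ->", len(rt_paths), "path(s);",
      "first:", " ".join(str(e) for e in rt_paths[0].elements))
# All four dialects are plain tab/line-oriented text and round-trip losslessly
# (label positions to 0.1 bp).
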