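"""Readers/writers for optical-map and breakpoint-graph text formats.

Formats handled:

* CMAP  — Bionano consensus-map format: one row per label plus a channel-0
          terminal row carrying the map length.
* XMAP  — Bionano alignment format; here Ref = optical map contig and
          Qry = in-silico-digested graph segment.
* breakpoint graph — a minimal AA-style dialect::

      sequence <chr>:<start>-<end> <copy_number>
      edge <chr>:<pos><+|->-><chr>:<pos><+|-> <concordant|discordant> <multiplicity>

  An edge endpoint ``chr:pos+`` names the right side of the segment ending at
  ``pos``; ``chr:pos-`` names the left side of the segment starting at ``pos``.
* cycles — reconstruction output::

      Segment <id> <chr> <start> <end>
      Cycle=<k>;Copy_count=<c>;Segments=<id><+|->,...

  Linear paths begin and end with the sentinel element ``0+``; cyclic paths
  omit the sentinels.

In-silico digestion turns a DNA sequence into a LabelMap by locating a
recognition motif on either strand (Nt.BspQI = GCTCTTC, DLE-1 = CTTAAG).
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    BreakpointGraph,
    GraphEdge,
    GraphSegment,
    LabelMap,
    OrientedSegment,
    ReconstructedPath,
    SegmentAlignment,
)

MOTIFS = {"BspQI": "GCTCTTC", "DLE1": "CTTAAG"}

_CMAP_COLUMNS = (
    "CMapId ContigLength NumSites SiteID LabelChannel "
    "Position StdDev Coverage Occurrence".split()
)
_XMAP_COLUMNS = (
    "XmapEntryID QryContigID RefContigID QryStartPos QryEndPos RefStartPos "
    "RefEndPos Orientation Confidence HitEnum QryLen RefLen LabelChannel Alignment".split()
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# CMAP


def read_cmap(path) -> list[LabelMap]:
    """Parse a CMAP file into one LabelMap per CMapId."""
    rows: dict[str, list[tuple[int, int, float]]] = {}
    lengths: dict[str, float] = {}
    nsites: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"short CMAP row: {line!r}")
            cmap_id = f[0]
            lengths[cmap_id] = float(f[1])
            nsites[cmap_id] = int(f[2])
            rows.setdefault(cmap_id, []).append((int(f[3]), int(f[4]), float(f[5])))
    maps = []
    for cmap_id, rr in rows.items():
        labels = sorted(pos for _site, chan, pos in rr if chan != 0)
        n_label_rows = sum(1 for _s, chan, _p in rr if chan != 0)
        if n_label_rows != nsites[cmap_id]:
            raise FormatError(
                f"CMapId {cmap_id}: {n_label_rows} label rows but NumSites={nsites[cmap_id]}"
            )
        arr = np.asarray(labels, dtype=float)
        if arr.size and np.any(np.diff(arr) <= 0):
            raise ValueError(f"CMapId {cmap_id}: non-monotone label positions")
        maps.append(LabelMap(cmap_id, lengths[cmap_id], arr))
    return maps


def write_cmap(maps: Iterable[LabelMap], path) -> None:
    with open(path, "w") as fh:
        fh.write("# CMAP File Version:\t0.1\n")
        fh.write("#h " + "\t".join(_CMAP_COLUMNS) + "\n")
        fh.write("#f int\tfloat\tint\tint\tint\tfloat\tfloat\tfloat\tfloat\n")
        for m in maps:
            n = m.n_labels
            for i, pos in enumerate(m.positions, start=1):
                fh.write(
                    f"{m.map_id}\t{m.length_bp:.1f}\t{n}\t{i}\t{m.channel}"
                    f"\t{pos:.1f}\t1.0\t1.0\t1.0\n"
                )
            fh.write(f"{m.map_id}\t{m.length_bp:.1f}\t{n}\t{n + 1}\t0\t{m.length_bp:.1f}\t0.0\t1.0\t1.0\n")


# ---------------------------------------------------------------------------
# XMAP

_PAIR_RE = re.compile(r"\((\d+),(\d+)\)")


def read_xmap(path) -> list[SegmentAlignment]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 14:
                raise FormatError(f"XMAP row {lineno}: expected 14 columns, got {len(f)}")
            aln_str = f[13]
            pairs = _PAIR_RE.findall(aln_str)
            if not pairs or _PAIR_RE.sub("", aln_str).strip():
                raise FormatError(f"XMAP row {lineno}: unparseable Alignment string {aln_str!r}")
            # stored 1-based (refsite, qrysite); qrysites descend for '-'
            pp = tuple((int(r) - 1, int(q) - 1) for r, q in pairs)
            out.append(
                SegmentAlignment(
                    segment_id=f[1],
                    contig_id=f[2],
                    orientation=f[7],
                    pairs=pp,
                    score=float(f[8]),
                    contig_start_bp=float(f[5]),
                    contig_end_bp=float(f[6]),
                )
            )
    return out


def write_xmap(alignments: Sequence[SegmentAlignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("# XMAP File Version:\t0.2\n")
        fh.write("#h " + "\t".join(_XMAP_COLUMNS) + "\n")
        for i, a in enumerate(alignments, start=1):
            aln = "".join(f"({r + 1},{q + 1})" for r, q in a.pairs)
            qry = [q for _r, q in a.pairs]
            fh.write(
                "\t".join(
                    [
                        str(i),
                        str(a.segment_id),
                        str(a.contig_id),
                        f"{min(qry) + 1}",
                        f"{max(qry) + 1}",
                        f"{a.contig_start_bp:.1f}",
                        f"{a.contig_end_bp:.1f}",
                        a.orientation,
                        f"{a.score:.2f}",
                        f"{len(a.pairs)}M",
                        "0.0",
                        "0.0",
                        "1",
                        aln,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# breakpoint graph dialect

_SEQ_RE = re.compile(r"^sequence\s+(\S+):(\d+)-(\d+)\s+(\S+)\s*$")
_EDGE_RE = re.compile(
    r"^edge\s+(\S+):(\d+)([+-])->(\S+):(\d+)([+-])\s+(concordant|discordant)\s+(\S+)\s*$"
)


def read_breakpoint_graph(path) -> BreakpointGraph:
    segments: list[GraphSegment] = []
    edge_specs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("sequence"):
                m = _SEQ_RE.match(line)
                if not m:
                    raise FormatError(
                        f"line {lineno}: bad sequence line (copy number required): {line!r}"
                    )
                chrom, start, end, cn = m.group(1), int(m.group(2)), int(m.group(3)), float(m.group(4))
                segments.append(GraphSegment(len(segments) + 1, chrom, start, end, cn))
            elif line.startswith("edge"):
                m = _EDGE_RE.match(line)
                if not m:
                    raise FormatError(f"line {lineno}: bad edge line: {line!r}")
                edge_specs.append((lineno, m.groups()))
            else:
                raise FormatError(f"line {lineno}: unrecognized line: {line!r}")
    graph = BreakpointGraph(segments)

    def locate(chrom: str, pos: int, sign: str) -> tuple[int, str]:
        for s in segments:
            if s.chrom != chrom:
                continue
            if sign == "+" and s.end == pos:
                return s.segment_id, "right"
            if sign == "-" and s.start == pos:
                return s.segment_id, "left"
        raise ValueError(f"edge endpoint {chrom}:{pos}{sign} matches no segment boundary")

    for _lineno, g in edge_specs:
        ca, pa, sa, cb, pb, sb, etype, mult = g
        seg_a, side_a = locate(ca, int(pa), sa)
        seg_b, side_b = locate(cb, int(pb), sb)
        graph.add_edge(GraphEdge(seg_a, side_a, seg_b, side_b, etype, float(mult)))
    return graph


def write_breakpoint_graph(graph: BreakpointGraph, path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(graph.segments):
            s = graph.segments[sid]
            fh.write(f"sequence {s.chrom}:{s.start}-{s.end} {s.copy_number:g}\n")

        def endpoint(sid: int, side: str) -> str:
            s = graph.segments[sid]
            return f"{s.chrom}:{s.end}+" if side == "right" else f"{s.chrom}:{s.start}-"

        for e in graph.edges:
            fh.write(
                f"edge {endpoint(e.seg_a, e.side_a)}->{endpoint(e.seg_b, e.side_b)}"
                f" {e.edge_type} {e.multiplicity:g}\n"
            )


# ---------------------------------------------------------------------------
# cycles dialect


def write_cycles(paths: Sequence[ReconstructedPath], segments: Mapping[int, GraphSegment], path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(segments):
            s = segments[sid]
            fh.write(f"Segment {sid} {s.chrom} {s.start} {s.end}\n")
        for k, p in enumerate(paths, start=1):
            for e in p.elements:
                if e.segment_id not in segments:
                    raise ValueError(f"path element references unknown segment {e.segment_id}")
            toks = [str(e) for e in p.elements]
            if not p.cyclic:
                toks = ["0+"] + toks + ["0+"]
            fh.write(f"Cycle={k};Copy_count={p.copy_count:g};Segments={','.join(toks)}\n")


def read_cycles(path) -> tuple[list[ReconstructedPath], dict[int, GraphSegment]]:
    segments: dict[int, GraphSegment] = {}
    paths: list[ReconstructedPath] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("Segment"):
                f = line.split()
                if len(f) != 5:
                    raise FormatError(f"line {lineno}: bad Segment line: {line!r}")
                sid = int(f[1])
                segments[sid] = GraphSegment(sid, f[2], int(f[3]), int(f[4]), 0.0)
            elif line.startswith("Cycle="):
                fields = dict(part.split("=", 1) for part in line.split(";"))
                toks = fields["Segments"].split(",")
                cyclic = not (toks[0] == "0+" and toks[-1] == "0+")
                if not cyclic:
                    toks = toks[1:-1]
                elems = tuple(OrientedSegment(int(t[:-1]), t[-1]) for t in toks)
                paths.append(
                    ReconstructedPath(
                        elems,
                        cyclic=cyclic,
                        path_id=int(fields["Cycle"]),
                        copy_count=float(fields.get("Copy_count", 1.0)),
                    )
                )
            else:
                raise FormatError(f"line {lineno}: unrecognized line: {line!r}")
    return paths, segments


# ---------------------------------------------------------------------------
# in-silico digestion


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def digest_sequence(sequence: str, motif: str = MOTIFS["BspQI"], map_id: str = "digest",
                    offset: int = 0) -> LabelMap:
    """Digest a DNA sequence into a LabelMap.

    One label per motif occurrence on either strand; the label position is the
    1-based start of the occurrence on the forward coordinate system (plus an
    optional constant ``offset``, e.g. a nick offset — a constant shift cancels
    in all downstream length-difference scores). Duplicate positions from
    palindromic motifs are collapsed. N bases never match.
    """
    seq = sequence.upper()
    if len(seq) == 0:
        raise ValueError("cannot digest an empty sequence")
    motif = motif.upper()
    hits: set[int] = set()
    for m in (motif, reverse_complement(motif)):
        pat = re.compile("(?=" + re.escape(m) + ")")
        hits.update(mm.start() + 1 for mm in pat.finditer(seq))
    positions = np.asarray(sorted(hits), dtype=float) + offset
    positions = positions[(positions > 0) & (positions <= len(seq))]
    return LabelMap(map_id, float(len(seq)), positions)


def digest_graph_segments(graph: BreakpointGraph, reference: Mapping[str, str],
                          motif: str = MOTIFS["BspQI"]) -> dict[int, LabelMap]:
    """Digest every graph segment; label positions are relative to segment start.

    ``reference`` is any chrom -> sequence mapping (a dict or a pyfaidx.Fasta).
    """
    out: dict[int, LabelMap] = {}
    for sid in sorted(graph.segments):
        s = graph.segments[sid]
        try:
            seq = str(reference[s.chrom][s.start - 1 : s.end])
        except KeyError as exc:
            raise ValueError(f"segment {sid}: chromosome {s.chrom} not in reference") from exc
        if len(seq) != s.length:
            raise ValueError(
                f"segment {sid}: coordinates {s.start}-{s.end} outside contig {s.chrom}"
            )
        out[sid] = digest_sequence(seq, motif, map_id=str(sid))
    return out
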