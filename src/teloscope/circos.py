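"""Circos-compatible karyotype and track export for the binned QC tracks.

The contract is the data files and their declared ranges, not the rendered
image: one karyotype file, one histogram track (read depth) and four
heatmap tracks (gene, SNP, SV and repeat densities), plus a minimal
configuration file referencing them all.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .qc import GenomicBin

__all__ = ["TrackSet", "export_circos_tracks", "parse_track_file"]

_TRACKS = (
    ("depth", "depth_mean", "histogram"),
    ("gene", "gene_count", "heatmap"),
    ("snp", "snp_count", "heatmap"),
    ("sv", "sv_count", "heatmap"),
    ("repeat", "repeat_ratio", "heatmap"),
)


@dataclass(frozen=True)
class TrackSet:
    karyotype: Path
    tracks: dict[str, Path]
    ranges: dict[str, tuple[float, float]]
    conf: Path


def export_circos_tracks(bins: Sequence[GenomicBin], out_dir: str | Path) -> TrackSet:
    """Write karyotype + five per-bin track files and a minimal circos.conf.

    Karyotype contigs are ordered by descending length; declared per-track
    ranges are the observed min/max of the bin values.
    """
    if not bins:
        raise ValueError("no bins to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    lengths: dict[str, int] = {}
    for b in bins:
        lengths[b.contig] = max(lengths.get(b.contig, 0), b.end)
    order = sorted(lengths, key=lambda c: -lengths[c])

    karyotype = out_dir / "karyotype.txt"
    with open(karyotype, "w") as fh:
        for c in order:
            fh.write(f"chr - {c} {c} 0 {lengths[c]} grey\n")

    tracks: dict[str, Path] = {}
    ranges: dict[str, tuple[float, float]] = {}
    for name, attr, _ptype in _TRACKS:
        path = out_dir / f"{name}.track.txt"
        values = [getattr(b, attr) for b in bins]
        with open(path, "w") as fh:
            for b, v in zip(bins, values):
                fh.write(f"{b.contig} {b.start} {b.end} {v}\n")
        tracks[name] = path
        ranges[name] = (float(min(values)), float(max(values)))

    conf = out_dir / "circos.conf"
    with open(conf, "w") as fh:
        fh.write(f"karyotype = {karyotype.name}\n<plots>\n")
        r0 = 0.95
        for name, _attr, ptype in _TRACKS:
            lo, hi = ranges[name]
            fh.write("<plot>\n")
            fh.write(f"type = {ptype}\nfile = {tracks[name].name}\n")
            fh.write(f"r1 = {r0:.2f}r\nr0 = {r0 - 0.12:.2f}r\n")
            fh.write(f"min = {lo}\nmax = {hi}\n")
            if ptype == "heatmap":
                fh.write("color = blues-9-seq\n")
            fh.write("</plot>\n")
            r0 -= 0.14
        fh.write("</plots>\n")

    return TrackSet(karyotype=karyotype, tracks=tracks, ranges=ranges, conf=conf)


def parse_track_file(path: str | Path) -> list[tuple[str, int, int, float]]:
    """Read a track data file back into ``(contig, start, end, value)`` rows."""
    rows = []
    with open(path) as fh:
        for line in fh:
            contig, start, end, value = line.split()
            rows.append((contig, int(start), int(end), float(value)))
    return rows
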