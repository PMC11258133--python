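"""Assembly-level QC: contig statistics, contig-end telomere scan, 100-kb
binned density tracks, repeat-vs-depth median split, SV spectra and the
gene-by-SV intersection.

Coordinates are 0-based half-open internally; GFF3 and VCF (1-based) are
converted on read.  The depth input is the three-column all-positions dump
(``contig<TAB>1-based position<TAB>depth``); positions absent from the dump
count as depth 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .telomere import TelomereMotif, _revcomp

__all__ = [
    "AssemblyStats",
    "GenomicBin",
    "ContigEndTelomereCall",
    "SVRecord",
    "FeatureInterval",
    "assembly_stats",
    "scan_contig_ends",
    "parse_repeatmasker_out",
    "repeat_class_category",
    "read_gff3_features",
    "read_snp_positions",
    "filter_and_spectrum_svs",
    "read_depth_tsv",
    "compute_bins",
    "bins_to_dataframe",
    "repeat_split_depth_summary",
    "genes_affected_by_sv",
]

REPEAT_CATEGORIES = (
    "Retroelement",
    "DNA transposon",
    "Rolling-circle",
    "Small RNA",
    "Satellite",
    "Simple repeat",
    "Low complexity",
    "Unclassified",
)

DEFAULT_BIN_WIDTH = 100_000
DEFAULT_MIN_SV_SIZE = 50

SV_CATEGORIES = ("DEL", "INS", "INV", "DUP:INT", "DUP:TANDEM")


@dataclass(frozen=True)
class AssemblyStats:
    total_size: int
    max_contig: int
    n50: int
    n_contigs: int


def assembly_stats(assembly: Mapping[str, str] | Sequence[int]) -> AssemblyStats:
    """Total size, longest contig and N50 of an assembly.

    N50 is the length of the contig at which the cumulative length, taken in
    descending order, first reaches half the total.
    """
    if isinstance(assembly, Mapping):
        lengths = [len(s) for s in assembly.values()]
    else:
        lengths = [int(x) for x in assembly]
    if not lengths:
        raise ValueError("empty assembly")
    lengths.sort(reverse=True)
    total = sum(lengths)
    half = total / 2
    cum = 0
    n50 = lengths[-1]
    for L in lengths:
        cum += L
        if cum >= half:
            n50 = L
            break
    return AssemblyStats(total_size=total, max_contig=lengths[0], n50=n50, n_contigs=len(lengths))


@dataclass(frozen=True)
class ContigEndTelomereCall:
    contig: str
    end: str  # "5'" or "3'"
    motif: str  # display form
    copies: int
    span: int  # bp from the contig terminus to the far edge of the cluster


def _find_occurrences(seq: str, pattern: str) -> list[int]:
    hits = []
    i = seq.find(pattern)
    while i != -1:
        hits.append(i)
        i = seq.find(pattern, i + len(pattern))
    return hits


def _clusters(starts: list[int], unit_len: int, max_gap: int) -> list[list[int]]:
    if not starts:
        return []
    out = [[starts[0]]]
    for s in starts[1:]:
        if s - (out[-1][-1] + unit_len) <= max_gap:
            out[-1].append(s)
        else:
            out.append([s])
    return out


def scan_contig_ends(
    assembly: Mapping[str, str],
    motif: TelomereMotif | str,
    end_window: int = 10_000,
    min_copies: int = 10,
    max_gap: int = 50,
) -> list[ContigEndTelomereCall]:
    """Scan both termini of every contig for telomeric repeat clusters.

    The G-rich display form is expected near 3' ends and its reverse
    complement near 5' ends (the G-strand runs toward each terminus).
    Copies separated by gaps of at most ``max_gap`` bp form one cluster; a
    cluster of ``min_copies`` or more yields a call.
    """
    display = motif.display_form if isinstance(motif, TelomereMotif) else motif.upper()
    rc = _revcomp(display)
    u = len(display)
    calls: list[ContigEndTelomereCall] = []
    for contig, seq in assembly.items():
        seq = seq.upper()
        clen = len(seq)
        w = min(end_window, clen)
        # 5' terminus: C-strand (reverse complement of the display form)
        for cluster in _clusters(_find_occurrences(seq[:w], rc), u, max_gap):
            if len(cluster) >= min_copies:
                calls.append(
                    ContigEndTelomereCall(contig, "5'", display, len(cluster), cluster[-1] + u)
                )
        # 3' terminus: G-strand
        off = clen - w
        for cluster in _clusters(_find_occurrences(seq[off:], display), u, max_gap):
            if len(cluster) >= min_copies:
                calls.append(
                    ContigEndTelomereCall(contig, "3'", display, len(cluster), clen - (off + cluster[0]))
                )
    return calls


@dataclass(frozen=True)
class FeatureInterval:
    contig: str
    start: int  # 0-based half-open
    end: int
    kind: str  # gene | CDS | repeat
    attributes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval {self.contig}:{self.start}-{self.end}")

    def attr(self, key: str, default: str | None = None) -> str | None:
        return dict(self.attributes).get(key, default)


def repeat_class_category(rm_class: str) -> str:
    """Map a RepeatMasker class/family string onto the seven summary
    categories (plus Unclassified)."""
    head = rm_class.split("/")[0].strip()
    if head in {"LTR", "LINE", "SINE", "Retroposon", "Retroelement"}:
        return "Retroelement"
    if head == "DNA":
        return "DNA transposon"
    if head == "RC":
        return "Rolling-circle"
    if head in {"snRNA", "rRNA", "tRNA", "scRNA", "srpRNA", "ncRNA"}:
        return "Small RNA"
    if head == "Satellite":
        return "Satellite"
    if head == "Simple_repeat":
        return "Simple repeat"
    if head == "Low_complexity":
        return "Low complexity"
    return "Unclassified"


def parse_repeatmasker_out(path: str | Path) -> tuple[list[FeatureInterval], dict[str, int]]:
    """Parse a RepeatMasker .out alignment table.

    Returns one interval per alignment line plus per-category base totals
    (overlaps are *not* deduplicated here; deduplication happens where
    masked fractions are computed).  The standard three header lines are
    skipped; any other malformed line raises with its line number.
    """
    intervals: list[FeatureInterval] = []
    totals = {cat: 0 for cat in REPEAT_CATEGORIES}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines[:4]):
        tok = line.split()
        if not tok or not tok[0].lstrip("-").isdigit():
            body_start = i + 1
    for lineno, line in enumerate(lines[body_start:], body_start + 1):
        if not line.strip():
            continue
        tok = line.split()
        if len(tok) < 14:
            raise ValueError(f"{path}:{lineno}: expected >= 14 fields, got {len(tok)}")
        try:
            query = tok[4]
            qbegin = int(tok[5])
            qend = int(tok[6])
            family = tok[9]
            rm_class = tok[10]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed alignment line: {line.rstrip()}") from exc
        if qbegin < 1 or qend < qbegin:
            raise ValueError(f"{path}:{lineno}: bad coordinates {qbegin}-{qend}")
        cat = repeat_class_category(rm_class)
        intervals.append(
            FeatureInterval(
                query,
                qbegin - 1,
                qend,
                "repeat",
                attributes=(("family", family), ("class", rm_class), ("category", cat)),
            )
        )
        totals[cat] += qend - qbegin + 1
    return intervals, totals


def read_gff3_features(path: str | Path) -> tuple[list[FeatureInterval], list[FeatureInterval]]:
    """Extract gene and CDS intervals from a GFF3 file.

    CDS features are tagged with the gene they belong to, resolved through
    the Parent chain (CDS -> mRNA -> gene) or directly when a CDS names a
    gene as parent.  Returns ``(genes, cds)``.
    """
    genes: list[FeatureInterval] = []
    cds_raw: list[tuple[str, int, int, str]] = []
    parent_of: dict[str, str] = {}
    gene_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            contig, _src, ftype, start1, end1, _score, _strand, _phase, attrs = cols
            attrd = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            start, end = int(start1) - 1, int(end1)
            if ftype == "gene":
                gid = attrd.get("ID", f"gene@{contig}:{start}")
                gene_ids.add(gid)
                genes.append(
                    FeatureInterval(contig, start, end, "gene", attributes=(("gene_id", gid),))
                )
            elif ftype in {"mRNA", "transcript"}:
                if "ID" in attrd and "Parent" in attrd:
                    parent_of[attrd["ID"]] = attrd["Parent"]
            elif ftype == "CDS":
                cds_raw.append((contig, start, end, attrd.get("Parent", "")))
    cds: list[FeatureInterval] = []
    for contig, start, end, parent in cds_raw:
        gid = parent
        seen = set()
        while gid in parent_of and gid not in gene_ids and gid not in seen:
            seen.add(gid)
            gid = parent_of[gid]
        cds.append(FeatureInterval(contig, start, end, "CDS", attributes=(("gene_id", gid),)))
    return genes, cds


def read_snp_positions(path: str | Path) -> list[tuple[str, int]]:
    """SNP ``(contig, 0-based position)`` pairs from a VCF."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            out.append((rec.chrom, rec.pos - 1))
    return out


@dataclass(frozen=True)
class SVRecord:
    contig: str
    pos: int  # 1-based, as in the VCF
    svtype: str
    length: int

    @property
    def footprint(self) -> tuple[int, int]:
        """Reference footprint, 0-based half-open; insertions occupy 1 bp."""
        start = self.pos - 1
        if self.svtype == "INS":
            return start, start + 1
        return start, start + self.length


def _normalize_svtype(raw: str) -> str:
    t = raw.upper().replace("_", ":")
    if t in SV_CATEGORIES:
        return t
    if t == "DUP":
        return "DUP:INT"
    return t


def filter_and_spectrum_svs(
    path: str | Path,
    min_sv_size: int = DEFAULT_MIN_SV_SIZE,
) -> tuple[list[SVRecord], dict[str, int], dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Read an SV VCF, apply the minimum-size filter and build the type spectrum.

    Length is |SVLEN|, falling back to END - POS when SVLEN is absent; a
    record carrying neither raises.  Records shorter than ``min_sv_size``
    (default 50 bp) are dropped.  Returns the retained records, per-type
    counts over the five categories (deletion, insertion, inversion,
    interspersed and tandem duplication), and per-type log-scaled length
    histograms as ``(counts, bin_edges)``.
    """
    def _info(rec, key):
        # pysam raises (not returns None) for INFO keys missing from the header
        try:
            return rec.info[key]
        except (KeyError, ValueError):
            return None

    records: list[SVRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = _info(rec, "SVTYPE")
            if svtype is None:
                alt = rec.alts[0] if rec.alts else ""
                svtype = alt.strip("<>") if alt.startswith("<") else None
            if svtype is None:
                raise ValueError(f"SV record without SVTYPE at {rec.chrom}:{rec.pos}")
            svtype = _normalize_svtype(str(svtype))
            svlen = _info(rec, "SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0] if svlen else None
            if svlen is not None:
                length = abs(int(svlen))
            else:
                end = _info(rec, "END")
                if end is None and rec.stop and rec.stop > rec.pos:
                    end = rec.stop
                if end is None:
                    raise ValueError(
                        f"SV record with neither SVLEN nor END: {rec.chrom}:{rec.pos} {svtype}"
                    )
                length = int(end) - rec.pos
            if length < min_sv_size:
                continue
            records.append(SVRecord(rec.chrom, rec.pos, svtype, length))
    counts = {cat: 0 for cat in SV_CATEGORIES}
    for r in records:
        counts[r.svtype] = counts.get(r.svtype, 0) + 1
    hists: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cat in counts:
        lens = np.array([r.length for r in records if r.svtype == cat])
        if lens.size:
            lo = np.log10(max(min_sv_size, 1))
            hi = np.log10(max(lens.max(), min_sv_size) + 1)
            edges = np.logspace(lo, hi + 1e-9, 25)
            h, edges = np.histogram(lens, bins=edges)
        else:
            h, edges = np.zeros(0, dtype=int), np.zeros(0)
        hists[cat] = (h, edges)
    return records, counts, hists


def read_depth_tsv(path: str | Path) -> pd.DataFrame:
    """Three-column per-base depth dump -> DataFrame(contig, pos, depth); pos 1-based."""
    df = pd.read_csv(path, sep="\t", header=None, names=["contig", "pos", "depth"],
                     dtype={"contig": str, "pos": np.int64, "depth": np.int64})
    return df


@dataclass
class GenomicBin:
    contig: str
    start: int  # 0-based half-open
    end: int
    depth_sum: int = 0
    depth_mean: float = 0.0
    repeat_ratio: float = 0.0
    gene_count: int = 0
    snp_count: int = 0
    sv_count: int = 0

    @property
    def width(self) -> int:
        return self.end - self.start


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivals:
        return []
    ivals = sorted(ivals)
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def compute_bins(
    contig_lengths: Mapping[str, int],
    depth: pd.DataFrame | None = None,
    repeat_intervals: Iterable[FeatureInterval] | None = None,
    genes: Iterable[FeatureInterval] | None = None,
    snps: Iterable[tuple[str, int]] | None = None,
    svs: Iterable[SVRecord] | None = None,
    bin_width: int = DEFAULT_BIN_WIDTH,
    min_contig_len: int = 0,
) -> list[GenomicBin]:
    """Tile retained contigs into fixed-width bins and aggregate tracks.

    Contigs shorter than ``min_contig_len`` are dropped (the length filter
    used to keep representative contigs only).  Bins step from 0 in
    ``bin_width`` increments, the last bin truncated at the contig end.
    Depth is summed per bin and averaged over the true bin width (missing
    positions count as depth 0); the repeat ratio is the unioned masked
    fraction of the bin; genes, SNPs and SVs are each assigned to the bin
    containing their start coordinate.
    """
    retained = {c: L for c, L in contig_lengths.items() if L >= min_contig_len}
    bins: dict[str, list[GenomicBin]] = {}
    for contig, L in retained.items():
        row = []
        for s in range(0, L, bin_width):
            row.append(GenomicBin(contig, s, min(s + bin_width, L)))
        bins[contig] = row

    def bin_of(contig: str, pos0: int) -> GenomicBin | None:
        row = bins.get(contig)
        if row is None:
            return None
        return row[pos0 // bin_width]

    if depth is not None and len(depth):
        for contig, sub in depth.groupby("contig", sort=False):
            contig = str(contig)
            if contig not in contig_lengths:
                raise ValueError(f"depth rows for unknown contig {contig!r}")
            L = contig_lengths[contig]
            pos = sub["pos"].to_numpy()
            if pos.min() < 1 or pos.max() > L:
                raise ValueError(f"depth position outside contig {contig} (length {L})")
            if contig not in bins:
                continue
            idx = (pos - 1) // bin_width
            sums = np.bincount(idx, weights=sub["depth"].to_numpy(), minlength=len(bins[contig]))
            for b, s in zip(bins[contig], sums):
                b.depth_sum = int(s)
                b.depth_mean = s / b.width

    if repeat_intervals is not None:
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for iv in repeat_intervals:
            by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
        for contig, ivals in by_contig.items():
            if contig not in bins:
                continue
            L = retained[contig]
            for s, e in _merge_intervals(ivals):
                s, e = max(0, s), min(e, L)
                b0, b1 = s // bin_width, (e - 1) // bin_width
                for bi in range(b0, b1 + 1):
                    b = bins[contig][bi]
                    ov = min(e, b.end) - max(s, b.start)
                    if ov > 0:
                        b.repeat_ratio += ov / b.width

    for feats, attr in ((genes, "gene_count"),):
        if feats is None:
            continue
        for iv in feats:
            b = bin_of(iv.contig, iv.start)
            if b is not None:
                setattr(b, attr, getattr(b, attr) + 1)
    if snps is not None:
        for contig, pos0 in snps:
            b = bin_of(contig, pos0)
            if b is not None:
                b.snp_count += 1
    if svs is not None:
        for sv in svs:
            b = bin_of(sv.contig, sv.pos - 1)
            if b is not None:
                b.sv_count += 1

    out: list[GenomicBin] = []
    for contig in retained:
        for b in bins[contig]:
            b.repeat_ratio = min(1.0, round(b.repeat_ratio, 12))
            out.append(b)
    return out


def bins_to_dataframe(bins: Sequence[GenomicBin]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": b.contig,
                "start": b.start,
                "end": b.end,
                "depth_sum": b.depth_sum,
                "depth_mean": b.depth_mean,
                "repeat_ratio": b.repeat_ratio,
                "gene_count": b.gene_count,
                "snp_count": b.snp_count,
                "sv_count": b.sv_count,
            }
            for b in bins
        ]
    )


def repeat_split_depth_summary(bins: Sequence[GenomicBin]) -> dict:
    """Median-split bins by repeat ratio and summarize read depth per group.

    The threshold is the median repeat ratio over all bins; bins at or below
    it form the "less repetitive" group, the rest the "more repetitive"
    group.  Depth is summarized by the median and sample standard deviation
    of per-bin mean depths (sd is None for groups of fewer than two bins).
    """
    if len(bins) < 2:
        raise ValueError("need at least 2 bins for a median split")
    ratios = np.array([b.repeat_ratio for b in bins])
    threshold = float(np.median(ratios))
    groups = {"less_repetitive": [], "more_repetitive": []}
    for b in bins:
        key = "less_repetitive" if b.repeat_ratio <= threshold else "more_repetitive"
        groups[key].append(b.depth_mean)
    summary: dict = {"threshold": threshold}
    for key, depths in groups.items():
        arr = np.array(depths, dtype=float)
        summary[key] = {
            "n": int(arr.size),
            "median_depth": float(np.median(arr)) if arr.size else None,
            "sd_depth": float(np.std(arr, ddof=1)) if arr.size > 1 else None,
        }
    return summary


def genes_affected_by_sv(
    cds_intervals: Iterable[FeatureInterval],
    svs: Sequence[SVRecord],
) -> tuple[int, dict[str, list[SVRecord]]]:
    """Genes whose coding sequence overlaps at least one SV footprint.

    Overlap is half-open, >= 1 bp; insertion footprints are 1 bp at the
    insertion site.  A gene with several hit CDS segments, or one CDS hit by
    several SVs, is still counted once.
    """
    trees: dict[str, IntervalTree] = {}
    for sv in svs:
        s, e = sv.footprint
        trees.setdefault(sv.contig, IntervalTree()).addi(s, e, sv)
    affected: dict[str, list[SVRecord]] = {}
    for cds in cds_intervals:
        tree = trees.get(cds.contig)
        if tree is None:
            continue
        hits = tree.overlap(cds.start, cds.end)
        if hits:
            gid = cds.attr("gene_id") or f"{cds.contig}:{cds.start}"
            bucket = affected.setdefault(gid, [])
            for h in hits:
                if h.data not in bucket:
                    bucket.append(h.data)
    return len(affected), affected
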