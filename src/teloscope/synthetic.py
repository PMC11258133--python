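"""Synthetic diploid genomes, reads and annotation fixtures with known truth.

The generator emulates the study design this package targets: small diploid
plant genomes carrying telomeric tandem arrays of a chosen motif at both ends
of every chromosome, a tunable load of interspersed repeats, and a second
haplotype diverged by planted SNPs and structural variants.  Short reads are
151-bp Illumina-like; long reads are HiFi-like (error-free by default,
lognormal lengths with means around 17-18 kb).

Every output is a pure function of the spec plus a seed, so downstream
stages (motif discovery, k-mer profiling, assembly QC) can be tested against
exact ground truth without any external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import write_fasta, write_fastq

__all__ = [
    "SyntheticGenomeSpec",
    "SVTruth",
    "GeneTruth",
    "TruthSet",
    "simulate_genome",
    "simulate_short_reads",
    "simulate_long_reads",
    "emit_annotation_fixtures",
    "diploid_pool",
    "reverse_complement",
]

SV_TYPES = ("DEL", "INS", "INV", "DUP:INT", "DUP:TANDEM")

_COMP = str.maketrans("ACGTN", "TGCAN")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of a simulated diploid genome.

    ``sv_events`` is a sequence of ``(type, length_bp, count)`` with type in
    ``{DEL, INS, INV, DUP:INT, DUP:TANDEM}``.  ``repeat_fraction`` is the
    fraction of each chromosome covered by copies of a small set of random
    interspersed repeat families; every family is placed at least twice so
    repeats show up as multi-copy k-mer peaks.
    """

    n_chromosomes: int = 1
    chrom_length_bp: int = 200_000
    telomere_motif: str = "TTTAGGG"
    telomere_copies_per_end: int = 300
    repeat_fraction: float = 0.0
    snp_rate: float = 0.0
    sv_events: tuple[tuple[str, int, int], ...] = ()
    genes_per_chrom: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if set(self.telomere_motif) - set("ACGT") or not self.telomere_motif:
            raise ValueError(f"telomere motif must be non-empty ACGT: {self.telomere_motif!r}")
        if not 0 <= self.repeat_fraction < 1:
            raise ValueError("repeat_fraction must be in [0, 1)")
        if not 0 <= self.snp_rate < 0.05:
            raise ValueError("snp_rate must be in [0, 0.05)")
        span = self.telomere_copies_per_end * len(self.telomere_motif)
        if self.chrom_length_bp <= 2 * span:
            raise ValueError(
                f"infeasible spec: chromosome ({self.chrom_length_bp} bp) must exceed "
                f"twice the telomere span (2 x {span} bp)"
            )
        for ev in self.sv_events:
            svtype, length, count = ev
            if svtype not in SV_TYPES:
                raise ValueError(f"unknown SV type {svtype!r}; expected one of {SV_TYPES}")
            if length < 1 or count < 0:
                raise ValueError(f"bad SV event {ev}")

    @property
    def telomere_span(self) -> int:
        return self.telomere_copies_per_end * len(self.telomere_motif)


@dataclass(frozen=True)
class SVTruth:
    chrom: str
    pos: int  # 1-based, reference (haplotype A) coordinate
    svtype: str
    length: int
    # DUP:INT also records where the extra copy landed (reference coord)
    insert_at: int | None = None

    @property
    def footprint(self) -> tuple[int, int]:
        """Reference footprint, 0-based half-open; 1 bp for insertions."""
        start = self.pos - 1
        if self.svtype == "INS":
            return start, start + 1
        return start, start + self.length


@dataclass(frozen=True)
class GeneTruth:
    chrom: str
    gene_id: str
    start: int  # 0-based half-open
    end: int
    strand: str
    cds: tuple[tuple[int, int], ...]


@dataclass
class TruthSet:
    """Ground truth planted by :func:`simulate_genome`."""

    telomere_motif: str
    chrom_lengths: dict[str, int]
    snps: list[tuple[str, int, str, str]]  # (chrom, pos0, ref, alt) on haplotype B
    svs: list[SVTruth]
    repeats: dict[str, list[tuple[int, int, str]]]  # chrom -> (start, end, family)
    repeat_classes: dict[str, str] = field(default_factory=dict)  # family -> RM class
    genes: list[GeneTruth] = field(default_factory=list)
    genome_size_bp: int = 0
    heterozygosity: float = 0.0


# RepeatMasker-style classes cycled over synthetic families so the seven
# repeat categories all appear in fixtures.
_FAMILY_CLASSES = (
    "LTR/Copia",
    "DNA/hAT",
    "RC/Helitron",
    "LINE/L1",
    "snRNA",
    "Satellite",
    "Simple_repeat",
    "Low_complexity",
    "Unknown",
)


def _random_seq_arr(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _place_repeats(
    rng: np.random.Generator,
    interior: np.ndarray,
    target_bases: int,
    occupied: np.ndarray,
) -> list[tuple[int, int, str]]:
    """Plant exact copies of random repeat families until coverage is met."""
    if target_bases <= 0:
        return []
    n_fam = int(rng.integers(3, 11))
    max_len = min(5000, max(300, len(interior) // 20))
    fam_lens = rng.integers(300, max_len + 1, n_fam)
    families = [(f"RFAM{i + 1}", _random_seq_arr(rng, int(fl))) for i, fl in enumerate(fam_lens)]
    placed: list[tuple[int, int, str]] = []
    covered = 0

    def try_place(fi: int, tries: int = 200) -> bool:
        nonlocal covered
        name, fam = families[fi]
        flen = len(fam)
        if flen > len(interior):
            return False
        for _ in range(tries):
            start = int(rng.integers(0, len(interior) - flen + 1))
            if not occupied[start : start + flen].any():
                interior[start : start + flen] = fam
                occupied[start : start + flen] = True
                placed.append((start, start + flen, name))
                covered += flen
                return True
        return False

    # guarantee >= 2 copies per family (multi-copy k-mer peaks), then fill
    for fi in list(range(n_fam)) * 2:
        if covered >= target_bases:
            break
        try_place(fi)
    attempts = 0
    while covered < target_bases and attempts < 20_000:
        attempts += 1
        try_place(int(rng.integers(0, n_fam)), tries=20)
    placed.sort()
    return placed


def _place_genes(
    rng: np.random.Generator, chrom: str, span: int, interior_len: int, n_genes: int, occupied: np.ndarray
) -> list[GeneTruth]:
    genes: list[GeneTruth] = []
    for gi in range(n_genes):
        glen = int(rng.integers(900, 3001))
        if glen + 2 > interior_len:
            break
        for _ in range(200):
            start = int(rng.integers(0, interior_len - glen))
            if not occupied[start : start + glen].any():
                break
        else:
            continue
        occupied[start : start + glen] = True
        n_cds = int(rng.integers(1, 4))
        bounds = np.sort(rng.choice(np.arange(1, glen - 1), size=2 * n_cds, replace=False))
        cds = tuple(
            (span + start + int(bounds[2 * j]), span + start + int(bounds[2 * j + 1]))
            for j in range(n_cds)
            if bounds[2 * j + 1] > bounds[2 * j]
        )
        if not cds:
            cds = ((span + start, span + start + glen),)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneTruth(chrom, f"{chrom}.g{gi + 1}", span + start, span + start + glen, strand, cds))
    return genes


def _choose_sv_intervals(
    rng: np.random.Generator, spec: SyntheticGenomeSpec, chrom_names: list[str], interior_len: int
) -> list[SVTruth]:
    span = spec.telomere_span
    margin = max(100, interior_len // 50)
    svs: list[SVTruth] = []
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def free(chrom: str, a: int, b: int) -> bool:
        return all(b <= s or a >= e for s, e in taken[chrom])

    for svtype, length, count in spec.sv_events:
        if length >= interior_len - 2 * margin:
            raise ValueError(f"SV of {length} bp does not fit the chromosome interior")
        for _ in range(count):
            for _ in range(500):
                chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
                lo = span + margin
                hi = span + interior_len - margin - length
                if hi <= lo:
                    raise ValueError("no room for SV placement")
                start = int(rng.integers(lo, hi))
                pad = (start - 1, start + length + 1)
                if free(chrom, *pad):
                    taken[chrom].append(pad)
                    insert_at = None
                    if svtype == "DUP:INT":
                        for _ in range(500):
                            ipos = int(rng.integers(lo, span + interior_len - margin))
                            if free(chrom, ipos - 1, ipos + 1):
                                taken[chrom].append((ipos - 1, ipos + 1))
                                insert_at = ipos + 1
                                break
                        else:
                            insert_at = start  # degenerate fallback
                    svs.append(SVTruth(chrom, start + 1, svtype, length, insert_at))
                    break
            else:
                raise ValueError(f"could not place {svtype} of {length} bp after 500 tries")
    svs.sort(key=lambda s: (s.chrom, s.pos))
    return svs


def simulate_genome(spec: SyntheticGenomeSpec) -> tuple[dict[str, str], dict[str, str], TruthSet]:
    """Build haplotypes A (reference) and B (diverged) plus their truth set.

    Telomeres follow the genomic convention that the G-rich strand runs
    5'->3' toward each terminus: the plus strand starts with tandem copies of
    the reverse complement of the motif and ends with copies of the motif
    itself.  SNPs and SVs are planted only in the interior, never inside the
    telomeric arrays, so planted-motif recovery stays exact.
    """
    rng = np.random.default_rng(spec.seed)
    span = spec.telomere_span
    interior_len = spec.chrom_length_bp - 2 * span
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]

    motif_arr = np.frombuffer(spec.telomere_motif.encode(), dtype=np.uint8)
    code = np.full(256, 255, dtype=np.uint8)
    for v, b in enumerate(b"ACGT"):
        code[b] = v
    motif_codes = code[motif_arr]
    left_telo = (3 - motif_codes)[::-1]  # reverse complement, toward 5' terminus
    left_arr = np.tile(left_telo, spec.telomere_copies_per_end)
    right_arr = np.tile(motif_codes, spec.telomere_copies_per_end)

    hap_a: dict[str, str] = {}
    repeats: dict[str, list[tuple[int, int, str]]] = {}
    repeat_classes: dict[str, str] = {}
    genes: list[GeneTruth] = []
    chrom_arrays: dict[str, np.ndarray] = {}

    for chrom in chrom_names:
        interior = _random_seq_arr(rng, interior_len)
        occupied = np.zeros(interior_len, dtype=bool)
        target = int(spec.repeat_fraction * spec.chrom_length_bp)
        placed = _place_repeats(rng, interior, target, occupied)
        fams = {}
        for s, e, fam in placed:
            fams[fam] = None
        for i, fam in enumerate(sorted(fams)):
            repeat_classes.setdefault(f"{chrom}.{fam}", _FAMILY_CLASSES[i % len(_FAMILY_CLASSES)])
        repeats[chrom] = [(span + s, span + e, f"{chrom}.{fam}") for s, e, fam in placed]
        genes.extend(_place_genes(rng, chrom, span, interior_len, spec.genes_per_chrom, occupied))
        full = np.concatenate([left_arr, interior, right_arr])
        chrom_arrays[chrom] = full
        hap_a[chrom] = _decode(full)

    # haplotype B: SNPs then SVs, both recorded in reference coordinates
    snps: list[tuple[str, int, str, str]] = []
    hap_b: dict[str, str] = {}
    svs = _choose_sv_intervals(rng, spec, chrom_names, interior_len) if spec.sv_events else []

    for chrom in chrom_names:
        arr = chrom_arrays[chrom].copy()
        if spec.snp_rate > 0:
            hit = np.flatnonzero(rng.random(interior_len) < spec.snp_rate) + span
            shifts = rng.integers(1, 4, len(hit)).astype(np.uint8)
            ref_codes = arr[hit]
            arr[hit] = (ref_codes + shifts) % 4
            for p, rc, ac in zip(hit.tolist(), ref_codes.tolist(), arr[hit].tolist()):
                snps.append((chrom, p, "ACGT"[rc], "ACGT"[ac]))
        seq = _decode(arr)
        edits = []
        for sv in svs:
            if sv.chrom != chrom:
                continue
            start = sv.pos - 1
            if sv.svtype == "DEL":
                edits.append((start, "del", start, start + sv.length, ""))
            elif sv.svtype == "INS":
                ins = _decode(_random_seq_arr(rng, sv.length))
                edits.append((start, "ins", start, start, ins))
            elif sv.svtype == "INV":
                edits.append((start, "inv", start, start + sv.length, ""))
            elif sv.svtype == "DUP:TANDEM":
                seg = seq[start : start + sv.length]
                edits.append((start + sv.length, "ins", start + sv.length, start + sv.length, seg))
            elif sv.svtype == "DUP:INT":
                seg = seq[start : start + sv.length]
                ip = sv.insert_at if sv.insert_at is not None else start
                edits.append((ip, "ins", ip, ip, seg))
        for _, kind, a, b, payload in sorted(edits, key=lambda e: -e[0]):
            if kind == "del":
                seq = seq[:a] + seq[b:]
            elif kind == "ins":
                seq = seq[:a] + payload + seq[a:]
            elif kind == "inv":
                seq = seq[:a] + reverse_complement(seq[a:b]) + seq[b:]
        hap_b[chrom] = seq

    genome_size = sum(len(s) for s in hap_a.values())
    truth = TruthSet(
        telomere_motif=spec.telomere_motif,
        chrom_lengths={c: len(s) for c, s in hap_a.items()},
        snps=snps,
        svs=svs,
        repeats=repeats,
        repeat_classes=repeat_classes,
        genes=genes,
        genome_size_bp=genome_size,
        heterozygosity=len(snps) / genome_size if genome_size else 0.0,
    )
    return hap_a, hap_b, truth


def diploid_pool(hap_a: dict[str, str], hap_b: dict[str, str]) -> dict[str, str]:
    """Merge two haplotype sets into one read-sampling pool."""
    pool = {f"hapA_{c}": s for c, s in hap_a.items()}
    pool.update({f"hapB_{c}": s for c, s in hap_b.items()})
    return pool


def simulate_short_reads(
    genome: dict[str, str],
    n_reads: int,
    read_length: int = 151,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Sample uniform 151-bp-style reads from both strands of a genome.

    Substitution errors are planted at ``error_rate`` per base.  The genome is
    a ``{name: sequence}`` mapping (pass :func:`diploid_pool` output to sample
    both haplotypes).  Deterministic under ``seed``.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    names = list(genome)
    if not names:
        raise ValueError("empty genome")
    shortest = min(len(genome[c]) for c in names)
    if read_length > shortest:
        raise ValueError(f"read_length {read_length} exceeds shortest sequence ({shortest} bp)")

    rng = np.random.default_rng(seed)
    code = np.full(256, 0, dtype=np.uint8)
    for v, b in enumerate(b"ACGT"):
        code[b] = v
    arrs = [code[np.frombuffer(genome[c].encode(), dtype=np.uint8)] for c in names]
    weights = np.array([len(a) - read_length + 1 for a in arrs], dtype=np.int64)
    cum = np.cumsum(weights)
    u = rng.integers(0, cum[-1], n_reads)
    seq_idx = np.searchsorted(cum, u, side="right")
    starts = u - np.concatenate([[0], cum[:-1]])[seq_idx]
    strands = rng.integers(0, 2, n_reads)

    out = np.empty((n_reads, read_length), dtype=np.uint8)
    offsets = np.arange(read_length)
    for si in range(len(arrs)):
        rows = np.flatnonzero(seq_idx == si)
        if rows.size == 0:
            continue
        out[rows] = arrs[si][starts[rows][:, None] + offsets]
    minus = np.flatnonzero(strands == 1)
    if minus.size:
        out[minus] = (3 - out[minus])[:, ::-1]
    if error_rate > 0:
        mask = rng.random(out.shape) < error_rate
        shift = rng.integers(1, 4, int(mask.sum())).astype(np.uint8)
        out[mask] = (out[mask] + shift) % 4

    ascii_out = _BASES[out]
    reads = []
    for i in range(n_reads):
        rid = f"r{i}/{names[seq_idx[i]]}/{starts[i]}/{'+-'[strands[i]]}"
        reads.append((rid, ascii_out[i].tobytes().decode()))
    return reads


def simulate_long_reads(
    genome: dict[str, str],
    coverage: float,
    mean_length: int = 17_289,
    sigma: float = 0.35,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """HiFi-like long reads: lognormal lengths, error-free by default.

    Lengths are lognormal with the requested arithmetic mean (mu is solved
    from ``mean = exp(mu + sigma^2/2)``).  Reads are drawn until total bases
    reach ``coverage x genome size``; with ~17 kb reads the overshoot is far
    inside the 5% coverage tolerance for Mb-scale genomes.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    names = list(genome)
    genome_size = sum(len(genome[c]) for c in names)
    shortest = min(len(genome[c]) for c in names)
    if mean_length >= shortest:
        raise ValueError("mean_length must be below the shortest sequence length")

    rng = np.random.default_rng(seed)
    mu = math.log(mean_length) - sigma**2 / 2
    target = int(coverage * genome_size)
    lens: list[int] = []
    total = 0
    while total < target:
        batch = rng.lognormal(mu, sigma, 1024).astype(np.int64)
        batch = np.clip(batch, 50, shortest)
        for L in batch.tolist():
            lens.append(L)
            total += L
            if total >= target:
                break

    weights = np.array([len(genome[c]) for c in names], dtype=np.float64)
    weights /= weights.sum()
    reads = []
    for i, L in enumerate(lens):
        ci = int(rng.choice(len(names), p=weights))
        seq = genome[names[ci]]
        start = int(rng.integers(0, len(seq) - L + 1))
        strand = int(rng.integers(0, 2))
        sub = seq[start : start + L]
        if strand:
            sub = reverse_complement(sub)
        if error_rate > 0:
            arr = np.frombuffer(sub.encode(), dtype=np.uint8).copy()
            code = np.full(256, 0, dtype=np.uint8)
            for v, b in enumerate(b"ACGT"):
                code[b] = v
            codes = code[arr]
            mask = rng.random(L) < error_rate
            shift = rng.integers(1, 4, int(mask.sum())).astype(np.uint8)
            codes[mask] = (codes[mask] + shift) % 4
            sub = _BASES[codes].tobytes().decode()
        reads.append((f"lr{i}/{names[ci]}/{start}/{'+-'[strand]}", sub))
    return reads


def emit_annotation_fixtures(
    truth: TruthSet,
    out_dir: str | Path,
    depth_mean: float = 40.0,
    seed: int = 0,
) -> dict[str, Path]:
    """Write RepeatMasker .out, GFF3, SNP/SV VCFs and a per-base depth TSV.

    The files round-trip exactly through the parsers in
    :mod:`teloscope.qc`.  An empty truth set yields header-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = {
        "repeats_out": out_dir / "repeats.out",
        "genes_gff": out_dir / "genes.gff3",
        "snp_vcf": out_dir / "snps.vcf",
        "sv_vcf": out_dir / "svs.vcf",
        "depth_tsv": out_dir / "depth.tsv",
    }

    with open(paths["repeats_out"], "w") as fh:
        fh.write(
            "   SW   perc perc perc  query      position in query           matching"
            "       repeat              position in repeat\n"
            "score   div. del. ins.  sequence    begin end          (left)   repeat"
            "         class/family         begin  end    (left)   ID\n\n"
        )
        rid = 0
        for chrom in sorted(truth.repeats):
            clen = truth.chrom_lengths.get(chrom, 0)
            for start, end, fam in truth.repeats[chrom]:
                rid += 1
                klass = truth.repeat_classes.get(fam, "Unknown")
                fh.write(
                    f"  463 11.5  0.0  0.0  {chrom} {start + 1} {end} ({clen - end}) + "
                    f"{fam} {klass} 1 {end - start} (0) {rid}\n"
                )

    with open(paths["genes_gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, clen in truth.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {clen}\n")
        for g in truth.genes:
            fh.write(
                f"{g.chrom}\tteloscope\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tteloscope\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for ci, (s, e) in enumerate(g.cds):
                fh.write(
                    f"{g.chrom}\tteloscope\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds{ci + 1};Parent={mrna}\n"
                )

    vcf_header = ["##fileformat=VCFv4.2"]
    for chrom, clen in truth.chrom_lengths.items():
        vcf_header.append(f"##contig=<ID={chrom},length={clen}>")

    with open(paths["snp_vcf"], "w") as fh:
        fh.write("\n".join(vcf_header) + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos0, ref, alt in truth.snps:
            fh.write(f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")

    with open(paths["sv_vcf"], "w") as fh:
        fh.write("\n".join(vcf_header) + "\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, sv in enumerate(truth.svs):
            svlen = -sv.length if sv.svtype == "DEL" else sv.length
            end = sv.pos if sv.svtype == "INS" else sv.pos + sv.length - 1
            alt = f"<{sv.svtype}>"
            fh.write(
                f"{sv.chrom}\t{sv.pos}\tsv{i + 1}\tN\t{alt}\t.\tPASS\t"
                f"SVTYPE={sv.svtype};SVLEN={svlen};END={end}\n"
            )

    with open(paths["depth_tsv"], "w") as fh:
        for chrom, clen in truth.chrom_lengths.items():
            depths = rng.poisson(depth_mean, clen)
            pos = np.arange(1, clen + 1)
            block = "\n".join(f"{chrom}\t{p}\t{d}" for p, d in zip(pos.tolist(), depths.tolist()))
            if block:
                fh.write(block + "\n")

    return paths


def write_genome_fasta(haplotype: dict[str, str], path: str | Path) -> None:
    write_fasta(haplotype, path)


def write_reads_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> int:
    return write_fastq(reads, path)
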