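"""k-mer spectrum genome profiling.

Canonical k-mers (the lexicographic minimum of a k-mer and its reverse
complement) are counted across a read set into a multiplicity histogram;
a peak-based model then reads off the quantities a k-mer profile reports
for a diploid: estimated genome size (len), unique-sequence fraction
(uniq), homozygosity/heterozygosity rates (aa/ab), heterozygous k-mer
coverage (kcov), read error rate (err), duplication rate (dup, not
estimated by this model), k-mer size (k) and ploidy (p).

The model is deliberately simple — error boundary at the first local
minimum of the histogram, het/hom peaks at kcov and 2*kcov — rather than a
negative-binomial mixture fit; it is meant for parameter recovery on
simulated data and desk-scale profiling, with k = 27 conventional for
151-bp short reads and k = 21 for HiFi-like long reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "KmerHistogram",
    "GenomeProfile",
    "count_kmers",
    "fit_genome_profile",
    "read_histogram",
    "write_histogram",
]

MAX_MULTIPLICITY = 1_000_000  # histogram tail saturates here, like -cs1000000 counters


@dataclass
class KmerHistogram:
    """Multiplicity -> distinct-canonical-k-mer-count mapping."""

    k: int
    entries: dict[int, int] = field(default_factory=dict)

    @property
    def total_kmers(self) -> int:
        return sum(m * c for m, c in self.entries.items())

    @property
    def n_distinct(self) -> int:
        return sum(self.entries.values())

    def as_array(self) -> np.ndarray:
        """Dense counts indexed by multiplicity (index 0 unused)."""
        if not self.entries:
            return np.zeros(1, dtype=np.int64)
        mmax = max(self.entries)
        arr = np.zeros(mmax + 1, dtype=np.int64)
        for m, c in self.entries.items():
            arr[m] = c
        return arr


def _encode_codes(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.uint8)
    for v, b in enumerate(b"ACGT"):
        table[b] = v
        table[b + 32] = v
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical k-mer integer codes for every valid position of one sequence."""
    n = len(codes)
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    c64 = codes.astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | c64[j : j + m]
        rev |= (np.uint64(3) - c64[j : j + m]) << np.uint64(2 * j)
    bad = (codes >= 4).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return np.minimum(fwd, rev)[valid]


def count_kmers(reads: Iterable[str] | Iterable[tuple[str, str]], k: int) -> KmerHistogram:
    """Count canonical k-mers over a read set into a multiplicity histogram.

    ``k`` must be odd (so no k-mer is its own reverse complement) and in
    [11, 31] to fit 2-bit codes in 64 bits.  k-mers containing non-ACGT
    characters are skipped.  The histogram conserves mass: the sum of
    multiplicity x count equals the number of valid k-mer positions.
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError("k must be odd and within [11, 31]")
    chunks: list[np.ndarray] = []
    for item in reads:
        seq = item if isinstance(item, str) else item[1]
        codes = _encode_codes(seq)
        kc = _kmer_codes(codes, k)
        if kc.size:
            chunks.append(kc)
    hist = KmerHistogram(k=k)
    if not chunks:
        return hist
    allk = np.concatenate(chunks)
    _, counts = np.unique(allk, return_counts=True)
    counts = np.minimum(counts, MAX_MULTIPLICITY)
    mult, mcount = np.unique(counts, return_counts=True)
    hist.entries = {int(m): int(c) for m, c in zip(mult, mcount)}
    return hist


@dataclass
class GenomeProfile:
    """Fitted spectrum quantities, named as a k-mer genome profile reports them."""

    len: int
    uniq: float
    aa: float
    ab: float
    kcov: float
    err: float
    dup: float | None
    k: int
    p: int = 2

    def to_dict(self) -> dict:
        return {
            "len": self.len,
            "uniq": self.uniq,
            "aa": self.aa,
            "ab": self.ab,
            "kcov": self.kcov,
            "err": self.err,
            "dup": self.dup,
            "k": self.k,
            "p": self.p,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _smooth3(h: np.ndarray) -> np.ndarray:
    out = h.astype(np.float64).copy()
    if len(h) > 3:
        out[1:-1] = (h[:-2] + h[1:-1] + h[2:]) / 3.0
    return out


def fit_genome_profile(hist: KmerHistogram, ploidy: int = 2, smooth: bool = False) -> GenomeProfile:
    """Peak-based profile fit on a k-mer multiplicity histogram.

    Steps: (1) the error boundary m0 is the first local minimum scanning up
    from multiplicity 1 — a monotone histogram cannot separate error k-mers
    and raises; (2) the dominant peak above m0 is located, and if a second
    local peak of at least 10% its height sits near twice its position the
    dominant peak is the heterozygous one (kcov = peak, homozygous coverage
    = 2*kcov), otherwise it is the homozygous peak; (3) genome size is the
    k-mer mass above m0 divided by homozygous coverage; (4) the heterozygous
    mass fraction f (twice the mass in (m0, kcov], see inline note) converts
    to a per-base rate via ab = 1 - (1 - f)^(1/k); (5) err is the mass at or
    below m0; (6) uniq is the single-copy mass in (m0, 1.5*hom] over
    hom * len.  dup is not estimated by this model and reported as None.
    """
    if ploidy != 2:
        raise ValueError("only diploid (p=2) profiles are supported")
    dense = hist.as_array()
    if len(dense) < 3 or hist.total_kmers == 0:
        raise ValueError("histogram too small to fit")
    h = _smooth3(dense) if smooth else dense.astype(np.float64)

    m0 = None
    for m in range(1, len(h) - 1):
        if h[m + 1] > h[m]:
            m0 = m
            break
    if m0 is None:
        raise ValueError("cannot separate error k-mers: histogram has no interior minimum")

    interior = h[m0 + 1 :]
    mp = int(np.argmax(interior)) + m0 + 1

    lo, hi = int(1.6 * mp), int(2.4 * mp) + 1
    second = None
    if lo < len(h):
        win = h[lo : min(hi, len(h))]
        if win.size:
            m2 = int(np.argmax(win)) + lo
            if (
                m2 > mp
                and h[m2] >= 0.1 * h[mp]
                and h[m2] >= h[max(m2 - 1, 0)] - 1e-9
                and (m2 + 1 >= len(h) or h[m2] >= h[m2 + 1] - 1e-9)
            ):
                second = m2
    def centroid(peak: int) -> float:
        # count-weighted centre of the peak; steadies the argmax of a noisy
        # discrete histogram (Poisson-wide peaks wobble the raw argmax)
        lo_w = max(1, int(0.85 * peak))
        hi_w = min(len(h) - 1, int(np.ceil(1.15 * peak)))
        w = h[lo_w : hi_w + 1]
        if w.sum() <= 0:
            return float(peak)
        return float(np.average(np.arange(lo_w, hi_w + 1), weights=w))

    if second is not None:
        kcov = centroid(mp)
        hom_cov = 2.0 * kcov
    else:
        hom_cov = centroid(mp)
        kcov = hom_cov / 2.0

    mults = np.arange(len(dense), dtype=np.float64)
    mass = mults * dense
    total_mass = float(mass.sum())
    genomic_mass = float(mass[m0 + 1 :].sum())
    if genomic_mass <= 0:
        raise ValueError("no k-mer mass above the error boundary")
    genome_len = genomic_mass / hom_cov

    # Heterozygous mass: twice the mass strictly below kcov.  The het peak is
    # near-symmetric about kcov while the homozygous peak (at 2*kcov) leaves
    # essentially no mass that far down, so doubling the left half isolates
    # the het component without absorbing the hom peak's lower tail.
    het_hi = int(np.floor(kcov))
    het_mass = 2.0 * float(mass[m0 + 1 : het_hi + 1].sum()) if het_hi > m0 else 0.0
    f_het = min(1.0, het_mass / genomic_mass)
    ab = 1.0 - (1.0 - f_het) ** (1.0 / hist.k)
    err = float(mass[: m0 + 1].sum()) / total_mass
    uniq_hi = int(np.floor(1.5 * hom_cov))
    uniq_mass = float(mass[m0 + 1 : uniq_hi + 1].sum())
    uniq = uniq_mass / (hom_cov * genome_len)

    return GenomeProfile(
        len=int(round(genome_len)),
        uniq=float(uniq),
        aa=float(1.0 - ab),
        ab=float(ab),
        kcov=float(kcov),
        err=float(err),
        dup=None,
        k=hist.k,
        p=2,
    )


def write_histogram(hist: KmerHistogram, path: str | Path) -> None:
    """Dump as two-column ``multiplicity count`` text, the common counter dialect."""
    with open(path, "w") as fh:
        for m in sorted(hist.entries):
            fh.write(f"{m} {hist.entries[m]}\n")


def read_histogram(path: str | Path, k: int = 27) -> KmerHistogram:
    """Parse a two-column histogram dump; ``#`` comment lines are skipped."""
    entries: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'multiplicity count', got {line!r}")
            try:
                m, c = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field in {line!r}") from exc
            if m < 1 or c < 0:
                raise ValueError(f"{path}:{lineno}: invalid multiplicity/count {line!r}")
            entries[m] = entries.get(m, 0) + c
    return KmerHistogram(k=k, entries=entries)
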