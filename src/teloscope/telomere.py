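"""Telomeric tandem-repeat discovery from trimmed read windows.

A telomeric repeat shows up in shotgun reads as a sequential, continuous
tandem array filling a read window.  The detector finds the smallest
primitive period of each window in the 6-10 bp range, merges rotations and
strands into a canonical display form (G-rich strand, G-run-terminal
rotation), classifies the unit against a catalog of eight known plant/algal
telomere motifs — admitting near-miss units as novel candidates — and
aggregates per-motif window and copy counts into a per-sample abundance
table from which the sample's telomeric repeat is called.

The catalog covers: TTTAGGG (Arabidopsis-type), TTAGGG (vertebrate-type),
TTTTAGGG (Chlamydomonas-type), TTCAGG and TTTCAGG (Genlisea-type), TTTTAGG
(Klebsormidium-type), TTTTTTAGGG (Cestrum-type) and TTCAGGG (Papaver-type).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TelomereMotif",
    "TandemHit",
    "MotifCountTable",
    "default_catalog",
    "find_tandem_unit",
    "canonical_form",
    "canonical_key",
    "circular_edit_distance",
    "classify_unit",
    "profile_sample",
    "call_sample_telomere",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _rotations(s: str):
    return (s[i:] + s[:i] for i in range(len(s)))


def canonical_key(unit: str) -> str:
    """Lexicographically minimal rotation over both strands."""
    return min(min(_rotations(unit)), min(_rotations(_revcomp(unit))))


def _trailing_run(s: str, ch: str) -> int:
    n = 0
    for c in reversed(s):
        if c != ch:
            break
        n += 1
    return n


def _leading_run(s: str, ch: str) -> int:
    n = 0
    for c in s:
        if c != ch:
            break
        n += 1
    return n


def canonical_form(unit: str) -> str:
    """Collapse rotation and strand into one display form.

    Strand choice: the G-rich strand (more G than C; on a tie, the strand
    whose minimal rotation sorts first).  Rotation choice: the rotation
    ending in the longest G-run, ties broken by the longest leading T-run,
    then lexicographically.  E.g. TAGGGTT, CCCTAAA and TTTAGGG all map to
    TTTAGGG.
    """
    if not unit or set(unit) - set("ACGT"):
        raise ValueError(f"unit must be non-empty ACGT: {unit!r}")
    rc = _revcomp(unit)
    g, c = unit.count("G"), unit.count("C")
    if g > c:
        strand = unit
    elif c > g:
        strand = rc
    else:
        strand = unit if min(_rotations(unit)) <= min(_rotations(rc)) else rc
    best = max(
        _rotations(strand),
        key=lambda r: (_trailing_run(r, "G"), _leading_run(r, "T"), [-ord(ch) for ch in r]),
    )
    return best


@dataclass(frozen=True)
class TelomereMotif:
    """A telomeric repeat unit in display form plus its strand/rotation key."""

    display_form: str
    family_name: str
    source: str = "catalog"  # catalog | novel_candidate

    def __post_init__(self) -> None:
        object.__setattr__(self, "display_form", self.display_form.upper())

    @property
    def canonical_key(self) -> str:
        return canonical_key(self.display_form)

    def __len__(self) -> int:
        return len(self.display_form)


_CATALOG_SPEC = (
    ("TTTAGGG", "Arabidopsis-type"),
    ("TTAGGG", "vertebrate-type"),
    ("TTTTAGGG", "Chlamydomonas-type"),
    ("TTCAGG", "Genlisea-type"),
    ("TTTCAGG", "Genlisea-type"),
    ("TTTTAGG", "Klebsormidium-type"),
    ("TTTTTTAGGG", "Cestrum-type"),
    ("TTCAGGG", "Papaver-type"),
)


def default_catalog() -> list[TelomereMotif]:
    """The eight-motif plant telomere catalog used for classification."""
    return [TelomereMotif(m, fam) for m, fam in _CATALOG_SPEC]


def _is_primitive(unit: str) -> bool:
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


@dataclass(frozen=True)
class TandemHit:
    window_id: str
    unit: str
    copies: int
    motif: TelomereMotif | None = None


def find_tandem_unit(
    window: str,
    unit_min: int = 6,
    unit_max: int = 10,
    max_mismatch: int = 0,
    min_copies: int = 4,
) -> tuple[str, int] | None:
    """Smallest primitive period of a window in ``[unit_min, unit_max]``.

    A period ``u`` qualifies when ``window[i] == window[i+u]`` holds with at
    most ``max_mismatch`` violations (N never matches anything) and the
    window holds at least ``min_copies`` complete copies.  The unit returned
    is the per-position majority over the complete copies (the plain prefix
    when no mismatches are allowed); non-primitive units — homopolymers and
    short microsatellites dressed up as a longer period — are rejected.
    """
    w = len(window)
    window = window.upper()
    for u in range(unit_min, unit_max + 1):
        if w // u < min_copies:
            continue
        mism = 0
        for i in range(w - u):
            a, b = window[i], window[i + u]
            if a != b or a == "N":
                mism += 1
                if mism > max_mismatch:
                    break
        if mism > max_mismatch:
            continue
        copies = w // u
        if max_mismatch == 0:
            unit = window[:u]
        else:
            cols = [window[j * u : (j + 1) * u] for j in range(copies)]
            unit = "".join(
                max("ACGT", key=lambda ch: sum(1 for col in cols if col[p] == ch)) for p in range(u)
            )
        if "N" in unit:
            continue
        if _is_primitive(unit):
            return unit, copies
    return None


def _levenshtein(a: str, b: str) -> int:
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def circular_edit_distance(query: str, target: str) -> int:
    """Minimum Levenshtein distance over all rotations of both strands of ``query``."""
    best = len(query) + len(target)
    for strand in (query, _revcomp(query)):
        for rot in _rotations(strand):
            d = _levenshtein(rot, target)
            if d < best:
                best = d
    return best


def _has_gg(display: str) -> bool:
    doubled = display + display[0]
    return "GG" in doubled


def classify_unit(
    display_form: str,
    catalog: Sequence[TelomereMotif] | None = None,
    max_circular_edit: int = 1,
) -> TelomereMotif | None:
    """Resolve a canonical unit against the telomere catalog.

    Exact key matches return the catalog motif.  Units within
    ``max_circular_edit`` of any catalog motif that retain a G-run of at
    least 2 are reported as novel candidates (this is how a previously
    undescribed motif such as TTCAGGG surfaces when absent from the
    catalog); everything else — generic microsatellites — returns None.
    """
    catalog = default_catalog() if catalog is None else list(catalog)
    key = canonical_key(display_form)
    for motif in catalog:
        if motif.canonical_key == key:
            return motif
    if not _has_gg(display_form):
        return None
    best_d = max_circular_edit + 1
    nearest = None
    for motif in catalog:
        d = circular_edit_distance(display_form, motif.display_form)
        if d < best_d:
            best_d, nearest = d, motif
    if nearest is not None and best_d <= max_circular_edit:
        return TelomereMotif(
            display_form,
            family_name=f"novel ({best_d} edit from {nearest.display_form})",
            source="novel_candidate",
        )
    return None


@dataclass
class MotifCountTable:
    """Per-sample telomere-like motif abundances.

    ``rows`` maps display form to window count, copy count, family and
    source.  Relative abundance is normalized over telomere-like hits only
    (catalog matches plus novel candidates); tandem windows that resolve to
    no telomere motif are tallied in ``n_other_tandem``.
    """

    sample_id: str
    rows: dict[str, dict] = field(default_factory=dict)
    n_windows: int = 0
    n_tandem: int = 0
    n_other_tandem: int = 0

    def add_hit(self, motif: TelomereMotif, copies: int) -> None:
        row = self.rows.setdefault(
            motif.display_form,
            {"family": motif.family_name, "source": motif.source, "windows": 0, "copies": 0},
        )
        row["windows"] += 1
        row["copies"] += copies

    @property
    def total_telomeric_windows(self) -> int:
        return sum(r["windows"] for r in self.rows.values())

    def relative_abundance(self) -> dict[str, float]:
        total = self.total_telomeric_windows
        if total == 0:
            return {}
        return {m: r["windows"] / total for m, r in self.rows.items()}

    def to_dataframe(self) -> pd.DataFrame:
        rel = self.relative_abundance()
        records = [
            {
                "sample": self.sample_id,
                "motif": m,
                "family": r["family"],
                "source": r["source"],
                "windows": r["windows"],
                "copies": r["copies"],
                "relative_abundance": rel.get(m, 0.0),
            }
            for m, r in sorted(self.rows.items(), key=lambda kv: -kv[1]["windows"])
        ]
        return pd.DataFrame.from_records(
            records,
            columns=["sample", "motif", "family", "source", "windows", "copies", "relative_abundance"],
        )


def _batch_find_units(
    windows: list[tuple[str, str]],
    unit_min: int,
    unit_max: int,
    max_mismatch: int,
    min_copies: int,
) -> list[tuple[str, str, int]]:
    """Vectorized periodicity scan over equal-length windows.

    Computes, for every candidate period at once, the mismatch count of
    ``w[i] != w[i+u]`` across the whole batch, then resolves the few passing
    windows through :func:`find_tandem_unit` so primitivity handling and
    consensus extraction stay in one place.
    """
    hits: list[tuple[str, str, int]] = []
    by_len: dict[int, list[int]] = {}
    for idx, (_, w) in enumerate(windows):
        by_len.setdefault(len(w), []).append(idx)
    for wlen, idxs in by_len.items():
        if wlen < unit_min * min_copies:
            continue
        mat = np.frombuffer("".join(windows[i][1] for i in idxs).encode(), dtype=np.uint8).reshape(
            len(idxs), wlen
        )
        is_n = mat == ord("N")
        candidate = np.zeros(len(idxs), dtype=bool)
        for u in range(unit_min, unit_max + 1):
            if wlen // u < min_copies:
                continue
            mism = (mat[:, : wlen - u] != mat[:, u:]) | is_n[:, : wlen - u]
            candidate |= mism.sum(axis=1) <= max_mismatch
        for j in np.flatnonzero(candidate).tolist():
            idx = idxs[j]
            wid, w = windows[idx]
            res = find_tandem_unit(w, unit_min, unit_max, max_mismatch, min_copies)
            if res is not None:
                hits.append((wid, res[0], res[1]))
    return hits


def profile_sample(
    windows: Iterable[tuple[str, str]] | Iterable[str],
    catalog: Sequence[TelomereMotif] | None = None,
    sample_id: str = "sample",
    unit_min: int = 6,
    unit_max: int = 10,
    max_mismatch: int = 0,
    min_copies: int = 4,
    max_circular_edit: int = 1,
) -> MotifCountTable:
    """Scan windows for tandem units and aggregate telomere-motif counts."""
    catalog = default_catalog() if catalog is None else list(catalog)
    table = MotifCountTable(sample_id=sample_id)
    wlist: list[tuple[str, str]] = []
    for i, item in enumerate(windows):
        if isinstance(item, str):
            wlist.append((f"w{i}", item.upper()))
        else:
            wlist.append((item[0], item[1].upper()))
    table.n_windows = len(wlist)
    hits = _batch_find_units(wlist, unit_min, unit_max, max_mismatch, min_copies)
    table.n_tandem = len(hits)
    classify_cache: dict[str, TelomereMotif | None] = {}
    for _wid, unit, copies in hits:
        display = canonical_form(unit)
        if display not in classify_cache:
            classify_cache[display] = classify_unit(display, catalog, max_circular_edit)
        motif = classify_cache[display]
        if motif is None:
            table.n_other_tandem += 1
        else:
            table.add_hit(motif, copies)
    return table


def call_sample_telomere(
    table: MotifCountTable,
    min_windows: int = 50,
    min_fraction: float = 0.5,
) -> dict:
    """Call the sample's telomeric repeat from its motif count table.

    Returns a record with ``call`` set to the winning display form, or to
    ``"undetermined"`` on an empty table, a tie, or a winner below the
    window-count / abundance-fraction thresholds (candidates are listed
    either way).
    """
    rel = table.relative_abundance()
    record: dict = {"sample": table.sample_id, "call": "undetermined", "candidates": []}
    if not rel:
        return record
    ranked = sorted(rel.items(), key=lambda kv: (-kv[1], kv[0]))
    record["candidates"] = [
        {
            "motif": m,
            "family": table.rows[m]["family"],
            "source": table.rows[m]["source"],
            "windows": table.rows[m]["windows"],
            "relative_abundance": frac,
        }
        for m, frac in ranked
    ]
    top_motif, top_frac = ranked[0]
    tied = [m for m, f in ranked if table.rows[m]["windows"] == table.rows[top_motif]["windows"]]
    if len(tied) > 1:
        return record
    if table.rows[top_motif]["windows"] >= min_windows and top_frac >= min_fraction:
        record["call"] = top_motif
        record["family"] = table.rows[top_motif]["family"]
        record["source"] = table.rows[top_motif]["source"]
    return record
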