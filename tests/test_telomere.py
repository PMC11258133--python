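"""Tandem-unit detection, canonicalization, classification and calling."""

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import teloscope as t
from teloscope.telomere import (
    _revcomp,
    canonical_form,
    canonical_key,
    circular_edit_distance,
    classify_unit,
    default_catalog,
    find_tandem_unit,
    profile_sample,
)


def brute_force_smallest_period(window: str, lo: int, hi: int, min_copies: int):
    """Independent oracle: smallest exactly-periodic primitive unit in range."""
    for u in range(lo, hi + 1):
        if len(window) // u < min_copies:
            continue
        if any(window[i] != window[i + u] or window[i] == "N" for i in range(len(window) - u)):
            continue
        unit = window[:u]
        if "N" in unit:
            continue
        if all(unit != unit[:d] * (u // d) for d in range(1, u) if u % d == 0):
            return unit, len(window) // u
    return None


class TestFindTandemUnit:
    def test_telomere_window_with_partial_last_copy(self):
        window = ("TTTAGGG" * 9)[:60]  # 8 full copies + 4 bp
        assert find_tandem_unit(window) == ("TTTAGGG", 8)
        assert brute_force_smallest_period(window, 6, 10, 4) == ("TTTAGGG", 8)

    def test_homopolymer_and_dinucleotide_excluded(self):
        assert find_tandem_unit("A" * 60) is None
        assert find_tandem_unit("AC" * 30) is None

    def test_random_windows_essentially_never_hit(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(1000):
            w = "".join(rng.choice(list("ACGT"), 60))
            if find_tandem_unit(w) is not None:
                hits += 1
        assert hits == 0

    def test_n_counts_as_mismatch(self):
        window = ("TTTAGGG" * 9)[:60]
        broken = window[:20] + "N" + window[21:]
        assert find_tandem_unit(broken) is None
        assert find_tandem_unit(broken, max_mismatch=2) == ("TTTAGGG", 8)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=12, max_size=30), st.integers(0, 2**31 - 1))
    def test_agrees_with_brute_force_oracle(self, window, seed):
        # also exercise periodic windows, not just random text
        rng = np.random.default_rng(seed)
        unit = "".join(rng.choice(list("ACGT"), rng.integers(2, 11)))
        periodic = (unit * 30)[: len(window)]
        for w in (window, periodic):
            got = find_tandem_unit(w, min_copies=2)
            want = brute_force_smallest_period(w, 6, 10, 2)
            assert got == want


class TestCanonicalForm:
    @pytest.mark.parametrize(
        "unit,expected",
        [("TAGGGTT", "TTTAGGG"), ("CCCTAAA", "TTTAGGG"), ("GGTTAG", "TTAGGG")],
    )
    def test_rotations_and_strand_merge(self, unit, expected):
        assert canonical_form(unit) == expected

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            canonical_form("TTNAGGG")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=10), st.data())
    def test_rotation_strand_closure(self, unit, data):
        """canonical_form is invariant under rotation and reverse complement."""
        base = canonical_form(unit)
        rot = data.draw(st.integers(0, len(unit) - 1))
        assert canonical_form(unit[rot:] + unit[:rot]) == base
        assert canonical_form(_revcomp(unit)) == base

    def test_closure_for_all_catalog_motifs(self):
        for motif in default_catalog():
            m = motif.display_form
            for r in range(len(m)):
                rot = m[r:] + m[:r]
                assert canonical_form(rot) == m
                assert canonical_form(_revcomp(rot)) == m


class TestCircularEditDistance:
    def test_matches_edlib_oracle_on_catalog_pairs(self):
        motifs = [m.display_form for m in default_catalog()]
        for a in motifs:
            for b in motifs:
                oracle = min(
                    edlib.align(rot, b, task="distance", mode="NW")["editDistance"]
                    for strand in (a, _revcomp(a))
                    for rot in (strand[i:] + strand[:i] for i in range(len(strand)))
                )
                assert circular_edit_distance(a, b) == oracle

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=10),
           st.text(alphabet="ACGT", min_size=2, max_size=10))
    def test_matches_edlib_oracle_on_random_units(self, a, b):
        oracle = min(
            edlib.align(rot, b, task="distance", mode="NW")["editDistance"]
            for strand in (a, _revcomp(a))
            for rot in (strand[i:] + strand[:i] for i in range(len(strand)))
        )
        assert circular_edit_distance(a, b) == oracle


class TestClassifyUnit:
    def test_catalog_match(self):
        m = classify_unit("TTTAGGG")
        assert m is not None and m.family_name == "Arabidopsis-type" and m.source == "catalog"

    def test_novel_candidate_one_edit_away(self):
        catalog = [m for m in default_catalog() if m.display_form != "TTCAGGG"]
        m = classify_unit("TTCAGGG", catalog)
        assert m is not None and m.source == "novel_candidate"
        assert m.display_form == "TTCAGGG"

    def test_microsatellite_rejected(self):
        assert classify_unit("ACACAC") is None

    def test_rotated_and_complemented_units_match_catalog(self):
        m = classify_unit(canonical_form("CCCTAAA"))
        assert m is not None and m.display_form == "TTTAGGG"

    def test_catalog_has_eight_motif_entries(self):
        catalog = default_catalog()
        assert len(catalog) == 8
        assert all(6 <= len(m) <= 10 for m in catalog)
        assert len({m.canonical_key for m in catalog}) == 8


class TestProfileAndCall:
    def test_constructed_window_mix(self):
        windows = [("TTTAGGG" * 9)[:60]] * 10
        rng = np.random.default_rng(1)
        windows += ["".join(rng.choice(list("ACGT"), 60)) for _ in range(90)]
        table = profile_sample(windows, sample_id="s1")
        assert table.rows["TTTAGGG"]["windows"] == 10
        assert table.relative_abundance()["TTTAGGG"] == 1.0
        df = table.to_dataframe()
        assert list(df.columns) == [
            "sample", "motif", "family", "source", "windows", "copies", "relative_abundance",
        ]

    def test_empty_stream(self):
        table = profile_sample([])
        assert table.rows == {}
        assert t.call_sample_telomere(table)["call"] == "undetermined"

    def test_call_thresholds_and_ties(self):
        table = t.MotifCountTable(sample_id="s")
        arab = default_catalog()[0]
        vert = default_catalog()[1]
        for _ in range(5000):
            table.add_hit(arab, 8)
        for _ in range(60):
            table.add_hit(vert, 10)
        assert t.call_sample_telomere(table)["call"] == "TTTAGGG"

        small = t.MotifCountTable(sample_id="s")
        for _ in range(10):
            small.add_hit(arab, 8)
        assert t.call_sample_telomere(small, min_windows=50)["call"] == "undetermined"

        tie = t.MotifCountTable(sample_id="s")
        for _ in range(100):
            tie.add_hit(arab, 8)
            tie.add_hit(vert, 10)
        res = t.call_sample_telomere(tie)
        assert res["call"] == "undetermined"
        assert {c["motif"] for c in res["candidates"]} == {"TTTAGGG", "TTAGGG"}

    def test_planted_truth_recovery_from_reads(self, small_genome):
        a, b, truth = small_genome
        pool = t.diploid_pool(a, b)
        reads = t.simulate_short_reads(pool, 60_000, error_rate=0.001, seed=2)
        res = t.trim_reads(reads)
        table = profile_sample(res.windows, sample_id="planted")
        call = t.call_sample_telomere(table)
        assert call["call"] == truth.telomere_motif == "TTCAGGG"
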