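"""Assembly statistics, parsers, binning, median split, SV spectrum and
gene x SV intersection."""

import numpy as np
import pytest

import teloscope as t
from teloscope import qc
from teloscope.synthetic import reverse_complement


def n50_oracle(lengths):
    lengths = sorted(lengths, reverse=True)
    total = sum(lengths)
    cum = 0
    for L in lengths:
        cum += L
        if cum >= total / 2:
            return L


class TestAssemblyStats:
    def test_hand_example(self):
        s = qc.assembly_stats([40, 30, 20, 10])
        assert (s.total_size, s.n50, s.max_contig, s.n_contigs) == (100, 30, 40, 4)

    def test_single_and_equal_contigs(self):
        s = qc.assembly_stats([77])
        assert s.n50 == s.max_contig == s.total_size == 77
        s = qc.assembly_stats([50, 50, 50])
        assert s.n50 == 50

    def test_matches_sort_and_scan_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            lengths = rng.integers(1, 10_000, rng.integers(1, 30)).tolist()
            assert qc.assembly_stats(lengths).n50 == n50_oracle(lengths)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            qc.assembly_stats([])


class TestScanContigEnds:
    def test_g_strand_cluster_at_three_prime(self):
        rng = np.random.default_rng(1)
        body = "".join(rng.choice(list("ACGT"), 5000))
        contig = body + "TTTAGGG" * 30
        calls = qc.scan_contig_ends({"c1": contig}, "TTTAGGG")
        assert len(calls) == 1
        c = calls[0]
        assert (c.end, c.copies, c.motif) == ("3'", 30, "TTTAGGG")
        assert c.span == 30 * 7

    def test_c_strand_cluster_at_five_prime(self):
        rng = np.random.default_rng(2)
        body = "".join(rng.choice(list("ACGT"), 5000))
        contig = reverse_complement("TTTAGGG") * 30 + body
        assert contig.startswith("CCCTAAA")
        calls = qc.scan_contig_ends({"c1": contig}, "TTTAGGG")
        assert len(calls) == 1
        assert (calls[0].end, calls[0].motif) == ("5'", "TTTAGGG")

    def test_telomere_free_contig_silent(self):
        rng = np.random.default_rng(3)
        contig = "".join(rng.choice(list("ACGT"), 20_000))
        assert qc.scan_contig_ends({"c1": contig}, "TTTAGGG") == []

    def test_gap_splits_clusters(self):
        arr = "TTTAGGG" * 8 + "A" * 100 + "TTTAGGG" * 8
        contig = "ACGT" * 2000 + arr
        calls = qc.scan_contig_ends({"c1": contig}, "TTTAGGG", min_copies=5)
        assert [c.copies for c in calls] == [8, 8]

    def test_recovers_planted_assembly_ends(self, small_genome):
        a, _, truth = small_genome
        calls = qc.scan_contig_ends(a, truth.telomere_motif, min_copies=10)
        got = {(c.contig, c.end) for c in calls}
        want = {(c, e) for c in truth.chrom_lengths for e in ("5'", "3'")}
        assert got == want
        assert all(c.copies >= 100 for c in calls)


class TestRepeatMaskerParser:
    def test_single_record_category_total(self, tmp_path):
        path = tmp_path / "one.out"
        path.write_text(
            "   SW   perc perc perc  query  position in query  matching repeat  position in repeat\n"
            "score   div. del. ins.  sequence begin end (left) repeat class/family begin end (left) ID\n"
            "\n"
            "  463 11.5 0.0 0.0 chr1 501 1000 (9000) + LTR7 LTR/Copia 1 500 (0) 1\n"
        )
        ivs, totals = qc.parse_repeatmasker_out(path)
        assert len(ivs) == 1
        assert ivs[0].start == 500 and ivs[0].end == 1000
        assert totals["Retroelement"] == 500
        assert sum(v for k, v in totals.items() if k != "Retroelement") == 0

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.out"
        path.write_text("h1\nh2\n\n  463 11.5 0.0 0.0 chr1 oops\n")
        with pytest.raises(ValueError, match=":4:"):
            qc.parse_repeatmasker_out(path)

    @pytest.mark.parametrize(
        "rm_class,category",
        [
            ("LTR/Gypsy", "Retroelement"), ("LINE/L1", "Retroelement"),
            ("SINE/tRNA", "Retroelement"), ("DNA/hAT-Ac", "DNA transposon"),
            ("RC/Helitron", "Rolling-circle"), ("snRNA", "Small RNA"),
            ("rRNA", "Small RNA"), ("Satellite", "Satellite"),
            ("Simple_repeat", "Simple repeat"), ("Low_complexity", "Low complexity"),
            ("Unknown", "Unclassified"),
        ],
    )
    def test_class_mapping(self, rm_class, category):
        assert qc.repeat_class_category(rm_class) == category

    def test_fixture_round_trip(self, fixture_files):
        paths, truth = fixture_files
        ivs, _ = qc.parse_repeatmasker_out(paths["repeats_out"])
        got = {(iv.contig, iv.start, iv.end, iv.attr("family")) for iv in ivs}
        want = {(c, s, e, f) for c, r in truth.repeats.items() for s, e, f in r}
        assert got == want


class TestSVFilterSpectrum:
    def test_fifty_bp_floor(self, tmp_path):
        truth = t.TruthSet(
            telomere_motif="TTTAGGG", chrom_lengths={"chr1": 10_000},
            snps=[], repeats={},
            svs=[t.synthetic.SVTruth("chr1", 100 * (i + 1), "DEL", L) for i, L in enumerate([49, 50, 51])],
        )
        paths = t.emit_annotation_fixtures(truth, tmp_path)
        svs, counts, _ = qc.filter_and_spectrum_svs(paths["sv_vcf"])
        assert sorted(s.length for s in svs) == [50, 51]
        assert min(s.length for s in svs) == 50
        assert counts["DEL"] == 2

    def test_type_spectrum_counts(self, fixture_files):
        paths, truth = fixture_files
        svs, counts, hists = qc.filter_and_spectrum_svs(paths["sv_vcf"])
        want = {}
        for sv in truth.svs:
            if sv.length >= 50:
                want[sv.svtype] = want.get(sv.svtype, 0) + 1
        assert {k: v for k, v in counts.items() if v} == want
        for cat, (h, edges) in hists.items():
            assert h.sum() == counts[cat]

    def test_filter_is_idempotent(self, fixture_files):
        paths, _ = fixture_files
        svs1, _, _ = qc.filter_and_spectrum_svs(paths["sv_vcf"])
        assert all(s.length >= 50 for s in svs1)

    def test_end_fallback_when_svlen_absent(self, tmp_path):
        path = tmp_path / "sv.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=10000>\n"
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
            '##INFO=<ID=END,Number=1,Type=Integer,Description="e">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t101\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=200\n"
        )
        svs, _, _ = qc.filter_and_spectrum_svs(path)
        assert svs[0].length == 99  # END - POS


class TestBins:
    def test_tiling_arithmetic(self):
        bins = qc.compute_bins({"c": 250_000})
        assert [(b.start, b.end) for b in bins] == [(0, 100_000), (100_000, 200_000), (200_000, 250_000)]
        assert bins[0].width == 100_000

    def test_min_contig_len_filter(self):
        bins = qc.compute_bins({"big": 1_200_000, "small": 250_000}, min_contig_len=1_000_000)
        assert {b.contig for b in bins} == {"big"}

    def test_saturated_repeat_bin(self):
        ivs = [qc.FeatureInterval("c", 0, 120_000, "repeat")]
        bins = qc.compute_bins({"c": 150_000}, repeat_intervals=ivs)
        assert bins[0].repeat_ratio == 1.0

    def test_depth_and_repeat_conservation(self, fixture_files, small_genome):
        paths, truth = fixture_files
        depth = qc.read_depth_tsv(paths["depth_tsv"])
        ivs, _ = qc.parse_repeatmasker_out(paths["repeats_out"])
        bins = qc.compute_bins(truth.chrom_lengths, depth=depth, repeat_intervals=ivs)
        # depth conservation, exact per contig
        for contig in truth.chrom_lengths:
            got = sum(b.depth_sum for b in bins if b.contig == contig)
            want = int(depth[depth.contig == contig].depth.sum())
            assert got == want
        # repeat-mass conservation, exact (truth intervals are disjoint)
        got_mass = sum(round(b.repeat_ratio * b.width) for b in bins)
        want_mass = sum(e - s for r in truth.repeats.values() for s, e, _ in r)
        assert got_mass == want_mass

    def test_depth_on_unknown_contig_or_bad_position_rejected(self):
        import pandas as pd

        bad = pd.DataFrame({"contig": ["ghost"], "pos": [1], "depth": [5]})
        with pytest.raises(ValueError, match="unknown contig"):
            qc.compute_bins({"c": 1000}, depth=bad)
        over = pd.DataFrame({"contig": ["c"], "pos": [2000], "depth": [5]})
        with pytest.raises(ValueError, match="outside"):
            qc.compute_bins({"c": 1000}, depth=over)

    def test_feature_counts_assigned_by_start(self, fixture_files, small_genome):
        paths, truth = fixture_files
        genes, _ = qc.read_gff3_features(paths["genes_gff"])
        snps = qc.read_snp_positions(paths["snp_vcf"])
        svs, _, _ = qc.filter_and_spectrum_svs(paths["sv_vcf"])
        bins = qc.compute_bins(truth.chrom_lengths, genes=genes, snps=snps, svs=svs)
        assert sum(b.gene_count for b in bins) == len(truth.genes)
        assert sum(b.snp_count for b in bins) == len(truth.snps)
        assert sum(b.sv_count for b in bins) == sum(1 for s in truth.svs if s.length >= 50)


class TestRepeatSplit:
    def test_direct_computation(self):
        bins = []
        for ratio, depth in zip([0.1, 0.2, 0.8, 0.9], [10, 10, 30, 30]):
            b = qc.GenomicBin("c", 0, 100)
            b.repeat_ratio, b.depth_mean = ratio, depth
            bins.append(b)
        s = qc.repeat_split_depth_summary(bins)
        assert s["threshold"] == 0.5
        assert s["less_repetitive"]["median_depth"] == 10
        assert s["more_repetitive"]["median_depth"] == 30
        assert s["less_repetitive"]["n"] == s["more_repetitive"]["n"] == 2

    def test_all_equal_ratios_degenerate(self):
        bins = []
        for depth in (5, 7, 9):
            b = qc.GenomicBin("c", 0, 100)
            b.repeat_ratio, b.depth_mean = 0.3, depth
            bins.append(b)
        s = qc.repeat_split_depth_summary(bins)
        assert s["less_repetitive"]["n"] == 3
        assert s["more_repetitive"]["n"] == 0
        assert s["more_repetitive"]["median_depth"] is None

    def test_two_bins(self):
        bins = []
        for ratio, depth in zip([0.2, 0.8], [11.0, 22.0]):
            b = qc.GenomicBin("c", 0, 100)
            b.repeat_ratio, b.depth_mean = ratio, depth
            bins.append(b)
        s = qc.repeat_split_depth_summary(bins)
        assert s["less_repetitive"]["median_depth"] == 11.0
        assert s["more_repetitive"]["median_depth"] == 22.0
        with pytest.raises(ValueError):
            qc.repeat_split_depth_summary(bins[:1])


def brute_force_affected(cds_list, svs):
    hit = set()
    for cds in cds_list:
        for sv in svs:
            s, e = sv.footprint
            if cds.contig == sv.contig and max(cds.start, s) < min(cds.end, e):
                hit.add(cds.attr("gene_id"))
    return hit


class TestGenesAffectedBySV:
    def test_overlap_and_half_open_adjacency(self):
        cds = [qc.FeatureInterval("c", 100, 200, "CDS", (("gene_id", "g1"),))]
        hit = [qc.SVRecord("c", 151, "DEL", 10)]  # footprint [150,160)
        assert qc.genes_affected_by_sv(cds, hit)[0] == 1
        adjacent = [qc.SVRecord("c", 201, "DEL", 50)]  # footprint [200,250)
        assert qc.genes_affected_by_sv(cds, adjacent)[0] == 0

    def test_gene_with_multiple_cds_counted_once(self):
        cds = [
            qc.FeatureInterval("c", s, s + 30, "CDS", (("gene_id", "g1"),))
            for s in (100, 200, 300)
        ]
        sv = [qc.SVRecord("c", 51, "DEL", 400)]
        n, per_gene = qc.genes_affected_by_sv(cds, sv)
        assert n == 1 and set(per_gene) == {"g1"}

    def test_insertion_footprint_is_one_bp(self):
        cds = [qc.FeatureInterval("c", 100, 200, "CDS", (("gene_id", "g1"),))]
        inside = [qc.SVRecord("c", 150, "INS", 500)]
        outside = [qc.SVRecord("c", 201, "INS", 500)]
        assert qc.genes_affected_by_sv(cds, inside)[0] == 1
        assert qc.genes_affected_by_sv(cds, outside)[0] == 0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            cds = []
            for gi in range(rng.integers(1, 15)):
                contig = f"c{rng.integers(1, 3)}"
                for _ in range(rng.integers(1, 4)):
                    s = int(rng.integers(0, 5000))
                    cds.append(
                        qc.FeatureInterval(contig, s, s + int(rng.integers(10, 300)), "CDS",
                                           (("gene_id", f"g{gi}"),))
                    )
            svs = []
            for _ in range(rng.integers(0, 10)):
                svtype = ["DEL", "INS", "INV", "DUP:TANDEM"][rng.integers(0, 4)]
                svs.append(
                    qc.SVRecord(f"c{rng.integers(1, 3)}", int(rng.integers(1, 5200)),
                                svtype, int(rng.integers(50, 500)))
                )
            n, per_gene = qc.genes_affected_by_sv(cds, svs)
            want = brute_force_affected(cds, svs)
            assert set(per_gene) == want and n == len(want)
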