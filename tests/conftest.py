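import pytest

import teloscope as t


@pytest.fixture(scope="session")
def small_spec():
    return t.SyntheticGenomeSpec(
        n_chromosomes=2,
        chrom_length_bp=150_000,
        telomere_motif="TTCAGGG",
        telomere_copies_per_end=100,
        repeat_fraction=0.15,
        snp_rate=0.002,
        sv_events=(
            ("DEL", 80, 3),
            ("INS", 60, 2),
            ("INV", 120, 1),
            ("DUP:TANDEM", 70, 1),
            ("DUP:INT", 90, 1),
        ),
        genes_per_chrom=8,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_genome(small_spec):
    """(hap_a, hap_b, truth) for a 2x150 kb diploid with every feature planted."""
    return t.simulate_genome(small_spec)


@pytest.fixture(scope="session")
def fixture_files(small_genome, tmp_path_factory):
    """Annotation fixture files emitted from the small genome's truth."""
    _, _, truth = small_genome
    out = tmp_path_factory.mktemp("fixtures")
    return t.emit_annotation_fixtures(truth, out, depth_mean=40.0, seed=1), truth
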