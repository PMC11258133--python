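# teloscope

Telomeric-repeat discovery from raw short reads, k-mer-spectrum genome
profiling, and assembly-QC density tracks — aimed at the kind of survey a
plant genomics group runs on a panel of newly sequenced species: what is each
species' telomeric repeat, how big and how heterozygous is each genome, and
how well does a draft assembly hold up along its contigs.

Plant telomeres are short tandem arrays (the canonical *Arabidopsis*-type
unit is TTTAGGG) but the unit varies across lineages, and occasionally a
species carries a motif nobody has described. Because a telomeric repeat
appears in shotgun reads as a *sequential, continuous* tandem array filling a
read, it can be called directly from raw FASTQ — no assembly needed — by
scanning fixed 60-bp read windows for their smallest primitive period,
merging rotations and strands, and tallying motifs against a catalog of
eight known telomere units. Near-misses (circular edit distance 1 from a
catalog unit, with an intact G-run) are reported as novel candidates, which
is exactly how a previously undescribed unit such as TTCAGGG surfaces.

The package has six parts, usable as a library or through the `teloscope`
CLI:

- `teloscope.synthetic` — diploid genome/read/annotation simulator with exact
  ground truth (telomere arrays, interspersed repeats, SNPs, SVs, genes);
- `teloscope.read_prep` — seeded uniform subsampling (default 20 M reads) and
  fixed interior-window trimming (keep bases 10–69 of a 151-bp read);
- `teloscope.telomere` — tandem-unit detection, canonicalization,
  classification, per-sample motif abundance table and the telomere call;
- `teloscope.kmer` — canonical k-mer counting (k = 27 for short reads, 21 for
  HiFi-like reads) and a peak-based spectrum fit reporting
  `len, uniq, aa, ab, kcov, err, dup, k, p`;
- `teloscope.qc` — contig stats (N50), contig-end telomere scan, RepeatMasker
  .out/GFF3/VCF/depth parsing, 100-kb binned tracks, repeat-vs-depth median
  split, ≥ 50 bp SV spectra, gene×SV intersection;
- `teloscope.circos` / `teloscope.pipeline` — Circos karyotype/track export
  and a one-config end-to-end driver.

## Worked example

Simulate a 150-kb diploid carrying the (real, but once-novel) TTCAGGG
telomere, sequence it, and call the motif back:

```python
import teloscope as t

spec = t.SyntheticGenomeSpec(
    n_chromosomes=1, chrom_length_bp=150_000,
    telomere_motif="TTCAGGG", telomere_copies_per_end=120,
    repeat_fraction=0.05, snp_rate=0.001, seed=7,
)
hap_a, hap_b, truth = t.simulate_genome(spec)
reads = t.simulate_short_reads(t.diploid_pool(hap_a, hap_b), 100_000,
                               error_rate=0.001, seed=8)
windows = t.trim_reads(reads).windows
table = t.profile_sample(windows, sample_id="demo")
print(table.to_dataframe().head(3).to_string(index=False))
print(t.call_sample_telomere(table)["call"])
```

```
sample   motif       family  source  windows  copies  relative_abundance
  demo TTCAGGG Papaver-type catalog      960    7680                 1.0
TTCAGGG
```

960 of 100,000 read windows are perfect TTCAGGG tandem arrays (8 complete
copies each), every telomere-like hit resolves to that one motif, and the
sample's telomere is called TTCAGGG. Profiling the same genome's k-mer
spectrum:

```python
profile = t.fit_genome_profile(
    t.count_kmers(t.simulate_short_reads(t.diploid_pool(hap_a, hap_b),
                                         40 * 150_000 // 151, seed=9), k=21))
print(profile.to_json())
```

prints `len` = 152,648 (the estimated genome size, 1.8% off the planted
150 kb), `ab` = 0.0009 (the planted 0.1% heterozygosity), `kcov` = 17.05
(the heterozygous k-mer coverage: 40× sequencing × the (151−21+1)/151
k-mer-per-read factor, halved; homozygous k-mers peak at twice this),
`err` = 0 for error-free reads and `uniq` = 0.98.

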