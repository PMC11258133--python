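# Methods

This note documents the models and procedures implemented in teloscope, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate. No empirical number appears here that the test suite or
`scripts/acceptance.py` does not itself compute.

## Telomere-motif discovery from raw reads

**Model.** A telomeric repeat is a tandem array of a short unit (6–10 bp in
all known plant/algal telomeres) occupying the very ends of chromosomes.
In whole-genome shotgun data such arrays appear as reads that are
wall-to-wall tandem repeats; interstitial microsatellites rarely run pure
for 60 bp. The detector therefore asks, for each fixed 60-bp read window,
whether the window is (near-)perfectly periodic with some primitive period
u ∈ [6, 10]: `window[i] == window[i+u]` for all i, allowing
`max_mismatch` violations (default 0; N never matches), with at least
`min_copies` = 4 complete copies. The smallest qualifying period wins;
units that are themselves periodic (homopolymers, dinucleotide repeats
dressed as a 6-mer) are rejected, so the reported unit is primitive.

**Windowing.** Reads are trimmed to bases [10, 70) — the 60-bp interior of a
151-bp read, dropping the first 10 bp and last 81 bp. The leading trim
avoids the low-quality read start; 60 bp still holds ≥ 6 copies of a 7-mer
and 6 copies of a 10-mer, so `min_copies` = 4 is conservative across the
whole catalog range. The trailing trim is *not* enforced against the actual
read length: mixed-length input yields windows whenever 70 bp exist, and
shorter reads are skipped and counted (`emitted + skipped = input` always
holds). Before trimming, the read pool is subsampled to 20 million records,
uniformly without replacement under a mandatory seed (default 42); a
`first_n` flag provides head-of-file compatibility. Sequence inputs are
sampled by index and streamed; pure iterators use reservoir sampling. The
two paths draw different (equally uniform) subsets for the same seed.

**Canonical form.** Reads sample both telomere strands and arbitrary
rotations of the unit, so counting must merge the orbit of each unit under
rotation and reverse complement. The display form is chosen as: the G-rich
strand (more G than C; ties broken by comparing minimal rotations), rotated
so the longest G-run is the suffix (ties: longest leading T-run, then
lexicographic). This reproduces the conventional way telomere units are
written (TTTAGGG, TTAGGG, …). A strand/rotation-free key (the minimal
rotation over both strands) backs exact catalog matching; the closure
property — every rotation and the reverse complement map to the same display
form — is property-tested.

**Classification and novelty.** The catalog holds eight motifs: TTTAGGG
(Arabidopsis-type), TTAGGG (vertebrate-type), TTTTAGGG
(Chlamydomonas-type), TTCAGG and TTTCAGG (Genlisea-type), TTTTAGG
(Klebsormidium-type), TTTTTTAGGG (Cestrum-type) and TTCAGGG (Papaver-type).
A unit that matches no catalog key is promoted to *novel candidate* when
its circular edit distance (minimum Levenshtein over all rotations of both
strands) to some catalog motif is ≤ 1 **and** it retains a G-run of length
≥ 2. Distance 1 is the smallest threshold that admits a genuine
one-substitution novelty (TTCAGGG from TTTAGGG) while the G-run condition
excludes AT-rich microsatellites; both are exposed as parameters. The
circular edit distance is an exact DP, cross-checked against edlib in the
tests.

**Calling.** Per-motif window counts (and secondary copy counts) are
aggregated into a table; relative abundance is normalized over
telomere-like hits only (catalog + novel candidates), with raw counts
always emitted alongside. The sample call is the motif of maximal
abundance, provided it has ≥ `min_windows` = 50 windows and ≥
`min_fraction` = 0.5 of telomere-like hits; ties or sub-threshold winners
return "undetermined" with all candidates listed.

## k-mer spectrum genome profiling

**Counting.** Canonical k-mers (minimum of a k-mer and its reverse
complement under 2-bit encoding) are counted over a read set; k must be odd
(no self-complementary k-mers) and ≤ 31 (64-bit codes). k-mers containing N
are skipped. Mass conservation — Σ multiplicity × count = number of valid
k-mer positions — is exact and tested against a dictionary counter.
Multiplicities saturate at 10⁶, the customary counter ceiling for highly
repetitive genomes. Defaults follow field practice: k = 27 for 151-bp
short-read surveys, k = 21 for HiFi-like long reads.

**Fit.** The profile fit is an intentionally simple peak model, not a
negative-binomial mixture: its role is parameter recovery at desk scale,
and its quantities carry the conventional spectrum-report names.

1. *Error boundary* m₀: the first local minimum scanning from
   multiplicity 1 (first m with h(m+1) > h(m)). A monotone non-increasing
   histogram has no interior minimum and raises "cannot separate error
   k-mers". `err` is the mass fraction at or below m₀.
2. *Peaks*: the global maximum above m₀ is located; if a second local peak
   of ≥ 10% its height lies in [1.6, 2.4]× its position, the main peak is
   heterozygous (kcov = peak, homozygous coverage = 2·kcov), otherwise
   homozygous (kcov = peak/2). The window and height floor are our
   concretion of "a second peak near twice the position"; peak positions
   are refined by a count-weighted centroid over ±15%, which steadies the
   argmax of Poisson-wide discrete peaks.
3. *Genome size*: `len` = (mass above m₀) / homozygous coverage. Counted
   over a diploid read set this is the haploid genome length, repeats
   included at their true multiplicity.
4. *Heterozygosity*: the heterozygous mass fraction is estimated as
   **twice the mass in (m₀, kcov]**. The het peak is near-symmetric about
   kcov while the hom peak (at 2·kcov, sd ≈ √(2·kcov)) leaves ~3-sd-deep
   negligible mass below kcov; a naive window reaching up to 1.5·kcov
   would absorb ~5–7% of the hom peak's lower tail at 40× and roughly
   double a 0.4% ab estimate. The per-base rate is
   ab = 1 − (1 − f_het)^(1/k), aa = 1 − ab; the f_het → 0 limit (ab = 0)
   is tested analytically.
5. *Uniqueness*: `uniq` = single-copy mass in (m₀, 1.5·hom] over
   hom · len. Repeat families at ≥ 2 copies push mass beyond the window
   and depress uniq, which the tests verify at repeat fractions 0 and 0.5.
6. `dup` (read duplication) has no component in this model and is reported
   as null; `p` is fixed at 2 (diploid only).

**What the tests can and cannot say.** Spectrum shape at desk scale depends
on how many *independent* coverage draws the genome offers, roughly
genome length / read length. With ~17-kb reads on sub-Mb toy chromosomes
that ratio is ~50 and single-realization histograms are visibly lumpy —
an artefact of miniaturization, not of the model, since real genomes are
10³–10⁴ read lengths long. Profile-recovery tests therefore sequence the
synthetic genomes with error-free 151-bp reads (HiFi-accuracy, short-read
geometry), which restores smooth spectra at 0.5–2 Mb. Recovery checked:
len within 10%, ab within ±50% relative for planted het ≥ 0.2%, at
30–60×. Note that k-mer coverage is read coverage × (L−k+1)/L, so kcov at
40× with 151-bp reads sits near 17, not 20.

## Assembly QC

- **Contig stats**: N50 is the length at which the descending cumulative
  sum first reaches half the total; verified against a sort-and-scan
  oracle on random multisets.
- **Contig-end telomere scan**: within 10 kb of each terminus, maximal
  clusters of exact motif copies with inter-copy gaps ≤ 50 bp; ≥ 10 copies
  yields a call. The G-rich display form is expected at 3' ends and its
  reverse complement at 5' ends, matching the orientation the simulator
  plants and the convention that the G-strand runs toward the terminus.
- **RepeatMasker .out**: the 15-column alignment table (3 header lines) is
  parsed line-wise — there is no installed parser for this format — and
  classes map onto seven summary categories (Retroelement, DNA transposon,
  Rolling-circle, Small RNA, Satellite, Simple repeat, Low complexity) plus
  Unclassified. Per-class base totals are not deduplicated; masked
  fractions are, via interval union.
- **Binning**: retained contigs (length ≥ `min_contig_len`; the survey
  convention keeps only representative long contigs) are tiled from 0 in
  100-kb steps, terminal bins truncated and normalized by their true width.
  Depth comes from a three-column all-positions dump, with absent positions
  counted as zero; repeat ratio is the unioned masked fraction clipped to
  the bin; genes, SNPs and SVs are assigned to the bin containing their
  start coordinate (integral counts, matching count-style heatmaps, rather
  than proportional splitting). Depth and repeat-mass conservation across
  bins are exact and tested. Coordinates are 0-based half-open internally;
  GFF3/VCF convert on read.
- **Repeat median split**: threshold = median bin repeat ratio; bins with
  ratio ≤ threshold are "less repetitive" (ties deliberately fall low, so
  an all-equal input degenerates to one full group, reported as such).
  Groups are summarized by median and sample sd of per-bin mean depth —
  mean rather than median within bins because per-bin depth is summed
  anyway and both are emitted.
- **SV spectrum**: length = |SVLEN|, else END − POS, else an error naming
  the record; records < 50 bp are dropped; types normalize onto
  {DEL, INS, INV, DUP:INT, DUP:TANDEM} (bare DUP → DUP:INT); per-type
  counts plus log₁₀-binned length histograms.
- **Gene×SV intersection**: a gene is affected iff ≥ 1 bp half-open overlap
  between any of its CDS intervals (genes are counted by coding-sequence
  impact) and any SV footprint; DEL/INV/DUP footprints are
  [POS−1, POS−1+len), insertions 1 bp at the site; genes dedup to one hit.
  Backed by an interval tree, verified against brute-force pairwise
  overlap.

## Circos export and pipeline

The export contract is data, not imagery: a karyotype (contigs in
descending length order), one histogram track (depth) and four heatmap
tracks (gene/SNP/SV/repeat), each `contig start end value` with declared
ranges equal to the observed min/max, plus a minimal configuration
referencing them (a 9-step sequential palette; color scaling is Circos's
business). Track files round-trip exactly.

`run_pipeline` validates every configured input path up front, then runs
subsample → trim → telomere → k-mer profile → assembly QC → export; each
stage is a pure function of inputs + config, failures abort with the stage
name, and the JSON report contains no timestamps so reruns are
byte-identical.

## Synthetic data: what it emulates, and what it does not

The generator builds diploids in the image of the target study design:
chromosome-scale sequences with telomere arrays of a chosen motif at both
ends (C-strand at 5', G-strand at 3'), interspersed repeats as exact copies
of 3–10 random 0.3–5 kb families (each placed ≥ 2 times so repeats create
multi-copy k-mer peaks — no real TE biology), haplotype B diverged by
substitution SNPs and by DEL/INS/INV/DUP:INT/DUP:TANDEM events recorded in
reference coordinates, and optional simple gene models for the annotation
fixtures. SNPs are substitutions only, keeping the two-peak diploid
spectrum exact, and SNPs/SVs avoid the telomere arrays so planted-motif
recovery is noise-free at the arrays themselves. Short reads are 151 bp,
uniform over both haplotypes and strands with substitution errors; long
reads are lognormal around a requested mean (defaults near the 17–18 kb
HiFi regime) and error-free by default, with an optional error rate.
Fixture writers emit RepeatMasker .out, GFF3, SNP/SV VCF and a Poisson
per-base depth dump that round-trip exactly through the QC parsers; FASTQ
qualities are constant Q40 because no stage consumes them.

Passing tests on this generator demonstrate algorithmic correctness against
planted truth, not robustness to real-data pathologies: no quality-dependent
error profiles, indel errors, PCR/optical duplicates, TE families with
internal structure, segmental duplications, or collapsed assembly regions.
Genome sizes in tests (0.15–2 Mb) are three orders below real plant
genomes; all rates and geometries (151-bp reads, 20 M subsample target,
100-kb bins, ≥ 50 bp SVs) match the study design the package targets.

## Known limitations

- The spectrum fit assumes a diploid with separable error/het/hom peaks;
  polyploids, very low coverage (< ~15×) or error rates pushing m₀ past the
  het peak defeat it, by design it refuses monotone histograms.
- Telomere detection requires pure (or near-pure, via `max_mismatch`)
  arrays within a 60-bp window; heavily degraded interstitial telomeric
  sequence is out of scope, as is telomere *length* estimation.
- The contig-end scan uses exact motif copies; diverged terminal arrays
  need the discovery path, not the scan.
- An alternative reading of motif quantification — fixed-k counting against
  rotated motif k-mer sets — is noted but not implemented; the
  window/period formulation reports both window and copy counts to bridge
  the ambiguity.
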