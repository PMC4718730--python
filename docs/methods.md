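# Methods

`hcrtkit` re-implements, as a tested pipeline, three analyses from cell-type
transcriptome profiling of hypocretin (Hcrt/orexin) neurons in larval
zebrafish: calling neuron-enriched transcripts from FACS/RNA-seq counts,
predicting shared transcription-factor regulators from conserved promoter
binding sites, and scoring larval sleep architecture from locomotor traces.
This note records the models, the numerical choices, and what the synthetic
generators do and do not emulate.

## Enrichment calling

### Input and normalization

The experimental design has three sample groups: FACS-sorted EGFP⁺ cells
(essentially the Hcrt neurons of *hcrt:EGFP* larvae), the EGFP⁻ remainder of
the same dissociation, and unsorted whole-head tissue, each sequenced in a
small number of replicates. The unit of analysis is the gene × sample raw
read-count matrix with per-gene transcript lengths.

Expression thresholds are stated in transcripts per million,
TPM_g = 10⁶·(c_g/ℓ_g)/Σ_j(c_j/ℓ_j), computed per pooled group. Between-sample
scale is estimated by a trimmed mean of M-values: for sample *s* against a
reference *r*, per-gene log-ratios M_g = log₂(c_sg/c_rg) over genes nonzero in
both are trimmed two-sided by 30% on M and 5% on abundance
A_g = ½log₂(c_sg·c_rg), and averaged with inverse-asymptotic-variance weights
1/(1/c_sg + 1/c_rg); the factor is 2^mean. Working on raw-count ratios (not
per-library proportions) makes the factor an *effective library size*: a
sample that is exactly the reference with every count doubled gets factor 2.
These factors supply the library-size ratio of the enrichment test; the TPM
thresholds are applied to TPM directly. Trim fractions and weighting are
configurable; the defaults are the method's published ones, since the study
cites only "a variation" of the procedure.

### The test

Replicates are pooled per group (the default; a per-replicate mode tests
every target/control replicate pair and keeps the max p). For one gene and
one target/control pair with counts (a, b) and effective library sizes
(N_a, N_b), the null of a common per-read rate conditions on the total:
a ~ Binomial(a+b, N_a/(N_a+N_b)). The two-sided p-value doubles the smaller
tail and caps at 1. This is exact at any count, which is what allows the
enumeration oracle in the tests.

Amplified picogram-input libraries violate Poisson sampling. A single
variance-inflation factor φ (variance = φ·mean) is estimated from
within-group replicate dispersion: the median, over genes with within-group
mean count ≥ 10 in every group with ≥ 2 replicates, of variance/mean —
divided by median(χ²_{k−1})/(k−1) per group of k replicates, because the
sample variance of k replicates is ≈ φ·mean·χ²_{k−1}/(k−1) and the raw
median of that ratio sits ~31% below φ at k = 3. The corrected estimator is
median-unbiased on Poisson data (φ̂ ≈ 1) and recovers generator values
(φ = 4 → φ̂ ∈ [3, 5] at 5,000 genes). Before testing, both counts are
deflated by φ and rounded (a quasi-Poisson correction that keeps the
conditional test exact on the deflated counts).

A gene's p-value is the **max** of its two pairwise tests (EGFP⁺ vs EGFP⁻,
EGFP⁺ vs whole head): enrichment must hold against *both* controls.
Bonferroni correction multiplies by the number of genes passing the
raw-read floor (average > 15 raw reads across EGFP⁺ replicates); only those
genes are analyzed.

### Tiers and output

With α = 0.01 on the adjusted p and the reads floor satisfied:

* **strict** — EGFP⁺ TPM ≥ 100 and fold ≥ 7 over the larger control;
* **relaxed** — EGFP⁺ TPM ≥ 10 and fold ≥ 3.6.

Fold uses a 1-TPM pseudocount in numerator and denominator so zero-TPM
controls stay finite. The emitted table keeps genes with fold > 3.6, sorted
by fold descending, ties broken by gene id.

## TF binding-site analysis

Position-frequency matrices (TRANSFAC-style text, parsed with Biopython) are
scored as log₂-odds against a background model after pseudocount smoothing
f′ = (f + pc·bg)/(1 + pc), pc = 0.25. The per-matrix threshold defaults to
85% of the maximal attainable score (the original thresholds come from a
proprietary matrix database and are not portable); it is configurable per
matrix. Scanning covers both strands, skips windows containing N, and
reports hits ascending by offset, '+' before '−'.

Conservation is approximated positionally: a reference-species hit is kept
iff every other species' promoter has an above-threshold hit for the same
matrix starting within a tolerance window (default 10 bp) of the same
offset. This stands in for scanning a true multiple alignment, which is out
of scope; it is exact for the generator's conserved plantings, which share
offsets across species.

A gene's **combined score** for one TF sums the above-threshold excess
(score − threshold) over its conserved hits, so extra and stronger sites
increase it monotonically and hit-free genes score 0 (max and count
aggregations are selectable; the source analysis describes the intent of the
score, not a formula). TF-set enrichment of a foreground gene set against a
background uses the one-sided hypergeometric tail on conserved-hit carriers,
Benjamini–Hochberg adjusted across TFs (statsmodels). The default
background is all genes in the promoter set.

## Sleep scoring

Sleep in larval zebrafish is behaviorally defined: any run of ≥ 1 consecutive
minute of immobility is a sleep bout. A minute is immobile iff its activity
is ≤ ε (default ε = 0; exposed for noisy trackers). Per clock hour the
scorer reports immobile minutes, wake→sleep transitions (bout onsets — so
hourly transition counts sum to the bout count), mean length of bouts
*starting* in the hour, and mean activity. A bout spanning an hour or
light-phase boundary belongs to its onset hour/phase, keeping counts
additive. Day/night aggregates are per-hour means over the light (14 h) and
dark (10 h) phases.

Genotype comparisons use a two-sided permutation test on the difference of
group means of per-larva phase aggregates, replacing the original
repeated-measures mixed model: the permutation test is distribution-free,
needs no proprietary software, and is testable against exact enumeration.
When C(n, n_a) ≤ 20,000 the null is enumerated exhaustively (the p-value is
exact); otherwise Monte-Carlo permutations with the add-one correction are
used, seeded. Sleep-deprivation rebound compares post-deprivation sleep time
(deprived − control) over matched windows with the same engine.

## Synthetic data

### Count experiment

True per-gene relative abundance is log-normal (ln-scale mean 1.0, sd 2.0 —
a realistic several-decade dynamic range), normalized to TPM. Planted genes
are elevated by `planted_fold` in the EGFP⁺ group only; their control TPM is
floored at 1.1·`planted_min_tpm`/`planted_fold` so the planted tier is
attainable after compositional renormalization. Expected counts are
per-replicate library size × length-weighted read proportions; draws are
Poisson (φ = 1) or negative binomial parameterized to variance = φ·mean.
Default library sizes mirror the study's read depths (24 M/22 M/175 M per
group, 3 replicates each). Not emulated: positional/GC bias, isoform
structure, gene-specific dispersion, or amplification artifacts beyond the
single global φ — so passing recovery tests demonstrates the statistical
machinery, not robustness to all real-library pathologies.

### Promoters

Backbone sequences are i.i.d. draws from the motif's background
distribution; a chosen fraction of the foreground genes receives a
motif-sampled instance at one offset and strand shared by all species
(conserved), while each non-planted gene may receive a single-species
instance with the background rate (non-conserved). Real promoters have
repeat structure, GC heterogeneity and imperfectly aligned orthologs; none
of that is modeled, which is precisely why the conservation filter's
positional surrogate is exact here.

### Activity traces

Each larva's sleep/wake sequence is a two-state Markov (alternating renewal)
process at minute resolution with geometric bout lengths: sleep→wake
probability 1/L fixes the mean bout length L, and wake→sleep probability
f/((1−f)·L) fixes the stationary sleep fraction f. Defaults are calibrated
to the study's printed genotype means (night sleep wt 15.46 / het 14.78 /
hom 13.08 min/h; night bouts wt 2.43 / hom 2.21 min, het interpolated at
2.32; day sleep 2.87/2.80/2.76 min/h). Two printed quantities cannot be
reproduced literally: day bout lengths implied by the printed day transition
counts are sub-minute (impossible at minute resolution; day bouts are set to
1.3 min), and the printed transition rates count is consistent with
counting both transition directions whereas the scorer counts onsets.
Each larva draws its own sleep target from a mean-preserving gamma
distribution (SD 1.9 min/h by day, 1.35 at night) so cohort dispersion
matches the study's printed SEMs (≈ 2.0–2.5 min/h per-larva SD at the
printed group sizes); without this biological heterogeneity a shared renewal
process makes cohorts unrealistically homogeneous and overstates the power
of the near-null day comparison. Wake-minute activity is gamma-distributed
(shape 2, mean 10) in arbitrary units, as the tracking software's units are
not standardized; sleep minutes have activity exactly 0. Circadian
modulation within a phase, startle responses, and tracker noise are not
modeled (ε exists for the latter).

## Validation problem sizes

The acceptance benchmarks (`hcrtkit.benchmarks`, run by
`tests/test_acceptance.py` and `scripts/acceptance.py`) use: all count pairs
≤ 50 at library ratios 1/2/5 against pmf enumeration; 100 null and 20
planted datasets of 10,000 genes × 3 × 3 replicates at study library depths;
1,000 random matrices for normalization invariants; 100 random 500-bp
sequences × 20 random 6–12-bp matrices against a brute-force scanner; 100
promoter-set runs of 480 genes (48 foreground, 30 planted, 5% background,
3 species, 500-bp promoters, one planted 10-bp matrix plus two decoys); 100
sleep cohorts of 90 larvae per genotype with 2,000-permutation comparisons;
and exhaustive 4+4 permutation enumeration. These sizes keep the whole
validation suite in the minutes range while leaving the statistical margins
(sensitivity, error rates, power) far from their thresholds.

## Known limitations

* The conditional-binomial test is a declared stand-in for the unpublished
  statistic of the study's cited method; only its described properties
  (Poisson null, variance-inflation awareness, exactness) are reproduced.
* The conservation filter assumes positionally comparable promoter windows;
  with real multi-species promoters a true alignment should replace it.
* TMM here returns effective-library-scale factors, not the
  library-size-normalized composition factors of common DE packages; the
  two conventions differ by the library-size ratio.
* Headline counts of the original study (20 strict / 212 relaxed
  transcripts, 68/13 TFs, the printed behavioral means as measurements)
  depend on the deposited reads, a proprietary matrix database, or live
  recordings and are not reproducible from synthetic data; the printed
  means and depths enter only as generator calibration.
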