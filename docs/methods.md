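# Methods

## Data model

All statistics operate on beta values: per-CpG methylation as the ratio of
methylated to total fluorescence signal, β ∈ [0, 1]. Each sample carries a
detection p-value per probe (small = reliably measured). Probe positions
are 1-based manifest coordinates; BED export converts to 0-based half-open
single-base intervals. Multi-gene annotation cells are split on ";" with
pairwise alignment to gene regions, so a probe annotated to k genes
contributes k (gene, region) pairs to region-based rules. The region
labels 5'UTR/3'UTR are normalised to 5UTR/3UTR internally to avoid quoting
issues in delimited files. Sex chromosomes are exactly {X, Y} after
stripping any "chr" prefix.

## Quality control

**Sample QC.** The loci call rate of a sample is
LCR = 100 · #{detection p < 0.01} / N_array, with the *platform* probe
total as denominator (485,577 for the 450K array; the simulator sets it to
the simulated array size so the statistic behaves identically at desk
scale). Samples are retained at LCR strictly > 98%. The inequality on the
detection p is strict: p = 0.01 does not count as detected. An alternative
reading of the inclusion rule via the median detection p-value exists in
the field; the counting formula is what this package implements.

**Probe QC.** Four removal rules applied in order, with each removed probe
attributed to the first matching rule: (1) sex-chromosome probes (gender
bias); (2) SNP at the interrogated CpG with allele frequency > 0.05
(strict); (3) SNP within 3 bp of the CpG with AF > 0.05; (4) cross-reactive
probes. The 3 bp window is a property of the annotation source — the
annotation table already encodes it as a per-probe MAF.

**Replicate averaging.** Biological replicates (same patient, same tissue)
collapse to one pseudo-sample: per-probe arithmetic mean of β, and the
*maximum* of the member detection p-values. The maximum is a deliberate
conservative choice — the source procedure does not specify a combination
rule, and a probe undetected in any replicate should remain flagged.

Ordering: sample QC → probe QC → replicate averaging, mirroring the order
in which the statistics are defined (LCR is a raw-array property; averaging
operates on cleaned probes).

## Differential screen

**Variance filter.** Per-probe sample standard deviation σ (n−1
denominator) across all retained samples, divided by the dataset maximum
σ_max; probes with σ/σ_max strictly > 0.4 enter the tests. Applying the
filter *before* testing — and computing the Benjamini–Hochberg adjustment
over the filtered probes only — reduces the multiple-testing burden, as
array-analysis suites conventionally do; both the threshold and the
ordering are configurable.

**Tests.** One-way fixed-effects ANOVA across tissue types (IAS, LA, RA,
LV, RV) and a two-group atrial-vs-ventricular test: pooled-variance
Student by default, Welch optional (the candidate-locus cohort analyses
use Welch throughout). Significance at q ≤ 1×10⁻⁶; the inclusive ≤ is used
where both readings of the threshold circulate. Δβ is
mean(atrial) − mean(ventricular); ventricular hypermethylation therefore
means Δβ < 0.

**Degenerate-variance rules.** With zero within-group variance and
distinct group means the statistic diverges; p is defined as 0 (and the
statistic ±∞). With all values equal, the statistic is 0 and p = 1. These
limits make the zero-noise simulation exact rather than NaN-ridden.

**Multiple testing.** BH step-up via `statsmodels`; a brute-force
implementation of the step-up definition serves as test oracle.

**Enrichment.** 2×2 Fisher exact (two-sided, scipy) of an annotation flag
among hit loci versus background. The background is the QC-passed array
minus the hits (the variance-filtered set can coincide exactly with the
hits, which would leave no contrast). Odds ratio (a·d)/(b·c) with the
Haldane–Anscombe +0.5 correction applied to all cells when any cell is
zero (flagged in the result). With several flags, BH across flags.

**Percent summaries** (direction split, concordance) round half-up to
integers: 124/168 → 74%, 11/16 → 69%, 14/16 → 88%.

## Panel selection

k = ⌊fraction · n⌋ with fraction = 0.10 — the floor is what maps a
168-locus significant set to a 16-locus panel. All significant loci are
ranked by descending |Δβ| with deterministic tie-breaks (ascending p, then
probe id). The ranking is walked until k loci are selected, skipping:
assay-excluded loci (rule 4, applied first so an unassayable probe does
not block its gene), loci with no (gene, region) pair inside
TSS200…3′UTR — TSS1500 lies outside this window, 1stExon inside — and loci
whose gene is already represented (rule 3). Backfills come from the full
significant ranking, not only the original top-10% window ("the next
significant locus"). Every locus receives a log entry: selected,
backfilled (selected from beyond the initial top-k window), one of the
three rejection reasons, or not_considered for loci ranked after the panel
was full — the last action exists so that provenance covers every
significant locus exactly once. A panel short of k is returned with a
warning flag, not an error.

## Classification and concordance

The panel reference stores per-locus atrial/ventricular means from the
discovery cohort, their midpoint, and the direction sign; loci with zero
reference difference are rejected at build time because they cannot define
a direction. Classification is per-locus midpoint voting: a locus votes
for the chamber on whose side of the midpoint the sample's value falls
(strictly), abstains exactly at the midpoint, and the majority decides;
ties and all-abstain are reported as indeterminate. The underlying studies
demonstrate separability without naming a decision rule, so the voting
rule is this package's construction; a nearest-centroid rule (mean
absolute distance to the two reference profiles) is provided as an
alternative and the test suite requires both to agree on all simulated
cohorts.

hiPSC-CM concordance per locus: Welch two-sided test between atrial-like
and ventricular-like groups; status AVM if p < α (default 0.05) and the
difference sign matches the reference, AVM* ("tendency") on a sign match
without significance, inv on a sign mismatch. A zero group difference is
classed inv: it cannot support the reference pattern. Strict concordance is
#AVM/panel, extended adds the tendency loci.

## Cross-platform concordance

Pyrosequencing control QC passes only when the methylated control is
strictly > 70% and the unmethylated control strictly < 10%. Per-locus
platform agreement is the Pearson r² between array β·100 and pyro percent
across paired samples (≥ 3 pairs), summarised by the unweighted mean over
loci; r² is invariant to the affine inter-platform bias, which is the
point of using it. Zero-variance vectors yield "missing with reason"
rather than r = 0 — an undefined statistic must not masquerade as a value.

## Synthetic data

The generator emulates the discovery-study structure: 44 atrial
pseudo-samples (35 IAS, 3 LA, 6 RA by largest-remainder allocation) vs 5
ventricular (3 LV, 2 RV); 168 planted loci with |Δβ| uniform in
[0.3, 0.6] and a 74% ventricular-hypermethylated fraction (Bernoulli per
locus); background probes from a bimodal baseline (modes near β = 0.1 and
0.85 plus a uniform middle component). Noise is additive Gaussian
truncated to [0, 1] rather than beta-distributed — this keeps the
zero-noise limit and the standard-error oracles exact; beta-scale realism
is not needed for what the tests claim. Replicated patients (defaults: one
atrial triplicate, one ventricular duplicate) share a patient effect with
SD = noise_sd/2. Planted-locus group means are drawn to keep both group
means within [0.12, 0.88], making truncation bias negligible at the
default noise.

The per-sample noise SD defaults to 0.05, a free parameter chosen once so
that the 44-vs-5 screen has near-complete power at q ≤ 10⁻⁶ (within-group
β variance is not published for the source cohorts). QC defects — sex/SNP/
cross-reactive flags, detection failures (rate 0.005), one sample with >2%
failing probes — are placed on *non-planted* probes only, so planted-signal
recovery is independent of filter ordering. Enhancer flags are enriched
among planted loci (base rate 0.2, enrichment ×3); the planted set always
contains two loci sharing a gene and one locus with only a TSS1500 region,
so the panel-selection rules are exercised on every run.

Pyrosequencing is simulated as an affine map of β·100 (default slope 0.9,
intercept 5%, noise SD 3%) clamped to [0, 100]; controls assay 80% and 3%
true methylation through the same map, which places the unmethylated
control near its QC threshold — occasional control failures at the default
noise are intended behaviour, not a bug. hiPSC-CM cohorts (default 4
atrial-like, 8 ventricular-like, split across 2D monolayer and engineered
heart tissue labels) attenuate each planted Δβ by a factor (default 0.6)
around the tissue midpoint and flip the sign at designated inverse loci
(the pipeline default inverts the two lowest-ranked panel loci);
non-cardiac cell lines sit globally near β = 0.1 or 0.78. Every generator
call derives one random stream from the configured seed, so identical
configuration yields byte-identical output.

**What the simulation does not model:** Infinium I/II probe-chemistry
differences and within-array normalisation (the pipeline accepts
normalised betas), beta-distributed heteroscedastic noise, correlated
probes within CpG islands or regions, batch effects, and age- or
disease-related methylation drift. Passing tests therefore demonstrate
that the *procedure* is implemented correctly and behaves as designed
under its assumed statistical structure — not that the effect sizes or
error rates transfer to any particular clinical cohort.

## Problem sizes and numerics

The default simulated array is 50,000 probes (configurable upward; the
test suite uses 2,000–10,000 for most checks and the full default for the
planted-recovery and classification properties). The BH oracle runs on
1,000 random p-vectors; the Fisher oracle enumerates every 2×2 table with
both group margins ≤ 30 against a conditional hypergeometric tail sum
(two-sided mass at pmf ≤ pmf(observed)·(1+1e-7), the convention scipy
itself uses). Matrix writers emit ≥ 6 significant digits so that
read(write(x)) round-trips to printed precision. Quantile counts use
⌊fraction·n + 1e-9⌋ to guard against binary-float artifacts in the floor.

## Known limitations

- The classifier is deterministic voting, not probabilistic; no class
  posteriors and no multi-class (e.g. nodal tissue) support.
- Enrichment uses user-supplied annotation flags; no live ontology or
  external-database queries.
- No DMR (region-level) calling, covariate adjustment, or moderated
  (empirical-Bayes) test statistics.
- IDAT parsing, manifest download and genome-build liftover are out of
  scope; inputs are delimited text.
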