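# avmpanel

Discovery and application of a compact CpG methylation marker panel that
distinguishes **atrial** from **ventricular** human cardiac tissue.

Cardiac chambers carry stable, chamber-specific DNA methylation patterns.
Given a methylation-array study — a probe × sample matrix of beta values
(β ∈ [0, 1], the fraction of methylated signal at a CpG) with aligned
detection p-values and a sample sheet — `avmpanel` implements the full
analysis path from raw matrices to a portable marker panel:

1. **QC** — sample inclusion by loci call rate
   (LCR = 100 · #{detection p < 0.01} / N<sub>array</sub>, samples kept at
   LCR > 98%), probe removal rules (sex-chromosome probes; SNP at the CpG or
   within 3 bp with allele frequency > 0.05; cross-reactive probes), and
   biological-replicate averaging.
2. **Differential screen** — variance filter σ/σ<sub>max</sub> > 0.4, then
   per-probe one-way ANOVA across tissue types and a two-group
   atrial-vs-ventricular t test (pooled-variance Student or Welch) with
   Benjamini–Hochberg FDR; significance at q ≤ 10⁻⁶. Effect size is
   Δβ = β̄<sub>atrial</sub> − β̄<sub>ventricular</sub>; Δβ < 0 means
   ventricular hypermethylation. Fisher-exact 2×2 enrichment of annotation
   flags (enhancer, DHS, …) among hits.
3. **Panel selection** — the upper 10% quantile of significant loci by
   |Δβ| (k = ⌊0.10 · n⌋) restricted to gene regions TSS200…3′UTR, one locus
   per gene, with assay-infeasible loci skipped and backfilled from the
   ranking.
4. **Classification & concordance** — a per-locus reference (group means,
   midpoint, direction) built from the discovery cohort classifies new
   samples by midpoint voting (nearest-centroid available as an
   alternative); hiPSC-derived cardiomyocyte cohorts get per-locus
   AVM / AVM\* / inv concordance calls (Welch p < 0.05 and direction match /
   direction match only / inverted direction).
5. **Cross-platform concordance** — bisulfite-pyrosequencing control QC
   (methylated control > 70%, unmethylated < 10%) and per-locus Pearson r²
   between array β·100 and pyro % methylation, summarised by the unweighted
   mean over loci.

A first-class synthetic-data module simulates study cohorts with planted
differential loci (44 atrial vs 5 ventricular samples, |Δβ| ∈ [0.3, 0.6],
74% ventricular-hypermethylated by default), QC defects, pyrosequencing
with affine bias, and hiPSC-CM profiles with attenuated or inverted
effects — so the entire pipeline is testable without any external data.

## Worked example

```python
from avmpanel import (
    SimulationConfig, generate_annotation, simulate_tissue_cohort,
    filter_samples_by_lcr, filter_probes, average_replicates,
    variance_filter, atrial_ventricular_test, select_candidates,
    build_reference, classify_dataset,
)

config = SimulationConfig(n_probes=10_000, n_true_loci=168, seed=1)
annotation, truth = generate_annotation(config)
cohort = simulate_tissue_cohort(config, annotation, truth)

dataset, _ = filter_samples_by_lcr(cohort)          # drops the low-LCR sample
dataset, _ = filter_probes(dataset, annotation)     # rules (1)-(4)
dataset = average_replicates(dataset)

retained, ratio = variance_filter(dataset)
results = atrial_ventricular_test(dataset.subset_probes(retained),
                                  sigma_ratio=ratio)
significant = results[results["significant"]]
panel = select_candidates(significant, annotation)
reference = build_reference(panel, dataset)
calls = classify_dataset(dataset, reference)
print(len(significant), len(panel),
      (calls["predicted"] == dataset.chamber_classes().to_numpy()).mean())
```

prints `168 16 1.0`: all 168 planted loci are recovered at q ≤ 10⁻⁶ (no
false positives pass the variance filter), the 10%-quantile rule yields a
16-locus panel, and midpoint voting classifies every one of the 49
pseudo-samples into its true chamber class. The scripts in `examples/`
walk through each capability with commentary; `examples/05_…` reports a
cross-platform mean r² of 0.971 under the default pyrosequencing bias and
noise.

The same flow is available from a shell:

```sh
avmpanel all --seed 1 --outdir out/   # simulate → qc → discover → select → classify → concord
```

writing delimited result tables, a BED6 panel export and a JSON run
manifest; identical config + seed reproduce byte-identical artifacts.

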