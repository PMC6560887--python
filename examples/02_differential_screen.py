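"""Screen for differentially methylated CpG loci between chambers.

Runs the variance filter (sigma/sigma_max > 0.4), the atrial-vs-ventricular
Student t test with Benjamini-Hochberg FDR at q <= 1e-6, and summarises the
direction of methylation change and enhancer-flag enrichment among hits.
"""

from avmpanel import (
    SimulationConfig,
    annotation_enrichment,
    atrial_ventricular_test,
    average_replicates,
    direction_summary,
    filter_probes,
    filter_samples_by_lcr,
    generate_annotation,
    simulate_tissue_cohort,
    variance_filter,
)

config = SimulationConfig(n_probes=10_000, n_true_loci=168, seed=1)
annotation, truth = generate_annotation(config)
cohort = simulate_tissue_cohort(config, annotation, truth)
dataset, _ = filter_samples_by_lcr(cohort)
dataset, _ = filter_probes(dataset, annotation)
dataset = average_replicates(dataset)

retained, sigma_ratio = variance_filter(dataset, threshold=0.4)
print(f"{len(retained)} of {dataset.n_probes} probes pass the variance filter")

results = atrial_ventricular_test(
    dataset.subset_probes(retained), method="student", sigma_ratio=sigma_ratio
)
significant = results[results["significant"]]
planted = set(truth.index[truth["is_true"]])
print(f"{len(significant)} significant loci at q <= 1e-6 "
      f"({len(set(significant.index) & planted)} of {len(planted)} planted)")

direction = direction_summary(results)
print(f"ventricular-hypermethylated: {direction['pct_ventricular_hyper']}% "
      f"({direction['n_ventricular_hyper']}/{direction['n_total']})")

# enrichment against the QC-passed array background
background = dataset.beta.index.difference(significant.index)
enr = annotation_enrichment(significant.index, background, annotation, "enhancer")
print(f"enhancer enrichment: OR = {enr.odds_ratio:.2f}, p = {enr.p:.2e}, "
      f"{enr.fraction_hits:.0%} of hits flagged")
# Most hits are ventricular-hypermethylated (the planted 74% fraction), and
# the enhancer flag is strongly over-represented among them because the
# simulation plants signal preferentially at enhancer CpGs.
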