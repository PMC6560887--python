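"""Select a compact CpG marker panel from the significant loci.

Applies the four selection rules: top 10% by |delta beta| sets the panel
size; loci must map to a gene region between TSS200 and the 3'UTR; one
locus per gene; assay-infeasible loci (an exclusion list) are skipped and
backfilled from the ranking. Exports the panel as BED6.
"""

from pathlib import Path

from avmpanel import (
    SimulationConfig,
    atrial_ventricular_test,
    average_replicates,
    filter_probes,
    filter_samples_by_lcr,
    generate_annotation,
    select_candidates,
    simulate_tissue_cohort,
    variance_filter,
    write_panel_bed,
)

config = SimulationConfig(n_probes=10_000, n_true_loci=168, seed=1)
annotation, truth = generate_annotation(config)
cohort = simulate_tissue_cohort(config, annotation, truth)
dataset, _ = filter_samples_by_lcr(cohort)
dataset, _ = filter_probes(dataset, annotation)
dataset = average_replicates(dataset)
retained, _ = variance_filter(dataset)
results = atrial_ventricular_test(dataset.subset_probes(retained))
significant = results[results["significant"]]

panel = select_candidates(significant, annotation, fraction=0.10)
print(f"panel: {len(panel)} loci (target {panel.k_target}) "
      f"from {len(significant)} significant loci")
print(panel.loci.to_string(index=False))

rejections = panel.selection_log.query("action.str.startswith('rejected')")
print(f"\n{len(rejections)} loci rejected during the ranking walk")

# rule 4: pretend no pyrosequencing primers could be designed for the
# top-ranked locus; the next eligible locus backfills the panel
excluded = panel.probe_ids[0]
redo = select_candidates(
    significant, annotation, fraction=0.10, assay_exclusions={excluded}
)
print(f"excluding {excluded} (assay infeasible) backfills with "
      f"{[p for p in redo.probe_ids if p not in set(panel.probe_ids)]}")

out = Path("scratch_panel.bed")
write_panel_bed(panel, annotation, out)
print(f"\nwrote {out} ({sum(1 for _ in open(out))} BED lines)")
# Each panel locus is the strongest-effect representative of its gene; the
# log records why every other ranked locus was passed over.
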