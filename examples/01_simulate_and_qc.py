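"""Simulate a discovery cohort and run sample- and probe-level QC.

Generates a 10,000-probe array study with 168 planted differential CpG
loci measured in 44 atrial and 5 ventricular samples (plus replicates and
one deliberately degraded sample), then applies the loci-call-rate sample
filter, the four probe-removal rules, and replicate averaging.
"""

from avmpanel import (
    SimulationConfig,
    average_replicates,
    filter_probes,
    filter_samples_by_lcr,
    generate_annotation,
    simulate_tissue_cohort,
)

config = SimulationConfig(n_probes=10_000, n_true_loci=168, seed=1)
annotation, truth = generate_annotation(config)
cohort = simulate_tissue_cohort(config, annotation, truth)
print(f"simulated {cohort.n_probes} probes x {cohort.n_samples} samples")

dataset, sample_report = filter_samples_by_lcr(cohort, threshold=98.0)
for sid, reason in sample_report.removed_samples:
    print(f"removed sample {sid}: {reason}")

dataset, probe_report = filter_probes(dataset, annotation)
for rule, n in probe_report.probe_removal_counts.items():
    print(f"rule {rule:>15}: removed {n} probes")

dataset = average_replicates(dataset)
classes = dataset.chamber_classes()
print(
    f"after QC: {dataset.n_probes} probes, "
    f"{(classes == 'atrial').sum()} atrial + "
    f"{(classes == 'ventricular').sum()} ventricular pseudo-samples"
)
# The removed sample failed the loci call rate (fraction of probes with
# detection p < 0.01); the probe counts show how many CpGs each QC rule
# excluded before any statistics were computed.
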