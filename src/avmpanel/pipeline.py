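"""Stage orchestration: simulate -> qc -> discover -> select -> classify -> concord.

Each stage reads the delimited artifacts of its prerequisites from the
output directory and writes its own, so stages can be run individually or
chained with :func:`run_all`. A run manifest (JSON) records the effective
configuration, seed, package version and per-stage row counts; outputs
contain no timestamps, so identical config + seed reproduce byte-identical
artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import (
    build_reference,
    call_locus_concordance,
    classify_dataset,
    concordance_summary,
)
from .config import PipelineConfig
from .crossplatform import (
    per_locus_cohort_test,
    platform_concordance,
    pyro_control_qc,
)
from .datamodel import MethylationDataset
from .differential import (
    anova_by_tissue,
    atrial_ventricular_test,
    direction_summary,
    enrichment_table,
    variance_filter,
)
from .io import (
    read_annotation,
    read_beta_matrix,
    read_pyro_tables,
    read_sample_sheet,
    write_annotation,
    write_beta_matrix,
    write_panel_bed,
    write_pyro_tables,
)
from .panel import CandidatePanel, select_candidates
from .qc import average_replicates, filter_probes, filter_samples_by_lcr
from .simulate import (
    generate_annotation,
    simulate_hipsc,
    simulate_pyro,
    simulate_tissue_cohort,
)

__all__ = ["run_stage", "run_all", "STAGES", "MissingArtifactError"]

log = logging.getLogger("avmpanel")

STAGES = ("simulate", "qc", "discover", "select", "classify", "concord")

_FLOAT_FMT = "%.8g"


class MissingArtifactError(FileNotFoundError):
    """A stage was invoked before its prerequisite artifacts exist."""


def _require(outdir: Path, name: str, produced_by: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {name!r}: run the '{produced_by}' stage first"
        )
    return path


def _update_manifest(outdir: Path, config: PipelineConfig, stage: str, counts: dict) -> None:
    path = outdir / "manifest.json"
    doc = json.loads(path.read_text()) if path.exists() else {}
    cfg_json = config.model_dump_json()
    doc.update(
        {
            "package": "avmpanel",
            "version": __version__,
            "seed": config.seed,
            "config": json.loads(cfg_json),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        }
    )
    doc.setdefault("stages", {})[stage] = counts
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def _load_dataset(outdir: Path, prefix: str, stage: str) -> MethylationDataset:
    sheet = read_sample_sheet(_require(outdir, f"samples_{prefix}.csv", stage))
    manifest = json.loads((outdir / "manifest.json").read_text())
    total = manifest["config"]["simulation"]["n_probes"]
    return read_beta_matrix(
        _require(outdir, f"beta_{prefix}.tsv", stage),
        _require(outdir, f"detp_{prefix}.tsv", stage),
        sheet,
        array_total_probes=total,
    )


def stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    annotation, truth = generate_annotation(config.simulation)
    cohort = simulate_tissue_cohort(config.simulation, annotation, truth)
    write_annotation(annotation, outdir / "annotation.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", float_format=_FLOAT_FMT)
    cohort.samples.drop(columns=["chamber_class"]).to_csv(
        outdir / "samples_raw.csv", index=False
    )
    write_beta_matrix(cohort, outdir / "beta_raw.tsv", outdir / "detp_raw.tsv")
    counts = {
        "n_probes": cohort.n_probes,
        "n_samples": cohort.n_samples,
        "n_true_loci": int(truth["is_true"].sum()),
    }
    log.info("simulate: %d probes x %d samples, %d planted loci",
             cohort.n_probes, cohort.n_samples, counts["n_true_loci"])
    return counts


def stage_qc(config: PipelineConfig, outdir: Path) -> dict:
    dataset = _load_dataset(outdir, "raw", "simulate")
    annotation = read_annotation(_require(outdir, "annotation.tsv", "simulate"))
    dataset, sample_report = filter_samples_by_lcr(
        dataset, threshold=config.qc.lcr_threshold
    )
    for sid, reason in sample_report.removed_samples:
        log.info("qc: removed sample %s (%s)", sid, reason)
    dataset, probe_report = filter_probes(
        dataset, annotation, maf_threshold=config.qc.maf_threshold
    )
    for rule, n in probe_report.probe_removal_counts.items():
        log.info("qc: rule %s removed %d probes", rule, n)
    dataset = average_replicates(dataset)
    sample_report.to_frame().to_csv(
        outdir / "qc_report.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    pd.Series(probe_report.probe_removal_counts).rename_axis("rule").rename(
        "removed"
    ).to_csv(outdir / "qc_probe_removals.tsv", sep="\t")
    dataset.samples.drop(columns=["chamber_class"]).to_csv(
        outdir / "samples_qc.csv", index=False
    )
    write_beta_matrix(dataset, outdir / "beta_qc.tsv", outdir / "detp_qc.tsv")
    counts = {
        "samples_retained": dataset.n_samples,
        "probes_retained": dataset.n_probes,
        "probe_removals": probe_report.probe_removal_counts,
        "samples_removed": len(sample_report.removed_samples),
    }
    log.info("qc: retained %d samples, %d probes",
             dataset.n_samples, dataset.n_probes)
    return counts


def stage_discover(config: PipelineConfig, outdir: Path) -> dict:
    dataset = _load_dataset(outdir, "qc", "qc")
    annotation = read_annotation(_require(outdir, "annotation.tsv", "simulate"))
    retained, sigma_ratio = variance_filter(
        dataset, threshold=config.stats.sigma_ratio_threshold
    )
    filtered = dataset.subset_probes(retained)
    anova = anova_by_tissue(filtered, sig_threshold=config.stats.q_threshold)
    results = atrial_ventricular_test(
        filtered,
        method=config.stats.method,
        sig_threshold=config.stats.q_threshold,
        sigma_ratio=sigma_ratio,
    )
    anova.to_csv(outdir / "anova.tsv", sep="\t", float_format=_FLOAT_FMT)
    results.to_csv(outdir / "differential.tsv", sep="\t", float_format=_FLOAT_FMT)

    sig = results[results["significant"]]
    summary: dict = {"n_variance_filtered": int(len(retained)),
                     "n_anova_significant": int(anova["significant"].sum()),
                     "n_significant": int(len(sig))}
    if len(sig):
        summary["direction"] = direction_summary(results)
        # flag enrichment is computed against the QC-passed array background
        background = dataset.probe_ids.difference(sig.index)
        if len(background):
            enr = enrichment_table(
                sig.index, background, annotation,
                ["enhancer", "dhs", "heart_enhancer"],
            )
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", float_format=_FLOAT_FMT)
            summary["enhancer_odds_ratio"] = float(enr.at["enhancer", "odds_ratio"])
    (outdir / "discover_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    log.info("discover: %d loci pass the variance filter, %d significant "
             "(t test), %d (ANOVA)", len(retained), len(sig),
             summary["n_anova_significant"])
    return summary


def _read_panel(outdir: Path) -> CandidatePanel:
    loci = pd.read_csv(_require(outdir, "panel.tsv", "select"), sep="\t")
    log_df = pd.read_csv(outdir / "panel_selection_log.tsv", sep="\t")
    manifest = json.loads((outdir / "manifest.json").read_text())
    return CandidatePanel(
        loci=loci,
        selection_log=log_df,
        k_target=manifest["stages"]["select"]["k_target"],
    )


def stage_select(config: PipelineConfig, outdir: Path) -> dict:
    results = pd.read_csv(
        _require(outdir, "differential.tsv", "discover"), sep="\t", index_col=0
    )
    annotation = read_annotation(_require(outdir, "annotation.tsv", "simulate"))
    exclusions: frozenset = frozenset()
    if config.panel.exclusions_path:
        exclusions = frozenset(
            Path(config.panel.exclusions_path).read_text().split()
        )
    sig = results[results["significant"]]
    panel = select_candidates(
        sig,
        annotation,
        fraction=config.panel.fraction,
        allowed_regions=config.panel.allowed_regions,
        assay_exclusions=exclusions,
    )
    panel.loci.to_csv(outdir / "panel.tsv", sep="\t", index=False,
                      float_format=_FLOAT_FMT)
    panel.selection_log.to_csv(
        outdir / "panel_selection_log.tsv", sep="\t", index=False
    )
    write_panel_bed(panel, annotation, outdir / "panel.bed")
    counts = {"n_significant": int(len(sig)), "k_target": panel.k_target,
              "panel_size": len(panel), "short": panel.short}
    log.info("select: panel of %d loci (target %d) from %d significant loci",
             len(panel), panel.k_target, len(sig))
    return counts


def stage_classify(config: PipelineConfig, outdir: Path) -> dict:
    dataset = _load_dataset(outdir, "qc", "qc")
    panel = _read_panel(outdir)
    truth = pd.read_csv(
        _require(outdir, "truth.tsv", "simulate"), sep="\t", index_col=0
    )
    reference = build_reference(panel, dataset)
    reference.table.to_csv(outdir / "reference.tsv", sep="\t",
                           float_format=_FLOAT_FMT)
    tissue_calls = classify_dataset(dataset, reference, rule=config.classifier.rule)
    tissue_calls["true_class"] = (
        dataset.chamber_classes().reindex(tissue_calls["sample_id"]).to_numpy()
    )
    tissue_calls.to_csv(outdir / "classification_tissue.tsv", sep="\t", index=False)

    inverse = panel.probe_ids[len(panel) - config.hipsc.n_inverse_loci:]
    hipsc = simulate_hipsc(
        truth,
        panel.probe_ids,
        attenuation=config.hipsc.attenuation,
        inverse_loci=inverse,
        n_atrial_like=config.hipsc.n_atrial_like,
        n_ventricular_like=config.hipsc.n_ventricular_like,
        noise_sd=config.hipsc.noise_sd,
        seed=config.seed + 1,
    )
    hipsc.samples.drop(columns=["chamber_class"]).to_csv(
        outdir / "samples_hipsc.csv", index=False
    )
    write_beta_matrix(hipsc, outdir / "beta_hipsc.tsv", outdir / "detp_hipsc.tsv")
    cm = hipsc.subset_samples(
        hipsc.samples.loc[hipsc.samples["cohort"] == "hipsc", "sample_id"]
    )
    hipsc_calls = classify_dataset(cm, reference, rule=config.classifier.rule)
    hipsc_calls["true_class"] = (
        cm.chamber_classes().reindex(hipsc_calls["sample_id"]).to_numpy()
    )
    hipsc_calls.to_csv(outdir / "classification_hipsc.tsv", sep="\t", index=False)

    acc = float(
        (tissue_calls["predicted"] == tissue_calls["true_class"]).mean()
    )
    counts = {
        "tissue_accuracy": acc,
        "n_tissue_samples": int(len(tissue_calls)),
        "n_hipsc_samples": int(len(hipsc_calls)),
        "n_inverse_loci": int(len(inverse)),
    }
    log.info("classify: tissue accuracy %.1f%% over %d samples",
             100 * acc, len(tissue_calls))
    return counts


def stage_concord(config: PipelineConfig, outdir: Path) -> dict:
    dataset = _load_dataset(outdir, "qc", "qc")
    panel = _read_panel(outdir)
    reference = build_reference(panel, dataset)

    assays = simulate_pyro(
        dataset,
        panel.probe_ids,
        bias=(config.pyro.slope, config.pyro.intercept),
        noise_sd_pct=config.pyro.noise_sd_pct,
        seed=config.seed + 2,
    )
    write_pyro_tables(assays, outdir / "pyro_measurements.tsv",
                      outdir / "pyro_controls.tsv")
    control_qc = [pyro_control_qc(a) for a in assays]
    pd.DataFrame(
        [
            {"locus_id": c.locus_id, "passed": c.passed,
             "reasons": "; ".join(c.reasons)}
            for c in control_qc
        ]
    ).to_csv(outdir / "pyro_control_qc.tsv", sep="\t", index=False)

    concordance = platform_concordance(dataset, assays)
    concordance.per_locus.to_csv(outdir / "platform_correlation.tsv", sep="\t",
                                 float_format=_FLOAT_FMT)
    cohort_tests = per_locus_cohort_test(
        assays, dataset.chamber_classes().to_dict()
    )
    cohort_tests.to_csv(outdir / "pyro_cohort_tests.tsv", sep="\t",
                        float_format=_FLOAT_FMT)

    hipsc = _load_dataset(outdir, "hipsc", "classify")
    cm = hipsc.subset_samples(
        hipsc.samples.loc[hipsc.samples["cohort"] == "hipsc", "sample_id"]
    )
    calls = call_locus_concordance(cm, reference, alpha=config.classifier.alpha)
    pd.DataFrame(
        [
            {"locus_id": c.locus_id, "status": c.status, "p": c.p,
             "delta_signed": c.delta_signed}
            for c in calls
        ]
    ).to_csv(outdir / "concordance_calls.tsv", sep="\t", index=False,
             float_format=_FLOAT_FMT)
    summary = concordance_summary(calls)
    counts = {
        "controls_passed": int(sum(c.passed for c in control_qc)),
        "mean_r_squared": concordance.mean_r_squared,
        "mean_abs_delta_pct": cohort_tests.attrs["mean_abs_delta_pct"],
        **summary,
    }
    (outdir / "concord_summary.json").write_text(
        json.dumps(counts, indent=2, sort_keys=True) + "\n"
    )
    log.info("concord: mean r^2 %.4f; concordance strict %d%% / extended %d%%",
             concordance.mean_r_squared, summary["pct_strict"],
             summary["pct_extended"])
    return counts


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "discover": stage_discover,
    "select": stage_select,
    "classify": stage_classify,
    "concord": stage_concord,
}


def run_stage(stage: str, config: PipelineConfig, outdir: str | Path) -> dict:
    """Run one named stage; returns its summary counts."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stage == "simulate":
        # fresh manifest so a re-run is self-consistent
        (outdir / "manifest.json").unlink(missing_ok=True)
    counts = _STAGE_FUNCS[stage](config, outdir)
    _update_manifest(Path(outdir), config, stage, counts)
    return counts


def run_all(config: PipelineConfig, outdir: str | Path) -> dict[str, dict]:
    """Chain all stages; returns the per-stage summary counts."""
    return {stage: run_stage(stage, config, outdir) for stage in STAGES}
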