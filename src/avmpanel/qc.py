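"""Sample- and probe-level quality control and replicate averaging.

Sample QC uses the loci call rate (LCR): the percentage of all array probes
whose detection p-value falls below 0.01 in a sample, with the platform
probe total (485,577 on the 450K array) as the fixed denominator. Samples
with LCR strictly above the threshold (default 98%) are retained.

Probe filtering removes, in order: (1) sex-chromosome probes, (2) probes
whose interrogated CpG overlaps a SNP with minor-allele frequency > 0.05,
(3) probes with such a SNP within 3 bp of the CpG, and (4) cross-reactive
probes. A probe hit by several rules is attributed to the first matching
rule. Biological replicates are then collapsed to per-group averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import SEX_CHROMS, MethylationDataset

__all__ = [
    "QCReport",
    "loci_call_rate",
    "filter_samples_by_lcr",
    "filter_probes",
    "average_replicates",
    "PROBE_FILTER_RULES",
]

PROBE_FILTER_RULES = (
    "sex_chromosome",
    "snp_at_cpg",
    "snp_within_3bp",
    "cross_reactive",
)


@dataclass
class QCReport:
    """Outcome of sample and probe QC.

    ``probe_removal_counts`` attributes each removed probe to the first
    matching rule in order; ``retained_probe_count`` therefore equals input
    probes minus the sum of the counts.
    """

    per_sample_lcr: dict[str, float] = field(default_factory=dict)
    retained_samples: list[str] = field(default_factory=list)
    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    probe_removal_counts: dict[str, int] = field(default_factory=dict)
    retained_probe_count: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Sample-level report as a table (one row per input sample)."""
        removed = dict(self.removed_samples)
        rows = [
            {
                "sample_id": sid,
                "lcr_percent": lcr,
                "retained": sid not in removed,
                "reason": removed.get(sid, ""),
            }
            for sid, lcr in self.per_sample_lcr.items()
        ]
        return pd.DataFrame(rows)


def loci_call_rate(detection_p: np.ndarray | pd.Series, array_total: int) -> float:
    """Percent of array probes with detection p < 0.01 (strict) in one sample.

    The denominator is the platform probe total, not the number of values
    supplied, so partial matrices yield proportionally lower LCRs.
    """
    p = np.asarray(detection_p, dtype=float)
    if p.size == 0:
        raise ValueError("empty detection p-value vector")
    if array_total < p.size:
        raise ValueError(
            f"array_total ({array_total}) smaller than number of probes ({p.size})"
        )
    return 100.0 * float(np.count_nonzero(p < 0.01)) / float(array_total)


def filter_samples_by_lcr(
    dataset: MethylationDataset, threshold: float = 98.0
) -> tuple[MethylationDataset, QCReport]:
    """Drop samples whose LCR is not strictly above ``threshold`` percent."""
    report = QCReport()
    keep = []
    for sid in dataset.sample_ids:
        lcr = loci_call_rate(dataset.detection_p[sid], dataset.array_total_probes)
        report.per_sample_lcr[sid] = lcr
        if lcr > threshold:
            keep.append(sid)
        else:
            report.removed_samples.append(
                (sid, f"LCR {lcr:.4g}% <= {threshold:g}%")
            )
    if not keep:
        raise ValueError(
            f"all {dataset.n_samples} samples fail the LCR > {threshold:g}% rule"
        )
    report.retained_samples = keep
    report.retained_probe_count = dataset.n_probes
    return dataset.subset_samples(keep), report


def filter_probes(
    dataset: MethylationDataset,
    annotation: pd.DataFrame,
    maf_threshold: float = 0.05,
    snp_window_bp: int = 3,
) -> tuple[MethylationDataset, QCReport]:
    """Apply probe-removal rules (1)-(4); strict MAF comparison (> removes).

    ``snp_window_bp`` is carried for interface completeness: the annotation
    already encodes "SNP within 3 bp" as a per-probe MAF, so the window is
    fixed by the annotation source.
    """
    missing = dataset.probe_ids.difference(annotation.index)
    if len(missing):
        raise ValueError(f"probe {missing[0]!r} has no annotation row")
    ann = annotation.loc[dataset.probe_ids]

    is_sex = ann["chrom"].astype(str).isin(SEX_CHROMS).to_numpy()
    snp_cpg = (ann["snp_at_cpg_maf"].to_numpy() > maf_threshold) & ~is_sex
    snp_near = (
        (ann["snp_within_3bp_maf"].to_numpy() > maf_threshold)
        & ~is_sex
        & ~snp_cpg
    )
    cross = (
        ann["cross_reactive"].to_numpy(dtype=bool)
        & ~is_sex
        & ~snp_cpg
        & ~snp_near
    )
    removed_any = is_sex | snp_cpg | snp_near | cross

    report = QCReport(
        retained_samples=dataset.sample_ids,
        probe_removal_counts={
            "sex_chromosome": int(is_sex.sum()),
            "snp_at_cpg": int(snp_cpg.sum()),
            "snp_within_3bp": int(snp_near.sum()),
            "cross_reactive": int(cross.sum()),
        },
        retained_probe_count=int((~removed_any).sum()),
    )
    kept = dataset.probe_ids[~removed_any]
    return dataset.subset_probes(kept), report


def average_replicates(dataset: MethylationDataset) -> MethylationDataset:
    """Collapse each biological replicate group into one pseudo-sample.

    Per probe, beta values are averaged arithmetically and detection
    p-values combined by maximum (a probe undetected in any replicate stays
    flagged). Members of a group must share tissue and patient; the
    pseudo-sample takes the replicate-group name as its sample_id.
    Non-replicated samples pass through unchanged, order preserved.
    """
    sheet = dataset.samples
    has_group = sheet["replicate_group"].notna()
    if not has_group.any():
        return dataset

    new_cols: list[str] = []
    beta_cols: dict[str, pd.Series] = {}
    detp_cols: dict[str, pd.Series] = {}
    new_rows: list[dict] = []
    seen_groups: set[str] = set()
    for rec in sheet.itertuples():
        if pd.isna(rec.replicate_group):
            new_cols.append(rec.sample_id)
            beta_cols[rec.sample_id] = dataset.beta[rec.sample_id]
            detp_cols[rec.sample_id] = dataset.detection_p[rec.sample_id]
            new_rows.append(sheet.loc[[rec.Index]].iloc[0].to_dict())
            continue
        group = rec.replicate_group
        if group in seen_groups:
            continue
        seen_groups.add(group)
        members = sheet[sheet["replicate_group"] == group]
        if members["tissue"].nunique() > 1:
            raise ValueError(
                f"replicate group {group!r} mixes tissues: "
                f"{sorted(members['tissue'].unique())}"
            )
        if members["patient_id"].nunique() > 1:
            raise ValueError(
                f"replicate group {group!r} mixes patients: "
                f"{sorted(members['patient_id'].unique())}"
            )
        ids = list(members["sample_id"])
        new_cols.append(group)
        beta_cols[group] = dataset.beta[ids].mean(axis=1)
        detp_cols[group] = dataset.detection_p[ids].max(axis=1)
        row = members.iloc[0].to_dict()
        row["sample_id"] = group
        row["replicate_group"] = np.nan
        new_rows.append(row)

    samples = pd.DataFrame(new_rows).reset_index(drop=True)
    return MethylationDataset(
        beta=pd.DataFrame(beta_cols)[new_cols],
        detection_p=pd.DataFrame(detp_cols)[new_cols],
        samples=samples,
        array_total_probes=dataset.array_total_probes,
    )
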