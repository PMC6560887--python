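"""Array vs bisulfite-pyrosequencing concordance.

Pyrosequencing runs carry a fully methylated and an unmethylated control;
a run passes QC only when the methylated control reads strictly above 70%
and the unmethylated control strictly below 10%.

Cross-platform agreement is assessed per locus by Pearson correlation of
array beta values (scaled to percent) against pyrosequencing percent
methylation across paired samples, summarised by the unweighted mean r^2
over loci. Per-locus cohort group tests use Welch's two-sided t test on
the percent scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import PyroAssay

__all__ = [
    "ControlQC",
    "PlatformConcordance",
    "pyro_control_qc",
    "platform_correlation",
    "platform_concordance",
    "per_locus_cohort_test",
]


@dataclass
class ControlQC:
    locus_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class PlatformConcordance:
    """Per-locus r^2 values plus their unweighted mean.

    Loci whose correlation is undefined (zero variance on either platform)
    are listed in ``missing`` with a reason and excluded from the mean.
    """

    per_locus: pd.DataFrame
    mean_r_squared: float
    missing: list[tuple[str, str]] = field(default_factory=list)


def pyro_control_qc(
    assay: PyroAssay,
    high_threshold: float = 70.0,
    low_threshold: float = 10.0,
) -> ControlQC:
    """Pass iff methylated control > 70% AND unmethylated control < 10% (strict)."""
    for name, v in (
        ("methylated_control", assay.methylated_control),
        ("unmethylated_control", assay.unmethylated_control),
    ):
        if np.isnan(v):
            raise ValueError(f"locus {assay.locus_id!r}: missing {name}")
    reasons = []
    if not assay.methylated_control > high_threshold:
        reasons.append(
            f"methylated control {assay.methylated_control:g}% "
            f"not > {high_threshold:g}%"
        )
    if not assay.unmethylated_control < low_threshold:
        reasons.append(
            f"unmethylated control {assay.unmethylated_control:g}% "
            f"not < {low_threshold:g}%"
        )
    return ControlQC(locus_id=assay.locus_id, passed=not reasons, reasons=reasons)


def platform_correlation(
    array_beta: pd.Series | dict,
    pyro_percent: pd.Series | dict,
) -> tuple[float, float, int]:
    """Pearson r^2 between array (beta, scaled x100) and pyro (%) per locus.

    Values are paired by sample id over the intersection. Returns
    (r_squared, p, n). Raises on < 3 pairs; zero variance in either vector
    makes the correlation undefined and raises with a reason (callers
    aggregating over loci record it as missing rather than 0).
    """
    a = pd.Series(array_beta, dtype=float) * 100.0
    y = pd.Series(pyro_percent, dtype=float)
    shared = a.index.intersection(y.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 paired samples, got {len(shared)}")
    x = a.loc[shared].to_numpy()
    yy = y.loc[shared].to_numpy()
    if np.ptp(x) == 0 or np.ptp(yy) == 0:
        which = "array" if np.ptp(x) == 0 else "pyro"
        raise ValueError(f"zero variance in {which} values: correlation undefined")
    r, p = stats.pearsonr(x, yy)
    return float(r) ** 2, float(p), int(len(shared))


def platform_concordance(
    dataset, assays: list[PyroAssay]
) -> PlatformConcordance:
    """Per-locus array-vs-pyro correlation across all assayed loci.

    The summary mean r^2 is the unweighted arithmetic mean over loci with a
    defined correlation.
    """
    rows = []
    missing: list[tuple[str, str]] = []
    for assay in assays:
        if assay.locus_id not in dataset.beta.index:
            raise ValueError(f"assayed locus {assay.locus_id!r} not in dataset")
        arr = dataset.beta.loc[assay.locus_id]
        try:
            r2, p, n = platform_correlation(arr, pd.Series(assay.measurements))
        except ValueError as exc:
            missing.append((assay.locus_id, str(exc)))
            continue
        rows.append({"locus_id": assay.locus_id, "r_squared": r2, "p": p, "n": n})
    per_locus = pd.DataFrame(
        rows, columns=["locus_id", "r_squared", "p", "n"]
    ).set_index("locus_id")
    mean_r2 = float(per_locus["r_squared"].mean()) if len(per_locus) else float("nan")
    return PlatformConcordance(
        per_locus=per_locus, mean_r_squared=mean_r2, missing=missing
    )


def per_locus_cohort_test(
    assays: list[PyroAssay],
    chamber_by_sample: pd.Series | dict,
) -> pd.DataFrame:
    """Welch two-sided test of atrial vs ventricular pyro values per locus.

    ``chamber_by_sample`` maps sample id to chamber class. Delta percent is
    mean(atrial) - mean(ventricular). Loci with fewer than 2 samples in
    either group are skipped with a warning row (p and delta NaN). The
    returned frame's ``.attrs["mean_abs_delta_pct"]`` carries the cohort
    summary: the mean |delta %| over testable loci.
    """
    chamber = pd.Series(chamber_by_sample)
    rows = []
    for assay in assays:
        vals = pd.Series(assay.measurements, dtype=float)
        shared = vals.index.intersection(chamber.index)
        a = vals.loc[[s for s in shared if chamber[s] == "atrial"]]
        v = vals.loc[[s for s in shared if chamber[s] == "ventricular"]]
        if len(a) < 2 or len(v) < 2:
            rows.append(
                {
                    "locus_id": assay.locus_id,
                    "p": np.nan,
                    "delta_pct_signed": np.nan,
                    "n_atrial": len(a),
                    "n_ventricular": len(v),
                    "note": "skipped: group too small",
                }
            )
            continue
        delta = float(a.mean() - v.mean())
        if a.var(ddof=1) == 0 and v.var(ddof=1) == 0:
            p = 1.0 if delta == 0 else 0.0
        else:
            _, p = stats.ttest_ind(a, v, equal_var=False)
            p = float(p)
        rows.append(
            {
                "locus_id": assay.locus_id,
                "p": p,
                "delta_pct_signed": delta,
                "n_atrial": len(a),
                "n_ventricular": len(v),
                "note": "",
            }
        )
    out = pd.DataFrame(rows).set_index("locus_id")
    out.attrs["mean_abs_delta_pct"] = float(
        out["delta_pct_signed"].abs().mean()
    )
    return out
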