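"""Differential-methylation screening and annotation enrichment.

The screen follows the array-analysis convention of variance-filtering
probes before testing: per-probe standard deviation sigma is divided by the
dataset maximum sigma_max, and only probes with sigma/sigma_max strictly
above the threshold (default 0.4) enter the tests. Benjamini-Hochberg FDR
is then computed over the tested probes only.

Two screens are provided: a one-way ANOVA across tissue types and a
two-group atrial-vs-ventricular t test (pooled-variance Student by default,
Welch optional). Delta beta is defined as mean(atrial) - mean(ventricular);
a negative sign therefore means ventricular hypermethylation.

Degenerate-variance rules make the zero-noise limit well defined: groups
with zero within-group variance but distinct means get p = 0; data with no
signal at all (all values equal) get statistic 0 and p = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "variance_filter",
    "bh_adjust",
    "anova_by_tissue",
    "atrial_ventricular_test",
    "direction_summary",
    "annotation_enrichment",
    "enrichment_table",
    "fisher_exact_p",
    "EnrichmentResult",
    "round_half_up_percent",
    "DEFAULT_Q_THRESHOLD",
]

DEFAULT_Q_THRESHOLD = 1e-6


def round_half_up_percent(count: int, total: int) -> int:
    """count/total as an integer percentage, .5 rounding away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(np.floor(100.0 * count / total + 0.5))


def variance_filter(
    dataset, threshold: float = 0.4
) -> tuple[pd.Index, pd.Series]:
    """Retain probes with sigma/sigma_max strictly above ``threshold``.

    sigma is the per-probe sample standard deviation (n-1 denominator)
    across all samples; sigma_max is its maximum over the probes present.
    Returns (retained probe index, sigma_ratio per probe).
    """
    if dataset.n_samples < 2:
        raise ValueError("variance filter needs at least 2 samples")
    sigma = dataset.beta.std(axis=1, ddof=1)
    sigma_max = float(sigma.max())
    if sigma_max == 0.0:
        raise ValueError("no variance: all probes are constant across samples")
    ratio = sigma / sigma_max
    return ratio.index[ratio > threshold], ratio


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _degenerate_groups(groups: list[np.ndarray]) -> tuple[float, float] | None:
    """Handle zero within-group variance: (stat, p) override or None."""
    within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    if within > 0:
        return None
    means = [g.mean() for g in groups]
    if np.allclose(means, means[0], rtol=0, atol=0):
        return 0.0, 1.0
    return np.inf, 0.0


def anova_by_tissue(
    dataset,
    sig_threshold: float = DEFAULT_Q_THRESHOLD,
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per probe across tissue types.

    Returns a table indexed by probe with columns F, p, q and significant
    (q <= sig_threshold). Run on variance-filtered probes; q is computed
    over the probes tested here.
    """
    tissues = dataset.samples.set_index("sample_id")["tissue"].loc[
        dataset.beta.columns
    ]
    groups = [
        dataset.beta[tissues.index[tissues == t]].to_numpy()
        for t in tissues.unique()
    ]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 tissue groups")
    for g, t in zip(groups, tissues.unique()):
        if g.shape[1] == 0:
            raise ValueError(f"tissue group {t!r} has no samples")

    n_total = sum(g.shape[1] for g in groups)
    k = len(groups)
    grand = dataset.beta.to_numpy().mean(axis=1)
    ssb = np.zeros(dataset.n_probes)
    ssw = np.zeros(dataset.n_probes)
    for g in groups:
        m = g.mean(axis=1)
        ssb += g.shape[1] * (m - grand) ** 2
        ssw += ((g - m[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n_total - k
    if df_w <= 0:
        raise ValueError("no residual degrees of freedom for ANOVA")

    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
        p = stats.f.sf(F, df_b, df_w)
    # degenerate-variance rules
    zero_w = ssw <= 0
    no_signal = zero_w & (ssb <= 1e-300)
    sep = zero_w & ~no_signal
    F = np.where(no_signal, 0.0, F)
    p = np.where(no_signal, 1.0, p)
    F = np.where(sep, np.inf, F)
    p = np.where(sep, 0.0, p)

    q = bh_adjust(p)
    return pd.DataFrame(
        {"F": F, "p": p, "q": q, "significant": q <= sig_threshold},
        index=dataset.probe_ids,
    )


def atrial_ventricular_test(
    dataset,
    method: str = "student",
    sig_threshold: float = DEFAULT_Q_THRESHOLD,
    sigma_ratio: pd.Series | None = None,
) -> pd.DataFrame:
    """Two-sided two-group t test of atrial vs ventricular per probe.

    ``method`` selects the pooled-variance Student test or Welch's unequal-
    variance test. Returns one row per probe: group means, signed and
    absolute delta beta (atrial - ventricular), sigma_ratio (if supplied),
    statistic, p, BH q over the tested probes, direction and significance.
    """
    if method not in ("student", "welch"):
        raise ValueError(f"method must be 'student' or 'welch', got {method!r}")
    classes = dataset.chamber_classes()
    a_ids = classes.index[classes == "atrial"]
    v_ids = classes.index[classes == "ventricular"]
    if len(a_ids) < 2 or len(v_ids) < 2:
        raise ValueError(
            "each chamber class needs >= 2 samples "
            f"(atrial {len(a_ids)}, ventricular {len(v_ids)})"
        )
    A = dataset.beta[a_ids].to_numpy()
    V = dataset.beta[v_ids].to_numpy()
    mean_a, mean_v = A.mean(axis=1), V.mean(axis=1)
    delta = mean_a - mean_v

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(A, V, axis=1, equal_var=(method == "student"))
    var_a = A.var(axis=1, ddof=1)
    var_v = V.var(axis=1, ddof=1)
    zero_w = (var_a <= 0) & (var_v <= 0)
    no_signal = zero_w & (delta == 0)
    sep = zero_w & (delta != 0)
    t = np.where(no_signal, 0.0, t)
    p = np.where(no_signal, 1.0, p)
    t = np.where(sep, np.where(delta > 0, np.inf, -np.inf), t)
    p = np.where(sep, 0.0, p)

    q = bh_adjust(p)
    direction = np.where(
        delta > 0, "atrial_hyper", np.where(delta < 0, "ventricular_hyper", "none")
    )
    out = pd.DataFrame(
        {
            "mean_atrial": mean_a,
            "mean_ventricular": mean_v,
            "delta_beta_signed": delta,
            "delta_beta_abs": np.abs(delta),
            "statistic": t,
            "p": p,
            "q": q,
            "direction": direction,
            "significant": q <= sig_threshold,
        },
        index=dataset.probe_ids,
    )
    if sigma_ratio is not None:
        out.insert(4, "sigma_ratio", sigma_ratio.reindex(out.index))
    return out


def direction_summary(
    results: pd.DataFrame, significant_only: bool = True
) -> dict[str, int | float]:
    """Count and percentage of hyper-methylation directions.

    Percentages are count/total*100 rounded half-up to integers, so 124
    ventricular-hypermethylated loci of 168 report as 74%.
    """
    if significant_only and "significant" in results.columns:
        results = results[results["significant"]]
    total = len(results)
    if total == 0:
        raise ValueError("empty result set")
    n_vent = int((results["delta_beta_signed"] < 0).sum())
    n_atr = int((results["delta_beta_signed"] > 0).sum())
    return {
        "n_total": total,
        "n_ventricular_hyper": n_vent,
        "n_atrial_hyper": n_atr,
        "pct_ventricular_hyper": round_half_up_percent(n_vent, total),
        "pct_atrial_hyper": round_half_up_percent(n_atr, total),
    }


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass
class EnrichmentResult:
    """Fisher-exact enrichment of an annotation flag among hit loci.

    a/b = hit loci flagged/unflagged, c/d = background flagged/unflagged.
    The odds ratio is (a*d)/(b*c); when any cell is zero, 0.5 is added to
    every cell (Haldane-Anscombe continuity correction, recorded in
    ``continuity_corrected``). p is two-sided Fisher exact.
    """

    flag_name: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    fraction_hits: float
    continuity_corrected: bool = False
    q: float | None = None


def annotation_enrichment(
    hit_loci,
    background_loci,
    annotation: pd.DataFrame,
    flag_name: str,
) -> EnrichmentResult:
    """2x2 enrichment of a boolean annotation flag in hits vs background.

    ``background_loci`` must exclude the hits (tested loci minus hits).
    """
    hits = pd.Index(hit_loci)
    bg = pd.Index(background_loci)
    if len(hits) == 0 or len(bg) == 0:
        raise ValueError("hit and background sets must be non-empty")
    overlap = hits.intersection(bg)
    if len(overlap):
        raise ValueError(
            f"hit and background sets overlap (e.g. {overlap[0]!r})"
        )
    flag = annotation[flag_name].astype(bool)
    a = int(flag.loc[hits].sum())
    b = len(hits) - a
    c = int(flag.loc[bg].sum())
    d = len(bg) - c
    p = fisher_exact_p(a, b, c, d)
    corrected = 0 in (a, b, c, d)
    if corrected:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    return EnrichmentResult(
        flag_name=flag_name,
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=(aa * dd) / (bb * cc),
        p=float(p),
        fraction_hits=a / (a + b),
        continuity_corrected=corrected,
    )


def enrichment_table(
    hit_loci, background_loci, annotation: pd.DataFrame, flags
) -> pd.DataFrame:
    """Enrichment of several flags with BH adjustment across the flags."""
    results = [
        annotation_enrichment(hit_loci, background_loci, annotation, f)
        for f in flags
    ]
    qs = bh_adjust([r.p for r in results])
    rows = []
    for r, q in zip(results, qs):
        r.q = float(q)
        rows.append(vars(r))
    return pd.DataFrame(rows).set_index("flag_name")
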