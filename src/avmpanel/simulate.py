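"""Synthetic methylation-array data with planted atrial-ventricular signal.

The generator reproduces the statistical structure the analysis assumes: a
heavily unbalanced tissue cohort (44 atrial vs 5 ventricular samples after
replicate averaging, the atrial side dominated by interatrial-septum
samples), a small set of planted differentially methylated CpG loci with
|delta beta| between 0.3 and 0.6 of which ~74% are ventricular-
hypermethylated, probe-level QC defects (sex-chromosome, SNP-proximal and
cross-reactive probes, detection failures, one low-call-rate sample),
pyrosequencing measurements related to array betas by an affine bias plus
noise, and hiPSC-derived cardiomyocyte profiles with attenuated effect
sizes and optional direction-inverted loci.

Noise is additive Gaussian truncated to [0,1] rather than beta-distributed,
which keeps the zero-noise limit exact: with ``noise_sd = 0`` every sample
equals its group mean and the planted signal is recovered exactly. QC flags
are never placed on planted loci, so probe filtering cannot remove signal.

Every generator call uses one random stream derived from ``config.seed``
(or an explicit ``seed`` argument), so identical configuration yields
byte-identical outputs.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .datamodel import MethylationDataset, PyroAssay, chamber_class

__all__ = [
    "SimulationConfig",
    "generate_annotation",
    "simulate_tissue_cohort",
    "simulate_pyro",
    "simulate_hipsc",
]

_GENE_REGION_POOL = ["Body", "TSS200", "5UTR", "3UTR", "1stExon", "TSS1500"]
_ISLAND_POOL = ["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"]
_ISLAND_P = [0.13, 0.15, 0.14, 0.035, 0.035, 0.51]

#: Atrial tissue composition of the discovery cohort (IAS-dominated).
_ATRIAL_MIX = (("IAS", 35), ("LA", 3), ("RA", 6))
_VENT_MIX = (("LV", 3), ("RV", 2))


class SimulationConfig(BaseModel):
    """Parameters of the synthetic study.

    Defaults mirror the discovery-cohort conditions: 44 atrial vs 5
    ventricular pseudo-samples, 168 planted loci with |delta beta| in
    [0.3, 0.6], 74% of them ventricular-hypermethylated, and a per-sample
    beta-scale noise SD of 0.05. ``n_probes`` defaults to a 50,000-probe
    desk-scale array; the loci-call-rate denominator of simulated datasets
    is set to ``n_probes`` so sample QC behaves as on a full array.
    """

    model_config = ConfigDict(extra="forbid")

    n_probes: int = Field(default=50_000, ge=1)
    n_true_loci: int = Field(default=168, ge=0)
    delta_range: tuple[float, float] = (0.3, 0.6)
    frac_vent_hyper: float = Field(default=0.74, ge=0.0, le=1.0)
    noise_sd: float = Field(default=0.05, ge=0.0)
    n_atrial: int = Field(default=44, ge=1)
    n_ventricular: int = Field(default=5, ge=1)
    #: patient id -> number of technical array replicates of that patient's
    #: sample (collapsed back to one pseudo-sample by replicate averaging).
    replicate_spec: dict[str, int] = Field(
        default_factory=lambda: {"P001": 3, "P045": 2}
    )
    frac_sex_probes: float = Field(default=0.02, ge=0.0, le=1.0)
    frac_snp_probes: float = Field(default=0.05, ge=0.0, le=1.0)
    frac_crossreactive: float = Field(default=0.01, ge=0.0, le=1.0)
    detection_fail_rate: float = Field(default=0.005, ge=0.0, le=1.0)
    low_lcr_sample: bool = True
    enhancer_base_rate: float = Field(default=0.2, ge=0.0, le=1.0)
    enhancer_enrichment: float = Field(default=3.0, ge=0.0)
    dhs_rate: float = Field(default=0.14, ge=0.0, le=1.0)
    heart_enhancer_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        lo, hi = self.delta_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"delta_range must lie within (0,1), got {self.delta_range}")
        if self.n_true_loci > self.n_probes:
            raise ValueError("n_true_loci cannot exceed n_probes")
        for pid, r in self.replicate_spec.items():
            if r < 1:
                raise ValueError(f"replicate count for {pid!r} must be >= 1")
        return self


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, stream]))


def generate_annotation(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a probe annotation table and the planted-signal truth table.

    QC-defect flags (sex chromosome, SNP, cross-reactive) are assigned to
    non-planted probes only, so probe filtering never removes signal. Among
    planted loci the enhancer flag rate is
    min(1, enhancer_base_rate * enhancer_enrichment), against
    enhancer_base_rate in the background. At least two planted loci share a
    gene symbol and at least one planted locus carries only a disallowed
    gene region (TSS1500), to exercise the panel-selection rules.

    The truth table (indexed by probe id) records is_true, the planted
    signed delta beta (atrial - ventricular; 0 for background probes), the
    direction, and the atrial/ventricular group means the cohort simulator
    will realise.
    """
    rng = _rng(config.seed, 0)
    n = config.n_probes
    probe_ids = np.array([f"cg{i:08d}" for i in range(1, n + 1)])
    is_true = np.zeros(n, dtype=bool)
    true_idx = np.sort(rng.choice(n, size=config.n_true_loci, replace=False))
    is_true[true_idx] = True

    # chromosomes: planted loci are always autosomal
    chrom = rng.integers(1, 23, size=n).astype(str)
    sex_mask = (~is_true) & (rng.random(n) < config.frac_sex_probes)
    chrom[sex_mask] = rng.choice(["X", "Y"], size=int(sex_mask.sum()))
    pos = rng.integers(1, 200_000_000, size=n)

    # gene assignment
    genes: list[list[str]] = []
    regions: list[list[str]] = []
    region_choices = rng.choice(len(_GENE_REGION_POOL), size=n)
    has_gene = rng.random(n) < 0.8
    for i in range(n):
        if is_true[i] or has_gene[i]:
            genes.append([f"GENE{i + 1:06d}"])
            regions.append([_GENE_REGION_POOL[region_choices[i]]])
        else:
            genes.append([])
            regions.append([])
    if config.n_true_loci >= 2:
        # two planted loci share a gene (exercises per-gene deduplication)
        shared = f"GENE{true_idx[0] + 1:06d}"
        genes[true_idx[1]] = [shared]
        # planted loci otherwise carry allowed regions ...
        for i in true_idx:
            if regions[i] == ["TSS1500"]:
                regions[i] = ["Body"]
    if config.n_true_loci >= 3:
        # ... except one with only a disallowed region (exercises rule 2)
        regions[true_idx[2]] = ["TSS1500"]

    island = rng.choice(_ISLAND_POOL, size=n, p=_ISLAND_P)

    # SNP flags: half at the CpG itself, half within 3 bp; MAFs drawn
    # strictly above the 0.05 filter threshold. A small extra fraction
    # carries sub-threshold MAFs that must survive filtering.
    snp_at = np.full(n, np.nan)
    snp_near = np.full(n, np.nan)
    u = rng.random(n)
    at_mask = (~is_true) & (~sex_mask) & (u < config.frac_snp_probes / 2)
    near_mask = (
        (~is_true)
        & (~sex_mask)
        & (u >= config.frac_snp_probes / 2)
        & (u < config.frac_snp_probes)
    )
    benign_mask = (~at_mask) & (~near_mask) & (rng.random(n) < 0.02)
    snp_at[at_mask] = rng.uniform(0.051, 0.5, size=int(at_mask.sum()))
    snp_near[near_mask] = rng.uniform(0.051, 0.5, size=int(near_mask.sum()))
    snp_at[benign_mask] = rng.uniform(0.0, 0.05, size=int(benign_mask.sum()))

    cross = (~is_true) & (rng.random(n) < config.frac_crossreactive)

    enh_rate = np.where(
        is_true,
        min(1.0, config.enhancer_base_rate * config.enhancer_enrichment),
        config.enhancer_base_rate,
    )
    enhancer = rng.random(n) < enh_rate
    dhs = rng.random(n) < config.dhs_rate
    heart_enh = rng.random(n) < config.heart_enhancer_rate

    annotation = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "genes": genes,
            "gene_regions": regions,
            "island_relation": island,
            "snp_at_cpg_maf": snp_at,
            "snp_within_3bp_maf": snp_near,
            "cross_reactive": cross,
            "enhancer": enhancer,
            "dhs": dhs,
            "heart_enhancer": heart_enh,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    # planted effects and group means
    lo, hi = config.delta_range
    delta = np.zeros(n)
    mag = rng.uniform(lo, hi, size=config.n_true_loci)
    sign = np.where(rng.random(config.n_true_loci) < config.frac_vent_hyper, -1.0, 1.0)
    delta[true_idx] = sign * mag

    # background probes: bimodal baseline (hypo ~0.1 / hyper ~0.85 modes
    # plus a uniform middle component); planted probes: atrial mean drawn
    # uniformly in the range keeping both group means inside [0.12, 0.88]
    # so additive noise rarely truncates.
    comp = rng.choice(3, size=n, p=[0.4, 0.4, 0.2])
    base = np.where(
        comp == 0,
        rng.normal(0.1, 0.04, size=n),
        np.where(comp == 1, rng.normal(0.85, 0.04, size=n), rng.uniform(0.2, 0.8, size=n)),
    )
    base = np.clip(base, 0.02, 0.98)
    mean_atrial = base.copy()
    mean_vent = base.copy()
    d_true = delta[true_idx]
    a_lo = np.where(d_true > 0, 0.12 + d_true, 0.12)
    a_hi = np.where(d_true > 0, 0.88, 0.88 + d_true)
    a_mean = rng.uniform(a_lo, a_hi)
    mean_atrial[true_idx] = a_mean
    mean_vent[true_idx] = a_mean - d_true

    truth = pd.DataFrame(
        {
            "is_true": is_true,
            "delta_signed": delta,
            "direction": np.where(
                delta < 0,
                "ventricular_hyper",
                np.where(delta > 0, "atrial_hyper", "none"),
            ),
            "mean_atrial": mean_atrial,
            "mean_ventricular": mean_vent,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return annotation, truth


def _allocate(total: int, mix: tuple[tuple[str, int], ...]) -> list[str]:
    """Largest-remainder allocation of `total` samples to a tissue mix."""
    weights = np.array([w for _, w in mix], dtype=float)
    exact = total * weights / weights.sum()
    counts = np.floor(exact).astype(int)
    rem = total - counts.sum()
    for i in np.argsort(-(exact - counts))[:rem]:
        counts[i] += 1
    out: list[str] = []
    for (tissue, _), c in zip(mix, counts):
        out.extend([tissue] * c)
    return out


def simulate_tissue_cohort(
    config: SimulationConfig,
    annotation: pd.DataFrame,
    truth: pd.DataFrame,
) -> MethylationDataset:
    """Simulate the discovery tissue cohort (pre-QC, pre-averaging).

    Each pseudo-sample's beta values are its chamber's group mean plus
    truncated Gaussian noise. Patients listed in ``replicate_spec`` appear
    as multiple replicate columns sharing a patient effect with
    SD = noise_sd/2. Detection p-values are 0 except a
    ``detection_fail_rate`` fraction set to 0.5 per sample; with
    ``low_lcr_sample`` one extra sample fails >2% of probes and is destined
    for removal by sample QC.
    """
    if len(truth) != config.n_probes:
        raise ValueError("truth table does not match config.n_probes")
    rng = _rng(config.seed, 1)
    tissues = _allocate(config.n_atrial, _ATRIAL_MIX) + _allocate(
        config.n_ventricular, _VENT_MIX
    )
    patients = [f"P{i + 1:03d}" for i in range(len(tissues))]

    mean_a = truth["mean_atrial"].to_numpy()
    mean_v = truth["mean_ventricular"].to_numpy()

    columns: dict[str, np.ndarray] = {}
    rows: list[dict] = []

    def add_sample(
        sid: str, pid: str, tissue: str, group_mean: np.ndarray,
        patient_effect: np.ndarray, rep_group: str | None, fail_rate: float,
    ) -> None:
        noise = (
            rng.normal(0.0, config.noise_sd, size=config.n_probes)
            if config.noise_sd > 0
            else 0.0
        )
        columns[sid] = np.clip(group_mean + patient_effect + noise, 0.0, 1.0)
        rows.append(
            {
                "sample_id": sid,
                "patient_id": pid,
                "tissue": tissue,
                "cohort": "discovery",
                "replicate_group": rep_group,
                "disease": "CHD",
                "fail_rate": fail_rate,
            }
        )

    for pid, tissue in zip(patients, tissues):
        gm = mean_a if chamber_class(tissue) == "atrial" else mean_v
        n_rep = config.replicate_spec.get(pid, 1)
        if n_rep > 1 and config.noise_sd > 0:
            effect = rng.normal(0.0, config.noise_sd / 2.0, size=config.n_probes)
        else:
            effect = np.zeros(config.n_probes)
        if n_rep == 1:
            add_sample(pid, pid, tissue, gm, effect * 0.0, None,
                       config.detection_fail_rate)
        else:
            for r in range(1, n_rep + 1):
                add_sample(
                    f"{pid}_r{r}", pid, tissue, gm, effect, f"{pid}_avg",
                    config.detection_fail_rate,
                )
    if config.low_lcr_sample:
        add_sample(
            "S_LOWLCR", "P_LOWLCR", "IAS", mean_a, np.zeros(config.n_probes),
            None, 0.03,
        )

    beta = pd.DataFrame(columns, index=truth.index)
    detp = pd.DataFrame(
        0.0, index=truth.index, columns=list(columns.keys())
    )
    for row in rows:
        fr = row.pop("fail_rate")
        if fr > 0:
            mask = rng.random(config.n_probes) < fr
            detp.loc[mask, row["sample_id"]] = 0.5
    samples = pd.DataFrame(rows)
    return MethylationDataset(
        beta=beta,
        detection_p=detp,
        samples=samples,
        array_total_probes=config.n_probes,
    )


def simulate_pyro(
    dataset: MethylationDataset,
    panel_loci: Sequence[str],
    bias: tuple[float, float] = (0.9, 5.0),
    noise_sd_pct: float = 3.0,
    seed: int = 0,
) -> list[PyroAssay]:
    """Simulate bisulfite-pyrosequencing of panel loci from array betas.

    Pyro percent = clamp(slope * (100*beta) + intercept + noise, 0, 100).
    Controls: the methylated control assays DNA at 80% true methylation,
    the unmethylated control at 3%, through the same affine bias.
    """
    slope, intercept = bias
    rng = np.random.default_rng(seed)
    assays = []
    for locus in panel_loci:
        if locus not in dataset.beta.index:
            raise ValueError(f"unknown locus {locus!r}")
        vals = dataset.beta.loc[locus]
        noise = (
            rng.normal(0.0, noise_sd_pct, size=len(vals) + 2)
            if noise_sd_pct > 0
            else np.zeros(len(vals) + 2)
        )
        pct = np.clip(slope * (100.0 * vals.to_numpy()) + intercept + noise[:-2], 0, 100)
        meth_ctrl = float(np.clip(slope * 80.0 + intercept + noise[-2], 0, 100))
        unmeth_ctrl = float(np.clip(slope * 3.0 + intercept + noise[-1], 0, 100))
        assays.append(
            PyroAssay(
                locus_id=locus,
                measurements=dict(zip(vals.index, pct)),
                methylated_control=meth_ctrl,
                unmethylated_control=unmeth_ctrl,
            )
        )
    return assays


def simulate_hipsc(
    truth: pd.DataFrame,
    panel_loci: Sequence[str],
    attenuation: float = 0.6,
    inverse_loci: Iterable[str] = (),
    n_atrial_like: int = 4,
    n_ventricular_like: int = 8,
    noise_sd: float = 0.05,
    seed: int = 0,
    n_cell_lines: int = 2,
) -> MethylationDataset:
    """Simulate hiPSC-CM subtype profiles at the panel loci.

    At each panel locus the atrial-like vs ventricular-like group
    difference is attenuation * (planted delta beta), with the sign flipped
    at ``inverse_loci``; group means straddle the tissue midpoint so
    attenuation = 1 with no inversion reproduces the tissue group means
    exactly. Also emits non-cardiac cell-line samples with globally low
    (~0.1) or high (~0.78) methylation at the panel loci.
    """
    if not (0.0 < attenuation <= 1.0):
        raise ValueError(f"attenuation must be in (0,1], got {attenuation}")
    panel = list(panel_loci)
    inverse = set(inverse_loci)
    bad = inverse - set(panel)
    if bad:
        raise ValueError(f"inverse locus {sorted(bad)[0]!r} not in panel")
    missing = [p for p in panel if p not in truth.index]
    if missing:
        raise ValueError(f"panel locus {missing[0]!r} not in truth table")

    rng = np.random.default_rng(seed)
    sub = truth.loc[panel]
    midpoint = (sub["mean_atrial"] + sub["mean_ventricular"]).to_numpy() / 2.0
    flip = np.array([-1.0 if p in inverse else 1.0 for p in panel])
    d = attenuation * sub["delta_signed"].to_numpy() * flip
    mean_a = np.clip(midpoint + d / 2.0, 0.0, 1.0)
    mean_v = np.clip(midpoint - d / 2.0, 0.0, 1.0)

    half_a = max(1, n_atrial_like // 2)
    half_v = max(1, n_ventricular_like // 2)
    specs: list[tuple[str, str, np.ndarray]] = []
    for i in range(n_atrial_like):
        tissue = "aCM2D" if i < half_a else "aCMEHT"
        specs.append((f"aCM{i + 1:02d}", tissue, mean_a))
    for i in range(n_ventricular_like):
        tissue = "vCM2D" if i < half_v else "vCMEHT"
        specs.append((f"vCM{i + 1:02d}", tissue, mean_v))

    columns: dict[str, np.ndarray] = {}
    rows = []
    for sid, tissue, gm in specs:
        noise = rng.normal(0.0, noise_sd, size=len(panel)) if noise_sd > 0 else 0.0
        columns[sid] = np.clip(gm + noise, 0.0, 1.0)
        rows.append(
            {
                "sample_id": sid,
                "patient_id": sid,
                "tissue": tissue,
                "cohort": "hipsc",
                "replicate_group": None,
                "disease": "none",
            }
        )
    cell_levels = [0.1, 0.78]
    for i in range(n_cell_lines):
        sid = f"CL{i + 1:02d}"
        level = cell_levels[i % len(cell_levels)]
        noise = rng.normal(0.0, noise_sd, size=len(panel)) if noise_sd > 0 else 0.0
        columns[sid] = np.clip(level + noise, 0.0, 1.0)
        rows.append(
            {
                "sample_id": sid,
                "patient_id": sid,
                "tissue": "OTHER",
                "cohort": "cellline",
                "replicate_group": None,
                "disease": "none",
            }
        )

    index = pd.Index(panel, name="probe_id")
    beta = pd.DataFrame(columns, index=index)
    detp = pd.DataFrame(0.0, index=index, columns=list(columns.keys()))
    return MethylationDataset(
        beta=beta,
        detection_p=detp,
        samples=pd.DataFrame(rows),
        array_total_probes=len(panel),
    )
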