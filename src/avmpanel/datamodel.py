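"""Core data model for methylation-array panel discovery.

The pipeline operates on three in-memory containers, all pandas-backed:

* an **annotation table** — one row per CpG probe with genomic position,
  gene/region assignments, CpG-island relation and QC/regulatory flags;
* a :class:`MethylationDataset` — a probe x sample beta-value matrix with an
  aligned detection p-value matrix and a sample sheet;
* :class:`PyroAssay` — per-locus bisulfite-pyrosequencing percent-methylation
  measurements with high/low methylation controls.

Beta values express per-CpG methylation as the ratio of methylated to total
signal, from 0 (unmethylated) to 1 (fully methylated). Detection p-values
quantify, per probe and sample, whether the signal is distinguishable from
background; small means reliably measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ALLOWED_CHROMS",
    "SEX_CHROMS",
    "ISLAND_RELATIONS",
    "GENE_REGIONS",
    "TISSUES",
    "COHORTS",
    "chamber_class",
    "validate_annotation",
    "validate_sample_sheet",
    "MethylationDataset",
    "PyroAssay",
]

ALLOWED_CHROMS = frozenset(str(i) for i in range(1, 23)) | {"X", "Y"}
SEX_CHROMS = frozenset({"X", "Y"})

ISLAND_RELATIONS = frozenset(
    {"Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"}
)

#: RefSeq gene-region vocabulary. "5'UTR"/"3'UTR" spellings are normalised to
#: the quote-free forms on read.
GENE_REGIONS = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR"})

TISSUES = frozenset(
    {"IAS", "LA", "RA", "LV", "RV", "aCM2D", "vCM2D", "aCMEHT", "vCMEHT", "OTHER"}
)
COHORTS = frozenset({"discovery", "verification", "validation", "hipsc", "cellline"})

_ATRIAL_TISSUES = {"IAS", "LA", "RA", "aCM2D", "aCMEHT"}
_VENTRICULAR_TISSUES = {"LV", "RV", "vCM2D", "vCMEHT"}

#: Columns the annotation table must carry (index is probe_id).
ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "genes",
    "gene_regions",
    "island_relation",
    "snp_at_cpg_maf",
    "snp_within_3bp_maf",
    "cross_reactive",
    "enhancer",
    "dhs",
    "heart_enhancer",
]

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "patient_id",
    "tissue",
    "cohort",
    "replicate_group",
    "disease",
]


def chamber_class(tissue: str) -> str:
    """Map a tissue label to its cardiac chamber class.

    Atrial tissues (interatrial septum, left/right atrium, atrial-like
    cardiomyocytes) map to ``"atrial"``; ventricular tissues to
    ``"ventricular"``; anything else (non-cardiac cell lines) to ``"none"``.
    """
    if tissue in _ATRIAL_TISSUES:
        return "atrial"
    if tissue in _VENTRICULAR_TISSUES:
        return "ventricular"
    if tissue == "OTHER":
        return "none"
    raise ValueError(f"unknown tissue label: {tissue!r}")


def normalize_chrom(chrom: str) -> str:
    """Strip any 'chr' prefix; sex chromosomes are exactly {'X','Y'} after."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper() if c.upper() in ("X", "Y") else c


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate an annotation table (index = probe_id). Returns it unchanged.

    Raises ``ValueError`` naming the offending probe/column on violation.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table missing required columns: {missing}")
    if ann.index.has_duplicates:
        dup = ann.index[ann.index.duplicated()][0]
        raise ValueError(f"duplicate probe_id in annotation: {dup!r}")
    bad_chrom = set(ann["chrom"].astype(str)) - ALLOWED_CHROMS
    if bad_chrom:
        raise ValueError(f"invalid chromosome name(s): {sorted(bad_chrom)}")
    if (ann["pos"] < 1).any():
        probe = ann.index[ann["pos"] < 1][0]
        raise ValueError(f"probe {probe!r} has position < 1")
    for probe, genes, regions in zip(ann.index, ann["genes"], ann["gene_regions"]):
        if len(genes) != len(regions):
            raise ValueError(
                f"probe {probe!r}: genes {genes} and gene_regions {regions} "
                "have unequal length"
            )
        bad = set(regions) - GENE_REGIONS
        if bad:
            raise ValueError(f"probe {probe!r}: unknown gene region(s) {sorted(bad)}")
    bad_rel = set(ann["island_relation"]) - ISLAND_RELATIONS
    if bad_rel:
        raise ValueError(f"unknown island relation(s): {sorted(bad_rel)}")
    for col in ("snp_at_cpg_maf", "snp_within_3bp_maf"):
        vals = ann[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            probe = vals.index[(vals < 0) | (vals > 1)][0]
            raise ValueError(f"probe {probe!r}: {col} outside [0,1]")
    return ann


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet and attach the derived ``chamber_class`` column."""
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing required columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in sheet: {dup!r}")
    bad_tissue = set(sheet["tissue"]) - TISSUES
    if bad_tissue:
        raise ValueError(f"unknown tissue label(s): {sorted(bad_tissue)}")
    bad_cohort = set(sheet["cohort"]) - COHORTS
    if bad_cohort:
        raise ValueError(f"unknown cohort label(s): {sorted(bad_cohort)}")
    sheet = sheet.copy()
    sheet["chamber_class"] = sheet["tissue"].map(chamber_class)
    return sheet


@dataclass
class MethylationDataset:
    """A probe x sample beta matrix with aligned detection p-values.

    Parameters
    ----------
    beta : DataFrame
        Methylation levels in [0,1]; index = probe ids, columns = sample ids.
    detection_p : DataFrame
        Detection p-values in [0,1], same shape/labels as ``beta``.
    samples : DataFrame
        Sample sheet with one row per ``beta`` column, in column order;
        carries the derived ``chamber_class``.
    array_total_probes : int
        Denominator of the loci-call-rate statistic: the total number of
        probes on the array platform (450K default), not the number of rows
        present in this dataset.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    samples: pd.DataFrame
    array_total_probes: int = 485577

    def __post_init__(self) -> None:
        if self.beta.shape != self.detection_p.shape:
            raise ValueError(
                f"beta {self.beta.shape} and detection_p "
                f"{self.detection_p.shape} shapes differ"
            )
        if not self.beta.index.equals(self.detection_p.index) or not (
            self.beta.columns.equals(self.detection_p.columns)
        ):
            raise ValueError("beta and detection_p are not label-aligned")
        b = self.beta.to_numpy()
        if np.isnan(b).any() or (b < 0).any() or (b > 1).any():
            i, j = np.argwhere(~((b >= 0) & (b <= 1)))[0]
            raise ValueError(
                f"beta value out of [0,1] at probe {self.beta.index[i]!r}, "
                f"sample {self.beta.columns[j]!r}: {b[i, j]}"
            )
        d = self.detection_p.to_numpy()
        if np.isnan(d).any() or (d < 0).any() or (d > 1).any():
            i, j = np.argwhere(~((d >= 0) & (d <= 1)))[0]
            raise ValueError(
                f"detection p out of [0,1] at probe "
                f"{self.detection_p.index[i]!r}, sample "
                f"{self.detection_p.columns[j]!r}: {d[i, j]}"
            )
        if "chamber_class" not in self.samples.columns:
            self.samples = validate_sample_sheet(self.samples)
        if list(self.samples["sample_id"]) != list(self.beta.columns):
            raise ValueError("sample sheet order does not match beta columns")
        if self.array_total_probes < len(self.beta):
            raise ValueError(
                "array_total_probes smaller than the number of probes present"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def chamber_classes(self) -> pd.Series:
        """chamber_class per sample, indexed by sample_id, in column order."""
        return self.samples.set_index("sample_id")["chamber_class"].loc[
            self.beta.columns
        ]

    def subset_samples(self, sample_ids: Iterable[str]) -> "MethylationDataset":
        ids = list(sample_ids)
        samples = self.samples[self.samples["sample_id"].isin(ids)]
        order = [s for s in self.beta.columns if s in set(ids)]
        samples = samples.set_index("sample_id").loc[order].reset_index()
        return MethylationDataset(
            beta=self.beta[order],
            detection_p=self.detection_p[order],
            samples=samples,
            array_total_probes=self.array_total_probes,
        )

    def subset_probes(self, probe_ids: Iterable[str]) -> "MethylationDataset":
        ids = [p for p in probe_ids if p in self.beta.index]
        return MethylationDataset(
            beta=self.beta.loc[ids],
            detection_p=self.detection_p.loc[ids],
            samples=self.samples,
            array_total_probes=self.array_total_probes,
        )


@dataclass
class PyroAssay:
    """Bisulfite-pyrosequencing result for one CpG locus.

    Percent methylation (0-100) per sample plus the run's methylated
    (expected high) and unmethylated (expected low) control values.
    """

    locus_id: str
    measurements: Mapping[str, float] = field(default_factory=dict)
    methylated_control: float = float("nan")
    unmethylated_control: float = float("nan")

    def __post_init__(self) -> None:
        for sid, v in self.measurements.items():
            if not (0.0 <= v <= 100.0):
                raise ValueError(
                    f"locus {self.locus_id!r}, sample {sid!r}: percent "
                    f"methylation {v} outside [0,100]"
                )
        for name, v in (
            ("methylated_control", self.methylated_control),
            ("unmethylated_control", self.unmethylated_control),
        ):
            if not np.isnan(v) and not (0.0 <= v <= 100.0):
                raise ValueError(
                    f"locus {self.locus_id!r}: {name} {v} outside [0,100]"
                )
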