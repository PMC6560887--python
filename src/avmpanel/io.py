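"""Readers and writers for the pipeline's delimited-text formats.

All tabular inputs are plain tab- or comma-delimited text with a header
row; the delimiter is auto-detected from the header line and can be
overridden. The marker panel is exported as BED6 with 0-based half-open
single-base intervals (probe positions themselves are 1-based, manifest
convention).
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ANNOTATION_COLUMNS,
    MethylationDataset,
    PyroAssay,
    normalize_chrom,
    validate_annotation,
    validate_sample_sheet,
)

__all__ = [
    "read_annotation",
    "write_annotation",
    "read_sample_sheet",
    "read_beta_matrix",
    "write_beta_matrix",
    "write_panel_bed",
    "read_pyro_tables",
    "write_pyro_tables",
]

_BOOL_TRUE = {"1", "true", "TRUE", "True"}
_BOOL_FALSE = {"0", "false", "FALSE", "False", ""}

#: Printed float precision for matrix round-trips (>= 6 significant digits).
_FLOAT_FMT = "%.8g"


def _sniff_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _parse_bool(value: str, *, column: str, line: int) -> bool:
    if value in _BOOL_TRUE:
        return True
    if value in _BOOL_FALSE:
        return False
    raise ValueError(f"line {line}: cannot parse boolean {column}={value!r}")


def _normalize_region(label: str) -> str:
    return label.replace("5'UTR", "5UTR").replace("3'UTR", "3UTR").strip()


def read_annotation(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a probe annotation table (Illumina-manifest-like delimited text).

    Required columns: probe_id, chrom, pos, genes, gene_regions,
    island_relation, snp_at_cpg_maf, snp_within_3bp_maf, cross_reactive,
    enhancer, dhs, heart_enhancer. Multi-gene cells use ';' internally;
    empty gene cells yield empty lists; empty MAF cells mean "no SNP".
    """
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    rows: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        required = ["probe_id"] + ANNOTATION_COLUMNS
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise ValueError(
                f"{path.name}: missing required column(s) {missing}"
            )
        for lineno, rec in enumerate(reader, start=2):
            genes = [g for g in rec["genes"].split(";") if g.strip()]
            regions = [
                _normalize_region(r) for r in rec["gene_regions"].split(";")
                if r.strip()
            ]
            try:
                pos = int(rec["pos"])
            except ValueError:
                raise ValueError(
                    f"line {lineno}: cannot parse pos {rec['pos']!r}"
                ) from None
            mafs = {}
            for col in ("snp_at_cpg_maf", "snp_within_3bp_maf"):
                cell = rec[col].strip()
                if cell == "":
                    mafs[col] = math.nan
                else:
                    try:
                        mafs[col] = float(cell)
                    except ValueError:
                        raise ValueError(
                            f"line {lineno}: cannot parse {col} {cell!r}"
                        ) from None
            rows.append(
                {
                    "probe_id": rec["probe_id"],
                    "chrom": normalize_chrom(rec["chrom"]),
                    "pos": pos,
                    "genes": genes,
                    "gene_regions": regions,
                    "island_relation": rec["island_relation"].strip(),
                    **mafs,
                    "cross_reactive": _parse_bool(
                        rec["cross_reactive"].strip(), column="cross_reactive",
                        line=lineno,
                    ),
                    "enhancer": _parse_bool(
                        rec["enhancer"].strip(), column="enhancer", line=lineno
                    ),
                    "dhs": _parse_bool(rec["dhs"].strip(), column="dhs", line=lineno),
                    "heart_enhancer": _parse_bool(
                        rec["heart_enhancer"].strip(), column="heart_enhancer",
                        line=lineno,
                    ),
                }
            )
    ann = pd.DataFrame(rows).set_index("probe_id")
    return validate_annotation(ann)


def write_annotation(ann: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    """Write an annotation table in the format :func:`read_annotation` accepts."""
    out = ann.copy()
    out.insert(0, "probe_id", out.index)
    out["genes"] = out["genes"].map(";".join)
    out["gene_regions"] = out["gene_regions"].map(";".join)
    for col in ("snp_at_cpg_maf", "snp_within_3bp_maf"):
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else _FLOAT_FMT % v)
    for col in ("cross_reactive", "enhancer", "dhs", "heart_enhancer"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep=delimiter, index=False)


def read_sample_sheet(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    delim = _sniff_delimiter(Path(path), delimiter)
    sheet = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False)
    sheet["replicate_group"] = sheet["replicate_group"].where(
        sheet["replicate_group"] != "", np.nan
    )
    return validate_sample_sheet(sheet)


def _read_matrix(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    delim = _sniff_delimiter(Path(path), delimiter)
    mat = pd.read_csv(path, sep=delim, index_col=0)
    mat.index = mat.index.astype(str)
    return mat


def read_beta_matrix(
    path_beta: str | Path,
    path_detp: str | Path,
    sample_sheet: pd.DataFrame,
    array_total_probes: int | None = None,
    delimiter: str | None = None,
) -> MethylationDataset:
    """Assemble a :class:`MethylationDataset` from beta and detection-p files.

    Both matrices must share probe order and sample columns; every column
    must match a ``sample_id`` in the sheet. Sample order follows the sheet.
    """
    beta = _read_matrix(path_beta, delimiter)
    detp = _read_matrix(path_detp, delimiter)
    if beta.shape != detp.shape or not beta.index.equals(detp.index):
        raise ValueError(
            f"beta matrix {beta.shape} and detection matrix {detp.shape} "
            "do not align"
        )
    known = set(sample_sheet["sample_id"])
    unknown = [c for c in beta.columns if c not in known]
    if unknown:
        raise ValueError(f"sample column(s) not in sample sheet: {unknown}")
    order = [s for s in sample_sheet["sample_id"] if s in set(beta.columns)]
    samples = (
        sample_sheet.set_index("sample_id").loc[order].reset_index()
    )
    kwargs = {}
    if array_total_probes is not None:
        kwargs["array_total_probes"] = array_total_probes
    return MethylationDataset(
        beta=beta[order], detection_p=detp[order], samples=samples, **kwargs
    )


def write_beta_matrix(
    dataset: MethylationDataset,
    path_beta: str | Path,
    path_detp: str | Path,
    delimiter: str = "\t",
) -> None:
    """Write the beta and detection matrices with round-trip precision."""
    dataset.beta.to_csv(
        path_beta, sep=delimiter, index_label="probe_id", float_format=_FLOAT_FMT
    )
    dataset.detection_p.to_csv(
        path_detp, sep=delimiter, index_label="probe_id", float_format=_FLOAT_FMT
    )


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = normalize_chrom(chrom)
    return (int(c), "") if c.isdigit() else (100, c)


def write_panel_bed(
    panel, annotation: pd.DataFrame, path: str | Path
) -> None:
    """Export panel loci as BED6 (chr-prefixed, 0-based half-open, 1 bp wide).

    Score is round(1000*|delta beta|) capped at 1000; strand is '.'.
    Lines are sorted by chromosome then start.
    """
    records = []
    for locus in panel.loci.itertuples():
        if locus.probe_id not in annotation.index:
            raise ValueError(
                f"panel locus {locus.probe_id!r} missing from annotation"
            )
        row = annotation.loc[locus.probe_id]
        score = min(1000, round(1000 * abs(locus.delta_beta_signed)))
        records.append(
            (
                str(row["chrom"]),
                int(row["pos"]) - 1,
                int(row["pos"]),
                locus.probe_id,
                score,
            )
        )
    records.sort(key=lambda r: (_chrom_sort_key(r[0]), r[1]))
    with open(path, "w") as fh:
        for chrom, start, end, name, score in records:
            fh.write(f"chr{chrom}\t{start}\t{end}\t{name}\t{score}\t.\n")


def write_pyro_tables(
    assays: Sequence[PyroAssay],
    path_measurements: str | Path,
    path_controls: str | Path,
    delimiter: str = "\t",
) -> None:
    """Write pyrosequencing results as a long measurements table + controls table."""
    meas = pd.DataFrame(
        [
            (a.locus_id, sid, pct)
            for a in assays
            for sid, pct in a.measurements.items()
        ],
        columns=["locus_id", "sample_id", "percent_methylation"],
    )
    ctrl = pd.DataFrame(
        [
            (a.locus_id, a.methylated_control, a.unmethylated_control)
            for a in assays
        ],
        columns=["locus_id", "methylated_control", "unmethylated_control"],
    )
    meas.to_csv(path_measurements, sep=delimiter, index=False, float_format=_FLOAT_FMT)
    ctrl.to_csv(path_controls, sep=delimiter, index=False, float_format=_FLOAT_FMT)


def read_pyro_tables(
    path_measurements: str | Path,
    path_controls: str | Path,
    delimiter: str | None = None,
) -> list[PyroAssay]:
    delim = _sniff_delimiter(Path(path_measurements), delimiter)
    meas = pd.read_csv(path_measurements, sep=delim)
    delim_c = _sniff_delimiter(Path(path_controls), delimiter)
    ctrl = pd.read_csv(path_controls, sep=delim_c).set_index("locus_id")
    assays = []
    for locus_id, grp in meas.groupby("locus_id", sort=False):
        assays.append(
            PyroAssay(
                locus_id=str(locus_id),
                measurements=dict(
                    zip(grp["sample_id"].astype(str), grp["percent_methylation"])
                ),
                methylated_control=float(ctrl.loc[locus_id, "methylated_control"]),
                unmethylated_control=float(ctrl.loc[locus_id, "unmethylated_control"]),
            )
        )
    return assays
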