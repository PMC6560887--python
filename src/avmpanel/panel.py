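"""Candidate CpG panel selection.

Turns the list of significantly differentially methylated loci into a fixed
marker panel by four rules: (1) take the upper 10% quantile by largest
|delta beta| — k = floor(fraction * n); (2) keep only loci annotated to a
RefSeq gene region between TSS200 and the 3'UTR (TSS1500 is outside that
window); (3) one locus per gene — the one with the larger |delta beta|
wins, the next-ranked locus backfills; (4) loci for which no assay could be
designed (a user-supplied exclusion list) are skipped and likewise
backfilled from the ranking.

Ties in |delta beta| break by ascending p, then lexicographic probe id, so
selection is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["CandidatePanel", "quantile_count", "select_candidates", "ALLOWED_REGIONS"]

#: Rule-2 window: TSS200 up to the 3'UTR (excludes TSS1500).
ALLOWED_REGIONS = frozenset({"TSS200", "5UTR", "1stExon", "Body", "3UTR"})


@dataclass
class CandidatePanel:
    """An ordered marker panel with full selection provenance.

    ``loci`` holds the selected loci sorted by descending |delta beta| with
    columns probe_id, gene, region, delta_beta_signed, rank. ``selection_log``
    records one action per significant locus: selected, backfilled (selected
    from beyond the initial top-k window), rejected_region,
    rejected_duplicate_gene, rejected_assay, or not_considered (ranked after
    the panel was already full).
    """

    loci: pd.DataFrame
    selection_log: pd.DataFrame
    k_target: int
    short: bool = False

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.loci["probe_id"])


def quantile_count(n_significant: int, fraction: float = 0.10) -> int:
    """Panel size under the upper-quantile rule: floor(fraction * n)."""
    if n_significant < 0:
        raise ValueError("n_significant must be >= 0")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return math.floor(fraction * n_significant + 1e-9)


def _panel_gene(genes, regions, allowed) -> tuple[str, str] | None:
    """First (gene, region) pair in annotation order with an allowed region."""
    for g, r in zip(genes, regions):
        if r in allowed:
            return g, r
    return None


def select_candidates(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    fraction: float = 0.10,
    allowed_regions=ALLOWED_REGIONS,
    assay_exclusions=frozenset(),
) -> CandidatePanel:
    """Apply selection rules (1)-(4) to the significant-locus table.

    ``results`` is a DifferentialResult table restricted to significant loci
    (index = probe_id, with delta_beta_abs, delta_beta_signed, p). Returns a
    :class:`CandidatePanel`; if fewer than k loci are eligible the panel is
    returned short with ``short=True``.
    """
    if results.index.has_duplicates:
        raise ValueError("duplicate probe ids in results")
    missing = results.index.difference(annotation.index)
    if len(missing):
        raise ValueError(f"locus {missing[0]!r} has no annotation row")
    allowed = frozenset(allowed_regions)
    excl = frozenset(assay_exclusions)

    k = quantile_count(len(results), fraction)
    ranking = results.loc[
        sorted(
            results.index,
            key=lambda pid: (
                -results.at[pid, "delta_beta_abs"],
                results.at[pid, "p"],
                pid,
            ),
        )
    ]

    taken_genes: set[str] = set()
    selected: list[dict] = []
    log: list[dict] = []
    for walk_rank, probe_id in enumerate(ranking.index):
        if len(selected) >= k:
            log.append(
                {
                    "probe_id": probe_id,
                    "action": "not_considered",
                    "detail": "panel already full",
                }
            )
            continue
        if probe_id in excl:
            log.append(
                {
                    "probe_id": probe_id,
                    "action": "rejected_assay",
                    "detail": "in assay exclusion list",
                }
            )
            continue
        ann = annotation.loc[probe_id]
        pair = _panel_gene(ann["genes"], ann["gene_regions"], allowed)
        if pair is None:
            log.append(
                {
                    "probe_id": probe_id,
                    "action": "rejected_region",
                    "detail": (
                        "no gene region in allowed set; has "
                        + (";".join(ann["gene_regions"]) or "none")
                    ),
                }
            )
            continue
        gene, region = pair
        if gene in taken_genes:
            log.append(
                {
                    "probe_id": probe_id,
                    "action": "rejected_duplicate_gene",
                    "detail": f"gene {gene} already represented",
                }
            )
            continue
        taken_genes.add(gene)
        selected.append(
            {
                "probe_id": probe_id,
                "gene": gene,
                "region": region,
                "delta_beta_signed": float(
                    results.at[probe_id, "delta_beta_signed"]
                ),
                "rank": len(selected) + 1,
            }
        )
        log.append(
            {
                "probe_id": probe_id,
                "action": "selected" if walk_rank < k else "backfilled",
                "detail": f"rank {len(selected)}",
            }
        )

    loci = pd.DataFrame(
        selected,
        columns=["probe_id", "gene", "region", "delta_beta_signed", "rank"],
    )
    log_df = pd.DataFrame(log, columns=["probe_id", "action", "detail"])
    return CandidatePanel(
        loci=loci,
        selection_log=log_df,
        k_target=k,
        short=len(selected) < k,
    )
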