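import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from avmpanel.datamodel import MethylationDataset
from avmpanel.simulate import SimulationConfig, generate_annotation, simulate_tissue_cohort

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_annotation(rows: list[dict]) -> pd.DataFrame:
    """Build an annotation table from partial row dicts (index = probe_id)."""
    defaults = {
        "chrom": "1",
        "pos": 1000,
        "genes": [],
        "gene_regions": [],
        "island_relation": "OpenSea",
        "snp_at_cpg_maf": np.nan,
        "snp_within_3bp_maf": np.nan,
        "cross_reactive": False,
        "enhancer": False,
        "dhs": False,
        "heart_enhancer": False,
    }
    full = []
    for row in rows:
        rec = dict(defaults, **row)
        full.append(rec)
    df = pd.DataFrame(full)
    return df.set_index("probe_id")


def make_dataset(
    beta: dict[str, list[float]],
    probe_ids: list[str],
    tissues: dict[str, str] | None = None,
    detp: dict[str, list[float]] | None = None,
    replicate_groups: dict[str, str] | None = None,
    array_total: int | None = None,
) -> MethylationDataset:
    """Small dataset from per-sample beta columns; tissues default to IAS."""
    tissues = tissues or {}
    replicate_groups = replicate_groups or {}
    beta_df = pd.DataFrame(beta, index=probe_ids)
    detp_df = (
        pd.DataFrame(detp, index=probe_ids)
        if detp is not None
        else pd.DataFrame(0.0, index=beta_df.index, columns=beta_df.columns)
    )
    samples = pd.DataFrame(
        {
            "sample_id": list(beta.keys()),
            "patient_id": [f"pt_{s}" for s in beta.keys()],
            "tissue": [tissues.get(s, "IAS") for s in beta.keys()],
            "cohort": "discovery",
            "replicate_group": [replicate_groups.get(s) for s in beta.keys()],
            "disease": "CHD",
        }
    )
    return MethylationDataset(
        beta=beta_df,
        detection_p=detp_df,
        samples=samples,
        array_total_probes=array_total or max(485577, len(probe_ids)),
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast simulated study: 4,000 probes, 40 planted loci."""
    return SimulationConfig(n_probes=4000, n_true_loci=40, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    annotation, truth = generate_annotation(small_config)
    cohort = simulate_tissue_cohort(small_config, annotation, truth)
    return small_config, annotation, truth, cohort
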