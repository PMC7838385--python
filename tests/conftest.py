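import numpy as np
import pandas as pd
import pytest

from fmena.datatypes import RawProbeTable, StudyDesign
from fmena.preprocess import run_preprocessing
from fmena.synthetic import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Default-condition synthetic dataset (4 lakes x 6 samples)."""
    return generate_dataset(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def preprocessed(dataset):
    return run_preprocessing(dataset.raw, dataset.design)


@pytest.fixture(scope="session")
def clean_dataset():
    """Full-detection, no-SNR-failure variant for mechanism-recovery tests."""
    return generate_dataset(
        SynthConfig(seed=11, detection_prob=1.0, snr_fail_prob=0.0, stress_effect=1.0)
    )


def make_design(n_lakes=2, samples_per_lake=3):
    sample_to_lake = {}
    lake_to_group = {}
    for i in range(n_lakes):
        lake = f"L{i + 1}"
        lake_to_group[lake] = "low" if i < n_lakes // 2 else "high"
        for j in range(samples_per_lake):
            sample_to_lake[f"{lake}s{j + 1}"] = lake
    return StudyDesign(sample_to_lake, lake_to_group)


def make_raw(signal: dict, snr: dict, positive: list[str] | None = None) -> RawProbeTable:
    """Build a toy probe table from {probe: {sample: value}} dicts."""
    sig = pd.DataFrame(signal).T.astype(float)
    snr_df = pd.DataFrame(snr).T.astype(float)
    pos = pd.Series(False, index=sig.index)
    for p in positive or []:
        pos[p] = True
    return RawProbeTable(sig, snr_df, pos)


def make_annotation(probes, categories=None, families=None, lineages=None) -> pd.DataFrame:
    n = len(probes)
    return pd.DataFrame(
        {
            "gene_family": families or [f"fam{i}" for i in range(n)],
            "subcategory": ["sub"] * n,
            "category": categories or ["carbon cycling"] * n,
            "lineage": lineages or ["Firmicutes"] * n,
        },
        index=pd.Index(probes, name="probe_id"),
    )
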