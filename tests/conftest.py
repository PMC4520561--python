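import numpy as np
import pandas as pd
import pytest

from csplandscape import CountTable, SimulationConfig, simulate_annotation, simulate_counts


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_genes=500, libsize=500_000, n_replicates=3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    ann = simulate_annotation(small_config)
    counts, truth = simulate_counts(ann, small_config)
    return ann, counts, truth


def null_config(seed: int, n_genes: int = 2000, n_replicates: int = 3) -> SimulationConfig:
    """One-condition configuration with every binding effect switched off."""
    zero = {c: {"null": 0.0} for c in ("MPR", "CPR", "SPR", "CSP", "OTHER")}
    return SimulationConfig(
        n_genes=n_genes,
        binding_effect=zero,
        conditions=("null",),
        n_replicates=n_replicates,
        seed=seed,
    )


def mpr_effect_config(seed: int, n_genes: int = 2000, effect: float = 1.0) -> SimulationConfig:
    """One-condition configuration with a +effect log2 shift for MPRs only."""
    shifts = {c: {"on": 0.0} for c in ("CPR", "SPR", "CSP", "OTHER")}
    shifts["MPR"] = {"on": effect}
    return SimulationConfig(
        n_genes=n_genes,
        binding_effect=shifts,
        conditions=("on",),
        n_replicates=3,
        seed=seed,
    )


@pytest.fixture
def toy_counts():
    """Five genes, two samples per fraction, hand-checkable numbers."""
    genes = ["gA", "gB", "gC", "gD", "gR"]
    ann = pd.DataFrame(
        {
            "gene_id": genes,
            "length_nt": [1000, 500, 2000, 250, 1500],
            "category": ["MPR", "CPR", "OTHER", "SPR", "NONCODING"],
        }
    ).set_index("gene_id")
    counts = pd.DataFrame(
        {
            "extract_c_r1": [100, 50, 400, 10, 900],
            "extract_c_r2": [120, 40, 380, 0, 800],
            "pulldown_c_r1": [300, 10, 200, 5, 700],
            "pulldown_c_r2": [280, 15, 180, 0, 600],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    samples = pd.DataFrame(
        {
            "sample_id": counts.columns,
            "fraction": ["extract", "extract", "pulldown", "pulldown"],
            "condition": ["c"] * 4,
            "replicate": [1, 2, 1, 2],
        }
    ).set_index("sample_id")
    return ann, CountTable(counts, samples)
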