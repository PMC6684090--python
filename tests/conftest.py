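import numpy as np
import pandas as pd
import pytest

from mprakit.io import BarcodeMap, CountTable
from mprakit.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """Tiny simulated experiment: 6 variants x 2 alleles x 6 barcodes, 2+3 samples."""
    cfg = SimConfig(n_variants=6, n_controls=2, n_barcodes=6, ts=0.0)
    table, design, truth = simulate_experiment(cfg, seed=11)
    return table, design, truth


@pytest.fixture(scope="session")
def medium_experiment():
    """Mixed-effect experiment for analysis tests: 12 variants x 10 barcodes."""
    ts = np.array([0.0] * 6 + [1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
    cfg = SimConfig(n_variants=12, n_controls=2, n_barcodes=10, ts=ts)
    table, design, truth = simulate_experiment(cfg, seed=23)
    return table, design, truth


def make_table(counts: dict, materials: dict, barcodes=None) -> CountTable:
    """Build a CountTable from plain dicts (column -> list of counts)."""
    df = pd.DataFrame(counts)
    if barcodes is not None:
        df.index = barcodes
    else:
        df.index = [f"BC{i:04d}" for i in range(len(df))]
    samples = pd.DataFrame(
        {"material": [materials[c] for c in df.columns]}, index=df.columns
    )
    samples.index.name = "sample_id"
    return CountTable(df, samples)


def make_design(barcodes, variant_ids, alleles) -> BarcodeMap:
    df = pd.DataFrame(
        {"barcode": barcodes, "variant_id": variant_ids, "allele": alleles}
    ).set_index("barcode")
    return BarcodeMap(df)
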