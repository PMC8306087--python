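import warnings

import numpy as np
import pandas as pd
import pytest

from rohmap import GenotypeMatrix, SimConfig, simulate_dataset

warnings.filterwarnings("ignore", message="skipping .* monomorphic")


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition synthetic dataset shared across tests."""
    return simulate_dataset(SimConfig(seed=2))


@pytest.fixture(scope="session")
def small_sim():
    """A reduced dataset for fast structural tests."""
    return simulate_dataset(SimConfig(seed=3, n_wgs_variants=800,
                                      n_array_snps=400))


def make_gm(dosage, positions=None, chrom="chr1", status=None, ref=None,
            alt=None):
    """Hand-build a GenotypeMatrix from a dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    variants = pd.DataFrame({
        "chrom": [chrom] * m, "pos": np.asarray(positions, dtype=np.int64),
        "ref": list(ref) if ref is not None else ["A"] * m,
        "alt": list(alt) if alt is not None else ["G"] * m,
        "id": [None] * m,
    })
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "status": list(status) if status is not None else ["unknown"] * n,
        "excluded": [False] * n,
    })
    return GenotypeMatrix(dosage, variants, samples)
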