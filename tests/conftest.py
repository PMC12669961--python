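import numpy as np
import pandas as pd
import pytest

from devenh.motifs import calibrate_all
from devenh.synthetic import SynthConfig, generate_study


def small_config(seed: int = 1) -> SynthConfig:
    """A scaled-down study for fast unit tests (~250 cells, 3 x 2 Mb)."""
    return SynthConfig(seed=seed, cells_per_cluster=40, n_genes=120, n_snps=24)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_config())


@pytest.fixture(scope="session")
def small_reference(small_study):
    return small_study.reference


@pytest.fixture(scope="session")
def calibrated_pwms(small_reference):
    return calibrate_all(small_reference.pwms)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def toy_tss():
    return pd.DataFrame({
        "chrom": ["chrA", "chrA", "chrB"],
        "tss": [10_000, 30_000, 12_000],
        "gene": ["G1", "G2", "G3"],
        "strand": ["+", "+", "+"],
    })
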