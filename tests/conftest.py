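import numpy as np
import pandas as pd
import pytest

from pgs_spectrum.synthdata import SimulationConfig, TraitSpec, simulate_study


def small_config(seed: int = 7, **kw) -> SimulationConfig:
    """A fast, fully-featured study configuration for unit tests."""
    defaults = dict(
        n_subjects_per_ancestry={"EA": 400, "AA": 200},
        n_variants=300, n_blocks=15,
        trait_specs=[
            TraitSpec("ADHD", 50000, 0.25, 0.5, 1.0, 10.0),
            TraitSpec("SCZ", 80000, 0.25, 0.5, 0.0, 20.0),
        ],
        target_or_per_sd={"ADHD": {"EA": 1.3, "AA": 1.0}},
        seed=seed,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_variants():
    """Ten-variant table with known alleles for harmonization tests."""
    return pd.DataFrame({
        "id": [f"v{i}" for i in range(10)],
        "chrom": "1",
        "pos": np.arange(1, 11) * 1000,
        "a1": list("AAGGCCTTAG"),
        "a2": list("GCAATTGCTT"),
    })
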