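import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rnaseqbench import default_design, default_manifest, generate_panels, generate_truth

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def truth(design):
    return generate_truth(60, design, de_fraction=0.2, effect_size=2.0,
                          seed=7)


@pytest.fixture(scope="session")
def manifest():
    return default_manifest(4, noise_range=(0.05, 0.4), seed=7)


@pytest.fixture(scope="session")
def panels(truth, manifest, design):
    return generate_panels(truth, manifest, design, seed=7)


@pytest.fixture()
def toy_ct():
    """4 genes x 5 samples, duplicate-free, hand-enterable Ct values."""
    rng = np.random.default_rng(11)
    genes = ["gA", "gB", "gC", "gD"]
    samples = [f"s{i}" for i in range(1, 6)]
    rows = []
    for g in genes:
        base = rng.uniform(24, 30)
        for s in samples:
            rows.append((g, s, 1, base + rng.normal(0, 1.0)))
    return pd.DataFrame(rows, columns=["gene", "sample", "duplicate", "ct"])
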