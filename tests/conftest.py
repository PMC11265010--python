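import numpy as np
import pandas as pd
import pytest

import gveco as g


@pytest.fixture(scope="session")
def community():
    """Moderate simulated community shared across read-only tests."""
    cov, samples, truth = g.simulate_community(
        n_phylotypes=150, n_samples_per_habitat=10, seed=42)
    return cov, samples, truth


@pytest.fixture(scope="session")
def normalized(community):
    cov, samples, _ = community
    return g.normalize_coverage(cov, samples)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_sample_table(n_per_habitat: int = 2, seed: int = 0) -> g.SampleTable:
    """Small hand-sized sample table with all habitats and env columns."""
    rng = np.random.default_rng(seed)
    rows = []
    for hab in g.HABITATS:
        for i in range(n_per_habitat):
            rows.append({
                "sample_id": f"{hab}{i}", "habitat": hab,
                "read_count": int(rng.integers(10**6, 10**7)),
                **{v: float(rng.normal(10, 3)) for v in g.ENV_VARIABLES},
            })
    df = pd.DataFrame(rows).set_index("sample_id")
    df["LAT"] = rng.uniform(-60, 60, len(df))
    df["LON"] = rng.uniform(-170, 170, len(df))
    return g.SampleTable(df)
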