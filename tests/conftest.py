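import numpy as np
import pandas as pd
import pytest

from ohsurvey import default_codebook, default_config, generate


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture(scope="session")
def cohort():
    """The default synthetic cohort (n=62, seed 42)."""
    return generate(default_config())


@pytest.fixture(scope="session")
def big_cohort():
    """A large cohort for Monte-Carlo checks (n=10,000, seed 7)."""
    from dataclasses import replace

    return generate(replace(default_config(), n=10_000, seed=7))


def hub_and_filler_symptoms() -> pd.DataFrame:
    """A symptom matrix whose retained co-occurrence network is, by
    construction, a 4-regular graph on 13 nodes (26 edges).

    13 core symptoms form a circulant graph (each node tied to its 2 nearest
    neighbours on a ring) with co-occurrence weight 2 per pair; 15 filler
    symptoms contribute 58 weight-1 edges, so 26 = ceil(0.30 * 84) core edges
    survive the top-30% filter and every filler node is dropped as isolated.
    """
    core = [f"core_{i:02d}" for i in range(13)]
    filler = [f"filler_{i:02d}" for i in range(15)]
    columns = core + filler
    rows = []
    for i in range(13):
        for step in (1, 2):
            j = (i + step) % 13
            for _ in range(2):
                row = dict.fromkeys(columns, 0)
                row[core[i]] = 1
                row[core[j]] = 1
                rows.append(row)
    for k in range(58):
        row = dict.fromkeys(columns, 0)
        row[filler[k % 15]] = 1
        row[core[k % 13]] = 1
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)
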