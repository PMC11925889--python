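import numpy as np
import pandas as pd
import pytest

import microkeystone as mk


@pytest.fixture(scope="session")
def small_counts() -> mk.CountTable:
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.integers(0, 200, size=(20, 12)),
        index=[f"F{i:02d}" for i in range(20)],
        columns=[f"S{j:02d}" for j in range(12)],
    )
    data.iloc[0] += 1  # guarantee at least one feature present everywhere
    return mk.CountTable(data)


@pytest.fixture(scope="session")
def small_meta(small_counts) -> mk.SampleMetadata:
    groups = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
    return mk.SampleMetadata(
        pd.Series(groups, index=small_counts.sample_ids, name="group")
    )


@pytest.fixture(scope="session")
def community():
    """Default synthetic community (4 groups x 10), shared across tests."""
    cfg = mk.CommunityConfig(n_per_group=10)
    table, meta, truth = mk.generate_community(cfg, seed=11)
    return table, meta, truth
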