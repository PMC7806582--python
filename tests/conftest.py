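import numpy as np
import pandas as pd
import pytest
import skbio

import isobiome as ib

ib.setup_logging("WARNING")


@pytest.fixture
def toy_tree() -> skbio.TreeNode:
    """((A:1,B:1):1,(C:1,D:1):1); total branch length 6."""
    return skbio.TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1):0;"])


@pytest.fixture
def toy_table() -> ib.FeatureTable:
    counts = pd.DataFrame(
        [[1, 1, 0, 0], [1, 0, 1, 0], [1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 2]],
        index=[f"s{i}" for i in range(1, 7)],
        columns=list("ABCD"),
    )
    return ib.FeatureTable(counts)


@pytest.fixture
def mixing_cfg() -> ib.MixingModelConfig:
    """Baselines for which alpha=0.41 maps to d13C=-19.95 and the
    alpha-weighted d15N baseline is 8.0."""
    return ib.MixingModelConfig(
        d13c_littoral=-17.0,
        d13c_pelagic=-22.0,
        d15n_littoral=8.0,
        d15n_pelagic=8.0,
    )


@pytest.fixture(scope="session")
def null_study():
    """A 60-bird, 300-ASV desk-scale study with no planted effects."""
    cfg = ib.SimulationConfig(
        n_birds=60, n_asvs=300, depth_mean=5000, theta=20, seed=1234, n_controls=0
    )
    rng = np.random.default_rng(cfg.seed)
    metadata, isotopes, metrics = ib.simulate_cohort(cfg, rng)
    table, truth = ib.simulate_feature_table(cfg, metrics, rng)
    return cfg, metadata, isotopes, metrics, table, truth
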