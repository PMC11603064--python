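import numpy as np
import pandas as pd
import pytest

from dosewise.simulate import SimConfig, simulate_dataset, simulate_null_dataset


@pytest.fixture(scope="session")
def sim_small():
    """Small dataset with all archetypes planted (fast unit-test fixture)."""
    cfg = SimConfig(n_genes=800, n_cells_per_sample=200, seed=3)
    return cfg, *simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sim_default():
    """Spec-scale dataset with planted effects and 200 timing-shifted genes."""
    cfg = SimConfig(seed=1, n_timeshift_genes=200)
    return cfg, *simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sim_null():
    """Spec-scale null dataset (2,000 genes, 3 samples/dose, 500 cells/sample)."""
    cfg = SimConfig(seed=1)
    return cfg, *simulate_null_dataset(cfg)


@pytest.fixture(scope="session")
def pseudobulk_null(sim_null):
    """Sample-level pseudobulk of the null dataset (single pooled cluster)."""
    from dosewise.pseudobulk import aggregate_pseudobulk

    _, counts, cells, _ = sim_null
    pooled = cells.copy()
    pooled["cluster"] = "all"
    return aggregate_pseudobulk(counts, pooled)


@pytest.fixture(scope="session")
def pseudobulk_default(sim_default):
    from dosewise.pseudobulk import aggregate_pseudobulk

    _, counts, cells, _ = sim_default
    pooled = cells.copy()
    pooled["cluster"] = "all"
    return aggregate_pseudobulk(counts, pooled)


@pytest.fixture(scope="session")
def trajectory_default(sim_default):
    from dosewise.trajectory import assign_pseudotime

    _, counts, cells, _ = sim_default
    emb = cells[["embed_x", "embed_y"]]
    return assign_pseudotime(emb, root=emb["embed_x"].idxmin(), k=15)


@pytest.fixture(scope="session")
def trajectory_null(sim_null):
    from dosewise.trajectory import assign_pseudotime

    _, counts, cells, _ = sim_null
    emb = cells[["embed_x", "embed_y"]]
    return assign_pseudotime(emb, root=emb["embed_x"].idxmin(), k=15)


@pytest.fixture(scope="session")
def norm_default(sim_default):
    from dosewise.preprocess import normalize_log

    _, counts, _, _ = sim_default
    return normalize_log(counts)


@pytest.fixture(scope="session")
def norm_null(sim_null):
    from dosewise.preprocess import normalize_log

    _, counts, _, _ = sim_null
    return normalize_log(counts)
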