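import numpy as np
import pandas as pd
import pytest

from morphoprofile import (GeneratorConfig, MetaTable, MorphDataset,
                           ParameterMeta, generate_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_meta():
    return MetaTable([
        ParameterMeta("size", "cell", "nonneg"),
        ParameterMeta("roundness", "cell", "ratio"),
        ParameterMeta("size_cv", "cell", "cv", mean_partner="size"),
        ParameterMeta("budded", "cell", "proportion", trials_column="n_budded_pool"),
        ParameterMeta("actin_patch", "actin", "nonneg"),
        ParameterMeta("nuc_area", "nucleus", "nonneg", unimodal=False),
    ])


@pytest.fixture
def small_dataset(small_meta):
    """3 strains x 5 replicates, hand-sized and fully valid."""
    r = np.random.default_rng(7)
    rows = [(s, f"r{i+1}") for s in ("WT", "mutA", "mutB") for i in range(5)]
    idx = pd.MultiIndex.from_tuples(rows, names=("strain", "replicate"))
    n = len(idx)
    size = r.gamma(40, 0.5, n)
    values = pd.DataFrame({
        "size": size,
        "roundness": r.beta(8, 3, n),
        "size_cv": 0.2 * (size / size.mean()) ** -0.5 * (1 + r.normal(0, .05, n)),
        "budded": r.binomial(150, 0.4, n).astype(float),
        "actin_patch": r.gamma(15, 0.3, n),
        "nuc_area": r.gamma(30, 0.1, n),
    }, index=idx)
    trials = pd.DataFrame({"n_budded_pool": np.full(n, 150.0)}, index=idx)
    cells = pd.Series(r.integers(200, 600, n).astype(float), index=idx)
    return MorphDataset(values=values, cell_count=cells, meta=small_meta,
                        wt_strain_id="WT", trials=trials).validate()


@pytest.fixture(scope="session")
def tiny_study():
    """A small full-structure synthetic study shared by slower tests."""
    cfg = GeneratorConfig(
        n_params={"nonneg": 40, "ratio": 20, "cv": 16, "proportion": 10},
        n_mutants=8, n_wt_replicates=40, seed=2024)
    ds, truth = generate_dataset(cfg)
    return ds, truth
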