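import numpy as np
import pandas as pd
import pytest

from focaltax.tables import CountTable


@pytest.fixture
def star_tree() -> str:
    """Five-tip star tree with unit branch lengths."""
    return "(t1:1,t2:1,t3:1,t4:1,t5:1);"


@pytest.fixture
def toy_table() -> CountTable:
    df = pd.DataFrame(
        [[5, 0, 3], [0, 2, 1], [10, 10, 0], [1, 1, 1]],
        index=["s1", "s2", "s3", "s4"],
        columns=["otuA", "otuB", "otuC"],
    )
    return CountTable(df)


@pytest.fixture
def toy_meta() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": ["u1", "u2", "u3", "u1"],
            "collection_order": [1, 1, 1, 2],
            "body_site": ["feces", "feces", "skin", "feces"],
        },
        index=["s1", "s2", "s3", "s4"],
    )


def simulate_zinb(seed, n=5000, k=1.0,
                  gamma=(-9.5, 0.5, -0.5), beta=(-9.2, 0.3, -0.3)):
    """Intercept + 2-covariate zero-inflated NB cohort with log-depth
    offsets in both components; returns (y, design, truth arrays)."""
    from focaltax import zinb

    rng = np.random.default_rng(seed)
    meta = pd.DataFrame(
        {"x1": rng.normal(size=n), "x2": rng.binomial(1, 0.5, n).astype(float)},
        index=[f"s{i}" for i in range(n)],
    )
    depths = pd.Series(
        np.round(rng.lognormal(np.log(2e4), 0.5, n)).astype(int), index=meta.index
    )
    g, b = np.asarray(gamma), np.asarray(beta)
    X = np.column_stack([np.ones(n), meta.x1, meta.x2])
    off = np.log(depths.to_numpy())
    pi = 1.0 / (1.0 + np.exp(-(X @ g + off)))
    mu = np.exp(X @ b + off)
    y = rng.negative_binomial(k, k / (k + mu)).astype(float)
    y[rng.random(n) < pi] = 0
    design = zinb.build_design(meta, depths, ["x1", "x2"])
    return y, design, g, b
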