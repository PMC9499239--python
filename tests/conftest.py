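import anndata as ad
import numpy as np
import pandas as pd
import pytest

from crosstalk.io import FractionTable, LigandTargetMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_expr(counts: dict, n_genes: int = 4, seed: int = 0) -> ad.AnnData:
    """Tiny AnnData from {(sample, condition, cell_type): n_cells}."""
    rng = np.random.default_rng(seed)
    rows, obs = [], []
    for (sample, cond, ctype), n in counts.items():
        for _ in range(n):
            rows.append(rng.poisson(1.0, n_genes))
            obs.append({"sample_id": sample, "condition": cond, "cell_type": ctype})
    X = np.array(rows, dtype=float)
    obs = pd.DataFrame(obs, index=[f"c{i}" for i in range(len(obs))])
    var = pd.DataFrame(index=[f"g{j}" for j in range(n_genes)])
    return ad.AnnData(X=X, obs=obs, var=var)


@pytest.fixture
def tiny_expr():
    return make_expr(
        {
            ("s1", "case", "A"): 3,
            ("s1", "case", "B"): 1,
            ("s2", "control", "A"): 1,
            ("s2", "control", "B"): 3,
        }
    )


@pytest.fixture
def fraction_table():
    values = pd.DataFrame(
        {
            "A": [0.10, 0.12, 0.11, 0.50, 0.52, 0.49],
            "B": [0.30, 0.31, 0.29, 0.10, 0.12, 0.11],
        },
        index=[f"s{i}" for i in range(6)],
    )
    cond = pd.Series(["case"] * 3 + ["control"] * 3, index=values.index)
    return FractionTable(values=values, conditions=cond)


@pytest.fixture
def identity_prior():
    table = pd.DataFrame(np.eye(2), index=["t1", "t2"], columns=["l1", "l2"])
    return LigandTargetMatrix.from_frame(table)
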