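import numpy as np
import pandas as pd
import pytest

from synthcohort import TableData, VariableSpec
from synthcohort.bn_core import BayesNetwork, CategoricalCPD, NetworkStructure


def binary_spec(name, states=("0", "1"), **kw):
    return VariableSpec(name, "categorical", states, **kw)


@pytest.fixture
def chain_net():
    """A -> B -> C with fixed, hand-chosen CPTs (binary states '0'/'1')."""
    specs = tuple(binary_spec(n) for n in "ABC")
    st = NetworkStructure(("A", "B", "C"), frozenset({("A", "B"), ("B", "C")}))
    cpds = {
        "A": CategoricalCPD("A", (), [[0.3, 0.7]]),
        "B": CategoricalCPD("B", ("A",), [[0.9, 0.1], [0.4, 0.6]]),
        "C": CategoricalCPD("C", ("B",), [[0.2, 0.8], [0.75, 0.25]]),
    }
    return BayesNetwork(st, cpds, specs)


def random_binary_dag_net(n_nodes: int, seed: int) -> BayesNetwork:
    """A random DAG over binary nodes with random (Dirichlet) CPTs."""
    rng = np.random.default_rng(seed)
    names = tuple(f"X{i}" for i in range(n_nodes))
    edges = set()
    for j in range(n_nodes):
        for i in range(j):
            if rng.random() < 0.4 and sum(1 for p, c in edges if c == names[j]) < 3:
                edges.add((names[i], names[j]))
    st = NetworkStructure(names, frozenset(edges))
    specs = tuple(binary_spec(n) for n in names)
    cpds = {}
    for n in names:
        n_cfg = 2 ** len(st.parents(n))
        table = rng.dirichlet([1.0, 1.0], size=n_cfg)
        cpds[n] = CategoricalCPD(n, st.parents(n), table)
    return BayesNetwork(st, cpds, specs)


def random_mixed_table(n_rows: int, seed: int, missing_frac: float = 0.1) -> TableData:
    """A random cohort with categorical + continuous columns and sentinels."""
    rng = np.random.default_rng(seed)
    specs = (
        VariableSpec("colour", "categorical", ("red", "green", "blue")),
        VariableSpec("flag", "categorical", ("no", "yes")),
        VariableSpec("height", "continuous", units="cm"),
        VariableSpec("score", "continuous"),
    )
    df = pd.DataFrame(
        {
            "colour": rng.choice(["red", "green", "blue"], n_rows),
            "flag": rng.choice(["no", "yes"], n_rows),
            "height": rng.normal(170, 10, n_rows),
            "score": rng.exponential(2.0, n_rows),
        }
    )
    for col in df.columns:
        mask = rng.random(n_rows) < missing_frac
        if mask.any():
            if df[col].dtype == object:
                s = df[col].astype(object)
                s[mask] = np.nan
                df[col] = s
            else:
                df.loc[mask, col] = np.nan
    return TableData(specs, df)
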