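"""Bayesian network core: joint factorisation, sampling, fitting, search."""

import itertools

import numpy as np
import pandas as pd
import pytest

from synthcohort import TableData, ValidationError, VariableSpec
from synthcohort.bn_core import (
    BayesNetwork,
    CategoricalCPD,
    EMConfig,
    NetworkStructure,
    SchemaError,
    StructureConfig,
    fit_parameters,
    joint_probability,
    learn_structure,
    logic_sample,
    whitelist_edit,
)

from conftest import binary_spec, random_binary_dag_net


def brute_force_joint(net, record):
    """Chain-rule product computed independently of the implementation."""
    p = 1.0
    for n in net.structure.nodes:
        cpd = net.cpds[n]
        parents = net.structure.parents(n)
        cfg = 0
        for par in parents:
            cfg = cfg * net.spec(par).n_states + net.spec(par).state_index(record[par])
        p *= cpd.table[cfg, net.spec(n).state_index(record[n])]
    return p


# ---------------------------------------------------------------------------
# joint probability


def test_single_uniform_node():
    st = NetworkStructure(("A",), frozenset())
    net = BayesNetwork(st, {"A": CategoricalCPD("A", (), [[0.5, 0.5]])}, (binary_spec("A", ("a", "b")),))
    assert joint_probability(net, {"A": "a"}) == pytest.approx(0.5)


def test_chain_matches_enumeration_oracle(chain_net):
    for combo in itertools.product("01", repeat=3):
        rec = dict(zip("ABC", combo))
        assert joint_probability(chain_net, rec) == pytest.approx(
            brute_force_joint(chain_net, rec), abs=1e-12
        )


@pytest.mark.parametrize("seed", [0, 5, 9])
def test_joint_normalises_on_random_dags(seed):
    net = random_binary_dag_net(5, seed)
    total = sum(
        joint_probability(net, {f"X{i}": s for i, s in enumerate(c)})
        for c in itertools.product("01", repeat=5)
    )
    assert total == pytest.approx(1.0, abs=1e-9)


def test_incomplete_record_lists_missing_nodes(chain_net):
    with pytest.raises(ValidationError, match="C"):
        joint_probability(chain_net, {"A": "0", "B": "1"})


# ---------------------------------------------------------------------------
# logic sampling


def test_point_mass_cpd_samples_constant():
    st = NetworkStructure(("A",), frozenset())
    net = BayesNetwork(
        st, {"A": CategoricalCPD("A", (), [[0.0, 1.0]])}, (binary_spec("A", ("x", "y")),)
    )
    out = logic_sample(net, 50, seed=0)
    assert (out.df["A"] == "y").all()


def test_evidence_clamps_every_row(chain_net):
    out = logic_sample(chain_net, 200, evidence={"B": "1"}, seed=1)
    assert (out.df["B"] == "1").all()
    with pytest.raises(ValidationError):
        logic_sample(chain_net, 5, evidence={"B": "maybe"})
    with pytest.raises(ValidationError):
        logic_sample(chain_net, 5, evidence={"nope": "1"})


def test_sampling_matches_enumerated_marginals():
    net = random_binary_dag_net(6, seed=21)
    n = 50000
    sample = logic_sample(net, n, seed=4)
    # marginals by exhaustive enumeration
    marg = {f"X{i}": 0.0 for i in range(6)}
    for combo in itertools.product("01", repeat=6):
        rec = {f"X{i}": s for i, s in enumerate(combo)}
        p = joint_probability(net, rec)
        for k, s in rec.items():
            if s == "1":
                marg[k] += p
    for k, p in marg.items():
        freq = (sample.df[k] == "1").mean()
        half_width = 3 * np.sqrt(p * (1 - p) / n)  # 99.7% binomial interval
        assert abs(freq - p) < max(half_width, 1e-3), k


def test_sampling_reproducible_and_seed_sensitive(chain_net):
    a = logic_sample(chain_net, 500, seed=7)
    b = logic_sample(chain_net, 500, seed=7)
    c = logic_sample(chain_net, 500, seed=8)
    assert a.equals(b)
    assert not a.equals(c)


# ---------------------------------------------------------------------------
# parameter fitting


def test_complete_data_matches_counting_oracle():
    # 400 rows engineered so that P(B=1 | A=1) = 0.75 exactly
    a = ["0"] * 200 + ["1"] * 200
    b = ["0"] * 150 + ["1"] * 50 + ["0"] * 50 + ["1"] * 150
    specs = (binary_spec("A"), binary_spec("B"))
    data = TableData(specs, pd.DataFrame({"A": a, "B": b}))
    st = NetworkStructure(("A", "B"), frozenset({("A", "B")}))
    net = fit_parameters(st, data, EMConfig(seed=0, smoothing=0.5))
    # smoothed counting oracle: (150 + 0.5) / (200 + 1)
    assert net.cpds["B"].table[1, 1] == pytest.approx((150 + 0.5) / 201, abs=1e-12)
    assert net.cpds["B"].table[1, 1] == pytest.approx(0.75, abs=0.01)


def test_em_recovers_masked_child_cpd():
    st = NetworkStructure(("A", "B"), frozenset({("A", "B")}))
    cpds = {
        "A": CategoricalCPD("A", (), [[0.35, 0.65]]),
        "B": CategoricalCPD("B", ("A",), [[0.8, 0.2], [0.25, 0.75]]),
    }
    truth = BayesNetwork(st, cpds, (binary_spec("A"), binary_spec("B")))
    data = logic_sample(truth, 20000, seed=11)
    rng = np.random.default_rng(4)
    df = data.df.copy()
    col = df["B"].astype(object)
    col[rng.random(20000) < 0.3] = np.nan
    df["B"] = col
    masked = TableData(data.variables, df)
    fit = fit_parameters(st, masked, EMConfig(seed=0))
    assert np.abs(fit.cpds["B"].table - cpds["B"].table).max() < 0.03
    ll = fit.fit_info["loglik"]
    assert all(b - a > -1e-8 * (abs(a) + 1) for a, b in zip(ll, ll[1:]))


def test_zero_em_iterations_rejected():
    with pytest.raises(ValueError):
        EMConfig(max_iter=0)


def test_empty_data_rejected(chain_net):
    empty = TableData(
        chain_net.schema, pd.DataFrame({n: pd.Series([], dtype=object) for n in "ABC"})
    )
    with pytest.raises(ValidationError):
        fit_parameters(chain_net.structure, empty)


def test_unseen_parent_config_flagged_as_smoothed():
    specs = (binary_spec("A"), binary_spec("B"))
    data = TableData(specs, pd.DataFrame({"A": ["0"] * 50, "B": ["1"] * 50}))
    st = NetworkStructure(("A", "B"), frozenset({("A", "B")}))
    net = fit_parameters(st, data)
    assert net.cpds["B"].smoothed[1]  # A=1 never observed
    assert net.fit_info["smoothed_configs"]["B"] == 1


# ---------------------------------------------------------------------------
# structure learning


def _five_node_truth():
    edges = {("A", "B"), ("B", "C"), ("A", "D"), ("D", "E")}
    st = NetworkStructure(tuple("ABCDE"), frozenset(edges))
    cpds = {
        "A": CategoricalCPD("A", (), [[0.4, 0.6]]),
        "B": CategoricalCPD("B", ("A",), [[0.8, 0.2], [0.25, 0.75]]),
        "C": CategoricalCPD("C", ("B",), [[0.9, 0.1], [0.3, 0.7]]),
        "D": CategoricalCPD("D", ("A",), [[0.7, 0.3], [0.2, 0.8]]),
        "E": CategoricalCPD("E", ("D",), [[0.6, 0.4], [0.1, 0.9]]),
    }
    return BayesNetwork(st, cpds, tuple(binary_spec(n) for n in "ABCDE"))


def test_structure_recovery_on_known_dag():
    truth = _five_node_truth()
    data = logic_sample(truth, 50000, seed=3)
    learned = learn_structure(data, StructureConfig(resamples=10, seed=5))
    undirected = {frozenset(e) for e in learned.edges}
    for e in truth.structure.edges:
        assert frozenset(e) in undirected, f"true arc {e} missed"
        # confidence counts either orientation
        conf = learned.arc_confidence.get(e) or learned.arc_confidence.get((e[1], e[0]))
        assert conf >= 0.8
    false_arcs = undirected - {frozenset(e) for e in truth.structure.edges}
    for fa in false_arcs:
        e = tuple(fa)
        conf = learned.arc_confidence.get(e) or learned.arc_confidence.get((e[1], e[0]))
        assert conf <= 0.5, f"false arc {fa} at confidence {conf}"


def test_independent_columns_stay_unconnected():
    rng = np.random.default_rng(0)
    specs = (binary_spec("A"), binary_spec("B"))
    df = pd.DataFrame(
        {
            "A": rng.choice(["0", "1"], 10000),
            "B": rng.choice(["0", "1"], 10000),
        }
    )
    learned = learn_structure(TableData(specs, df), StructureConfig(resamples=10, seed=1))
    assert not learned.edges


def test_single_resample_confidences_are_binary():
    truth = _five_node_truth()
    data = logic_sample(truth, 5000, seed=9)
    learned = learn_structure(data, StructureConfig(resamples=1, seed=2))
    assert all(c in (0.0, 1.0) for c in learned.arc_confidence.values())


def test_structure_learning_row_order_invariant():
    truth = _five_node_truth()
    data = logic_sample(truth, 8000, seed=6)
    shuffled = TableData(
        data.variables, data.df.sample(frac=1.0, random_state=42).reset_index(drop=True)
    )
    cfg = StructureConfig(resamples=3, seed=4)
    a = learn_structure(data, cfg)
    b = learn_structure(shuffled, cfg)
    assert a.edges == b.edges
    assert a.arc_confidence == b.arc_confidence


# ---------------------------------------------------------------------------
# expert edits


def test_whitelist_edit_add_remove_idempotent(chain_net):
    st = chain_net.structure
    out = whitelist_edit(st, remove=[("A", "B")])
    assert ("A", "B") not in out.edges
    out2 = whitelist_edit(st, add=[("A", "C")])
    assert ("A", "C") in out2.edges and out2.arc_confidence[("A", "C")] == 1.0
    again = whitelist_edit(out2, add=[("A", "C")])
    assert again.edges == out2.edges


def test_whitelist_edit_cycle_named(chain_net):
    with pytest.raises(SchemaError, match="cycle"):
        whitelist_edit(chain_net.structure, add=[("C", "A")])
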