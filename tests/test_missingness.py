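"""Missing-data strategies: deletion, Miss Nodes/States, latent variables."""

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
    fit_parameters,
    joint_probability,
    logic_sample,
)
from synthcohort.fidelity_eval import kld_histogram
from synthcohort.missingness import (
    MISS_STATE,
    LatentSearchConfig,
    LatentSpec,
    attach_latents,
    augment_missing,
    delete_missing,
    discover_latents,
    required_miss_arcs,
    strip_missing_markers,
)
from synthcohort.world_fixture import make_world

from conftest import binary_spec, random_mixed_table


# ---------------------------------------------------------------------------
# deletion


def test_delete_missing_counts_rows():
    t = random_mixed_table(200, seed=1, missing_frac=0.15)
    complete = (~t.df.isna().any(axis=1)).sum()
    out = delete_missing(t)
    assert out.n_rows == complete


def test_delete_missing_identity_and_degenerate():
    clean = random_mixed_table(50, seed=2, missing_frac=0.0)
    assert delete_missing(clean).equals(clean)
    specs = (VariableSpec("x", "continuous"),)
    all_missing = TableData(specs, pd.DataFrame({"x": [np.nan] * 5}))
    assert delete_missing(all_missing).n_rows == 0


# ---------------------------------------------------------------------------
# augmentation round trip


def test_augment_counts_miss_states_and_nodes():
    specs = (
        VariableSpec("c", "categorical", ("a", "b")),
        VariableSpec("x", "continuous"),
    )
    df = pd.DataFrame(
        {"c": ["a", np.nan, "b", np.nan, np.nan], "x": [1.0, 2.0, 3.0, 4.0, 5.0]}
    )
    schema2, aug = augment_missing(specs, TableData(specs, df))
    assert (aug.df["c"] == MISS_STATE).sum() == 3
    assert (aug.df["x__miss"] == "observed").all()  # no continuous sentinel
    assert MISS_STATE in aug.spec("c").states


@pytest.mark.parametrize("seed", [0, 3, 8])
def test_strip_of_augment_is_identity(seed):
    t = random_mixed_table(120, seed=seed, missing_frac=0.2)
    _, aug = augment_missing(t.variables, t)
    back = strip_missing_markers(aug)
    assert back.equals(t)


def test_strip_resolves_conflicts_toward_miss_node():
    specs = (VariableSpec("x", "continuous"),)
    t = TableData(specs, pd.DataFrame({"x": [1.0, np.nan]}))
    _, aug = augment_missing(specs, t)
    df = aug.df.copy()
    df.loc[1, "x"] = 99.0  # value present although miss node says missing
    with pytest.warns(UserWarning, match="1 continuous"):
        back = strip_missing_markers(TableData(aug.variables, df), warn_conflicts=True)
    assert np.isnan(back.df["x"][1])


def test_augment_name_collision_rejected():
    specs = (
        VariableSpec("x", "continuous"),
        VariableSpec("x__miss", "categorical", ("observed", "missing")),
    )
    df = pd.DataFrame({"x": [1.0], "x__miss": ["observed"]})
    with pytest.raises(Exception, match="collides"):
        augment_missing(specs, TableData(specs, df))


def test_required_miss_arcs_pair_each_continuous():
    t = random_mixed_table(10, seed=0)
    schema2, _ = augment_missing(t.variables, t)
    arcs = required_miss_arcs(schema2)
    assert ("height__miss", "height") in arcs and ("score__miss", "score") in arcs


def test_sampled_missing_rate_matches_fitted_p_miss():
    # a single continuous variable with its miss node: the emitted sentinel
    # fraction must match the fitted P(miss) within a binomial interval
    specs = (VariableSpec("x", "continuous"),)
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 5000)
    x[rng.random(5000) < 0.3] = np.nan
    t = TableData(specs, pd.DataFrame({"x": x}))
    schema2, aug = augment_missing(specs, t)
    st = NetworkStructure(("x", "x__miss"), frozenset({("x__miss", "x")}))
    net = fit_parameters(st, aug, EMConfig(seed=0))
    p_miss = net.cpds["x__miss"].table[0, 1]
    samp = strip_missing_markers(logic_sample(net, 20000, seed=1))
    frac = samp.df["x"].isna().mean()
    assert abs(frac - p_miss) < 3 * np.sqrt(p_miss * (1 - p_miss) / 20000)


# ---------------------------------------------------------------------------
# latent discovery


def _confounded_table(n=20000, seed=2):
    st = NetworkStructure(("H", "X", "Y", "Z"), frozenset({("H", "X"), ("H", "Y")}))
    cpds = {
        "H": CategoricalCPD("H", (), [[0.5, 0.5]]),
        "X": CategoricalCPD("X", ("H",), [[0.9, 0.1], [0.15, 0.85]]),
        "Y": CategoricalCPD("Y", ("H",), [[0.85, 0.15], [0.1, 0.9]]),
        "Z": CategoricalCPD("Z", (), [[0.6, 0.4]]),
    }
    net = BayesNetwork(st, cpds, tuple(binary_spec(n) for n in "HXYZ"))
    full = logic_sample(net, n, seed=seed, include_latent=True)
    return net, full.subset(["X", "Y", "Z"])


def test_planted_confounder_recovered():
    _, obs = _confounded_table()
    found = discover_latents(obs, LatentSearchConfig(resamples=10, seed=1))
    assert len(found) == 1
    assert found[0].children >= {"X", "Y"}
    assert found[0].support >= 0.8


def test_independent_columns_yield_no_latents():
    rng = np.random.default_rng(3)
    specs = tuple(binary_spec(n) for n in "ABC")
    df = pd.DataFrame({n: rng.choice(["0", "1"], 10000) for n in "ABC"})
    found = discover_latents(TableData(specs, df), LatentSearchConfig(resamples=10, seed=0))
    assert found == []


def test_impossible_support_threshold_empties_result():
    _, obs = _confounded_table(n=4000)
    found = discover_latents(
        obs, LatentSearchConfig(resamples=5, support_threshold=1.01, seed=0)
    )
    assert found == []


def test_too_few_variables_rejected():
    specs = (binary_spec("A"), binary_spec("B"))
    t = TableData(specs, pd.DataFrame({"A": ["0", "1"], "B": ["1", "0"]}))
    with pytest.raises(ValidationError):
        discover_latents(t)


# ---------------------------------------------------------------------------
# attaching latents


def test_attach_latents_adds_roots():
    st = NetworkStructure(("a", "b"), frozenset())
    out = attach_latents(st, [LatentSpec("L1", 2, frozenset({"a", "b"}))])
    assert set(out.nodes) == {"a", "b", "L1"}
    assert out.edges == {("L1", "a"), ("L1", "b")}
    assert attach_latents(st, []) == st


def test_attach_duplicate_or_unknown_rejected():
    st = NetworkStructure(("a", "L1"), frozenset())
    with pytest.raises(Exception, match="duplicate"):
        attach_latents(st, [LatentSpec("L1", 2, frozenset({"a"}))])
    with pytest.raises(Exception, match="undeclared"):
        attach_latents(
            NetworkStructure(("a",), frozenset()), [LatentSpec("L2", 2, frozenset({"zz"}))]
        )


def test_latent_fit_beats_independent_fit_on_confounded_data():
    """KLD of the fitted observable joint to the truth: with latent < without."""
    truth_net, obs = _confounded_table(n=20000, seed=6)
    xy = obs.subset(["X", "Y"])

    def joint_of(net, hidden):
        out = {}
        for x, y in itertools.product("01", "01"):
            p = 0.0
            for extra in itertools.product(*[net.spec(h).states for h in hidden]):
                rec = {"X": x, "Y": y} | dict(zip(hidden, extra))
                p += joint_probability(net, rec)
            out[(x, y)] = p
        return out

    true_joint = joint_of(truth_net, ["H", "Z"])
    # without latent: X and Y independent roots
    st0 = NetworkStructure(("X", "Y"), frozenset())
    net0 = fit_parameters(st0, xy, EMConfig(seed=0))
    # with latent
    st1 = attach_latents(st0, [LatentSpec("L1", 2, frozenset({"X", "Y"}))])
    net1 = fit_parameters(st1, xy, EMConfig(seed=1, max_iter=200, tol=1e-6), latents={"L1": 2})

    def kld_to_truth(net, hidden):
        j = joint_of(net, hidden)
        return sum(
            true_joint[k] * np.log(true_joint[k] / max(j[k], 1e-12)) for k in true_joint
        )

    assert kld_to_truth(net1, ["L1"]) < kld_to_truth(net0, [])


def test_latent_nodes_never_emitted_in_samples():
    st = attach_latents(
        NetworkStructure(("X",), frozenset()), [LatentSpec("L1", 2, frozenset({"X"}))]
    )
    specs = (binary_spec("X"),)
    data = TableData(specs, pd.DataFrame({"X": ["0", "1"] * 50}))
    net = fit_parameters(st, data, EMConfig(seed=0, max_iter=5), latents={"L1": 2})
    samp = logic_sample(net, 100, seed=0)
    assert samp.names == ("X",)


# ---------------------------------------------------------------------------
# MNAR contrast on the fixture world


def test_latent_model_beats_deletion_on_mnar_variable():
    """The hidden health-seeking factor both shifts choleratio and drives its
    missingness; a latent over (value, miss-node) must reconstruct the complete
    marginal better than complete-case analysis does."""
    w = make_world(30000, seed=7)
    truth = w.population.df["choleratio"].to_numpy(float)
    obs = w.observed.subset(["choleratio"])

    deleted = delete_missing(obs)
    st_d = NetworkStructure(("choleratio",), frozenset())
    net_d = fit_parameters(st_d, deleted, EMConfig(seed=0))
    syn_d = logic_sample(net_d, 30000, seed=101)
    kld_deletion = kld_histogram(truth, syn_d.df["choleratio"].to_numpy(float))

    _, aug = augment_missing(obs.variables, obs)
    st_l = NetworkStructure(
        ("L1", "choleratio", "choleratio__miss"),
        frozenset({("L1", "choleratio"), ("L1", "choleratio__miss")}),
    )
    net_l = fit_parameters(
        st_l, aug, EMConfig(seed=0, max_iter=120, tol=1e-6, restarts=3), latents={"L1": 2}
    )
    inferred = logic_sample(net_l, 30000, seed=101)  # values before stripping
    kld_latent = kld_histogram(truth, inferred.df["choleratio"].to_numpy(float))
    assert kld_latent < kld_deletion
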