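"""Classifier equivalence: training, curves, AUCs, Granger predictivity."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synthcohort import TableData, ValidationError, VariableSpec
from synthcohort.classifier_eval import (
    CLASSIFIER_KINDS,
    CurveSet,
    granger_predictivity,
    roc_pr_curves,
    sensitivity_comparison,
    train_classifier,
)


def _toy_table(n, seed, signal=3.0):
    """Binary outcome driven by two continuous predictors."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(0, 1, n)
    x2 = rng.normal(0, 1, n)
    logit = signal * x1 - signal * x2
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    specs = (
        VariableSpec("x1", "continuous"),
        VariableSpec("x2", "continuous"),
        VariableSpec("y", "categorical", ("0", "1"), role="dependent"),
    )
    return TableData(
        specs, pd.DataFrame({"x1": x1, "x2": x2, "y": y.astype(str)})
    )


def _separable_table(n=200, seed=0):
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.normal(-3, 0.3, n // 2), rng.normal(3, 0.3, n // 2)])
    y = ["0"] * (n // 2) + ["1"] * (n // 2)
    specs = (
        VariableSpec("x", "continuous"),
        VariableSpec("y", "categorical", ("0", "1"), role="dependent"),
    )
    return TableData(specs, pd.DataFrame({"x": x, "y": y}))


# ---------------------------------------------------------------------------
# training


@pytest.mark.parametrize("kind", CLASSIFIER_KINDS)
def test_separable_data_trains_to_perfect_roc(kind):
    t = _separable_table()
    model = train_classifier(t, "y", kind, seed=0)
    roc, pr = roc_pr_curves(model, t, grid_size=401)  # grid finer than the data
    assert roc.auc == pytest.approx(1.0, abs=1e-6)
    assert pr.auc == pytest.approx(1.0, abs=1e-6)


def test_null_model_auc_near_half():
    rng = np.random.default_rng(7)
    train = _toy_table(5000, seed=1, signal=0.0)
    test = _toy_table(5000, seed=2, signal=0.0)
    model = train_classifier(train, "y", "bayes_glm", seed=0)
    roc, _ = roc_pr_curves(model, test)
    assert abs(roc.auc - 0.5) < 0.05


def test_unknown_classifier_kind_rejected():
    with pytest.raises(ValidationError):
        train_classifier(_separable_table(), "y", "deep_net")


def test_single_class_target_rejected():
    specs = (
        VariableSpec("x", "continuous"),
        VariableSpec("y", "categorical", ("0", "1"), role="dependent"),
    )
    t = TableData(specs, pd.DataFrame({"x": [1.0, 2.0], "y": ["1", "1"]}))
    with pytest.raises(ValidationError):
        train_classifier(t, "y", "lda")


# ---------------------------------------------------------------------------
# curves


class _FixedScores:
    """Scoring stub: returns a stored score vector."""

    def __init__(self, scores, labels):
        self._scores = np.asarray(scores, float)
        self._labels = np.asarray(labels, int)
        self.kind = "stub"

    def score(self, data):
        return self._scores

    def labels(self, data):
        return self._labels


def _dummy_table(n):
    specs = (VariableSpec("x", "continuous"),)
    return TableData(specs, pd.DataFrame({"x": np.zeros(n)}))


def test_scores_equal_to_labels_give_unit_aucs():
    y = [0, 0, 1, 1, 0, 1]
    m = _FixedScores(y, y)
    roc, pr = roc_pr_curves(m, _dummy_table(6), target="x", grid_size=20)
    assert roc.auc == pytest.approx(1.0, abs=1e-9)
    assert pr.auc == pytest.approx(1.0, abs=1e-9)


def test_inverted_scores_give_zero_roc_auc():
    y = np.array([0, 0, 1, 1, 0, 1])
    m = _FixedScores(1 - y, y)
    roc, _ = roc_pr_curves(m, _dummy_table(6), target="x", grid_size=20)
    assert roc.auc == pytest.approx(0.0, abs=1e-9)


def test_confusion_counts_match_exhaustive_tabulation():
    scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.9, 0.05, 0.55, 0.7, 0.2])
    labels = np.array([0, 0, 1, 1, 0, 1, 0, 1, 1, 0])
    m = _FixedScores(scores, labels)
    roc, pr = roc_pr_curves(m, _dummy_table(10), target="x", grid_size=15)
    pos, neg = labels.sum(), (1 - labels).sum()
    for t, (fpr, tpr) in zip(roc.thresholds, roc.points):
        tp = ((scores >= t) & (labels == 1)).sum()
        fp = ((scores >= t) & (labels == 0)).sum()
        assert tpr == pytest.approx(tp / pos)
        assert fpr == pytest.approx(fp / neg)


def test_roc_auc_equals_mann_whitney_on_tie_free_data():
    rng = np.random.default_rng(3)
    scores = rng.permutation(np.linspace(0, 1, 40))  # tie-free
    labels = (rng.random(40) < 0.5).astype(int)
    labels[0], labels[1] = 0, 1  # both classes present
    m = _FixedScores(scores, labels)
    roc, _ = roc_pr_curves(m, _dummy_table(40), grid_size=201, target="x")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    mw = np.mean([s > t for s in pos for t in neg])
    assert roc.auc == pytest.approx(mw, abs=1e-9)


def test_row_order_does_not_change_curves():
    t = _toy_table(2000, seed=5)
    model = train_classifier(t, "y", "bayes_glm", seed=0)
    roc1, pr1 = roc_pr_curves(model, t)
    shuffled = TableData(t.variables, t.df.sample(frac=1.0, random_state=9))
    roc2, pr2 = roc_pr_curves(model, shuffled)
    assert roc1.auc == pytest.approx(roc2.auc, abs=1e-12)
    assert pr1.auc == pytest.approx(pr2.auc, abs=1e-12)


def test_one_class_test_set_rejected():
    t = _separable_table()
    model = train_classifier(t, "y", "lda")
    one_class = TableData(t.variables, t.df[t.df["y"] == "1"])
    with pytest.raises(ValidationError):
        roc_pr_curves(model, one_class)


# ---------------------------------------------------------------------------
# Granger predictivity


def _curve(y):
    y = np.asarray(y, float)
    pts = np.column_stack([np.linspace(0, 1, len(y)), y])
    return CurveSet("ROC", pts, np.linspace(0, 1, len(y)), 0.5)


def test_lagged_dependence_detected():
    rng = np.random.default_rng(0)
    syn = np.cumsum(rng.normal(0, 1, 101))
    gt = syn[:-1] + rng.normal(0, 0.01, 100)  # gt follows syn by one step
    p = granger_predictivity(_curve(syn[1:]), _curve(gt), lag=1)
    assert p < 0.001


def test_null_calibration_on_independent_ar1_pairs():
    """Independent stationary AR(1) sequences: rejection rate ~ alpha.

    (Independent *random walks* are the textbook spurious-regression case
    where any F-test over-rejects, so stationary series are the right
    null for calibration.)
    """
    rng = np.random.default_rng(42)
    rejections = 0
    trials = 500

    def ar1(n, phi=0.5):
        x = np.empty(n)
        x[0] = rng.normal()
        for t in range(1, n):
            x[t] = phi * x[t - 1] + rng.normal()
        return x

    for _ in range(trials):
        p = granger_predictivity(_curve(ar1(60)), _curve(ar1(60)), lag=1)
        rejections += p < 0.05
    rate = rejections / trials
    assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / trials) + 0.01


def test_granger_config_validation():
    with pytest.raises(ValidationError):
        granger_predictivity(_curve(np.arange(5)), _curve(np.arange(5)), lag=3)
    with pytest.raises(ValidationError):
        granger_predictivity(_curve(np.arange(50)), _curve(np.ones(50)), lag=1)
    with pytest.raises(ValidationError):
        granger_predictivity(_curve(np.arange(10)), _curve(np.arange(12)), lag=1)


def test_granger_agrees_with_statsmodels():
    from statsmodels.tsa.stattools import grangercausalitytests

    rng = np.random.default_rng(11)
    syn = np.cumsum(rng.normal(0, 1, 80))
    gt = 0.6 * np.roll(syn, 1) + rng.normal(0, 0.5, 80)
    p_ours = granger_predictivity(_curve(syn), _curve(gt), lag=1)
    data = np.column_stack([gt, syn])
    res = grangercausalitytests(data, maxlag=1, verbose=False)
    p_sm = res[1][0]["ssr_ftest"][1]
    assert p_ours == pytest.approx(p_sm, rel=1e-6, abs=1e-12)


# ---------------------------------------------------------------------------
# orchestration


def test_self_split_gives_matched_aucs():
    t = _toy_table(8000, seed=8)
    gt = TableData(t.variables, t.df.iloc[:4000])
    syn = TableData(t.variables, t.df.iloc[4000:])
    report = sensitivity_comparison(gt, syn, "y", samples=2, seed=0)
    for entry in report["samples"]:
        a = entry["syn_to_gt"]["test_roc_auc"]
        b = entry["gt_to_syn"]["test_roc_auc"]
        assert abs(a - b) < 0.02


def test_well_fitted_generator_yields_equivalent_sensitivity_analysis():
    """Sampling from the true fixture network (a perfectly fitted generator):
    paired AUCs agree closely and the synthetic curves predict the real ones
    for most draws.  (When the two curves are *nearly identical*, the
    synthetic lags become collinear with the real curve's own lags and the
    Granger F-test loses power, so unanimity is not expected.)"""
    from synthcohort.bn_core import logic_sample
    from synthcohort.world_fixture import make_world

    w = make_world(30000, seed=3)
    syn = logic_sample(w.network, 30000, seed=77)
    rep = sensitivity_comparison(
        w.population, syn, "strokeha",
        classifier_kinds=("bayes_glm",), samples=5, sample_size=10000, seed=4,
    )
    granger_ps = []
    for e in rep["samples"]:
        assert abs(e["syn_to_gt"]["test_roc_auc"] - e["gt_to_syn"]["test_roc_auc"]) < 0.05
        granger_ps += [e["granger_p_roc"], e["granger_p_pr"]]
    assert sum(p < 0.05 for p in granger_ps) >= 7, granger_ps


def test_mismatched_target_rejected():
    t = _toy_table(100, seed=0)
    other = t.subset(["x1", "x2"])
    with pytest.raises(ValidationError):
        sensitivity_comparison(t, other, "y")
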