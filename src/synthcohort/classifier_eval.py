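"""Classifier-equivalence evaluation.

Whether a synthetic cohort supports the same machine-learning analysis
as the real one is tested by training classifiers for the dependent
(binary) variable and comparing their sensitivity analyses: ROC and
precision–recall curves on a shared threshold grid, their AUCs, and a
Granger-style predictivity test of whether the synthetic-data curve, as
a sequence over the grid, statistically predicts the ground-truth curve.

Three classifier families are provided: forward–backward stepwise
logistic regression on AIC, linear discriminant analysis, and a
"Bayesian GLM" — logistic regression with a weakly informative Gaussian
prior on the coefficients (L2-regularised fit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression

from .fidelity_eval import encode_numeric
from .schema_io import CATEGORICAL, TableData, ValidationError

__all__ = [
    "CLASSIFIER_KINDS",
    "CurveSet",
    "ScoringModel",
    "train_classifier",
    "roc_pr_curves",
    "granger_predictivity",
    "sensitivity_comparison",
]

CLASSIFIER_KINDS = ("stepwise_logistic", "lda", "bayes_glm")


@dataclass
class CurveSet:
    """An ROC or PR curve evaluated on a fixed threshold grid."""

    kind: str  # "ROC" or "PR"
    points: np.ndarray  # (grid, 2): ROC -> (FPR, TPR); PR -> (recall, precision)
    thresholds: np.ndarray
    auc: float
    source: str = ""  # "GT" or "SYN"
    classifier: str = ""

    def __post_init__(self):
        if self.kind not in ("ROC", "PR"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if len(self.points) < 2:
            raise ValueError("curve needs a grid of length >= 2")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC outside [0, 1]")

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def to_frame(self) -> pd.DataFrame:
        x = "fpr" if self.kind == "ROC" else "recall"
        y = "tpr" if self.kind == "ROC" else "precision"
        return pd.DataFrame(
            {"threshold": self.thresholds, x: self.points[:, 0], y: self.points[:, 1]}
        )


@dataclass
class ScoringModel:
    """A fitted binary classifier producing a real-valued risk score per row."""

    kind: str
    target: str
    positive_state: str
    predictors: tuple[str, ...]
    moments: Mapping[str, tuple[float, float]]
    selected: np.ndarray  # encoded-column mask (stepwise selection)
    model: object

    def score(self, data: TableData) -> np.ndarray:
        X, _ = encode_numeric(data, self.predictors, center=self.moments)
        X = X[:, self.selected]
        if hasattr(self.model, "predict_proba"):
            return self.model.predict_proba(X)[:, 1]
        return X @ self.model["coef"] + self.model["intercept"]

    def labels(self, data: TableData) -> np.ndarray:
        col = data.df[self.target].astype(object)
        if col.isna().any():
            raise ValidationError(f"target {self.target!r} contains missing values")
        return (col == self.positive_state).to_numpy(dtype=int)


def _target_labels(data: TableData, target: str) -> tuple[np.ndarray, str]:
    spec = data.spec(target)
    if spec.kind != CATEGORICAL or spec.n_states != 2:
        raise ValidationError(f"target {target!r} must be binary categorical")
    col = data.df[target].astype(object)
    if col.isna().any():
        raise ValidationError(f"target {target!r} contains missing values; drop or encode them first")
    positive = spec.states[1]
    y = (col == positive).to_numpy(dtype=int)
    if y.min() == y.max():
        raise ValidationError(f"training target {target!r} has a single class")
    return y, positive


def _stepwise_logistic(X: np.ndarray, y: np.ndarray, seed: int) -> tuple[np.ndarray, LogisticRegression]:
    """Forward–backward column selection on AIC, then an unpenalised refit."""

    def aic(cols: tuple[int, ...]) -> float:
        if not cols:
            p1 = y.mean()
            ll = y.sum() * np.log(max(p1, 1e-12)) + (len(y) - y.sum()) * np.log(max(1 - p1, 1e-12))
            return -2 * ll + 2
        m = LogisticRegression(penalty=None, max_iter=200, random_state=seed)
        m.fit(X[:, list(cols)], y)
        p = np.clip(m.predict_proba(X[:, list(cols)])[:, 1], 1e-12, 1 - 1e-12)
        ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        return -2 * ll + 2 * (len(cols) + 1)

    cache: dict[tuple[int, ...], float] = {}

    def score(cols):
        key = tuple(sorted(cols))
        if key not in cache:
            cache[key] = aic(key)
        return cache[key]

    current: tuple[int, ...] = ()
    best = score(current)
    improved = True
    while improved:
        improved = False
        candidates = []
        for j in range(X.shape[1]):
            if j in current:
                candidates.append(tuple(c for c in current if c != j))
            else:
                candidates.append(current + (j,))
        for cand in candidates:
            s = score(cand)
            if s < best - 1e-9:
                best, current, improved = s, tuple(sorted(cand)), True
    if not current:  # degenerate: keep the single best column
        current = (int(np.argmin([score((j,)) for j in range(X.shape[1])])),)
    mask = np.zeros(X.shape[1], dtype=bool)
    mask[list(current)] = True
    final = LogisticRegression(penalty=None, max_iter=500, random_state=seed)
    final.fit(X[:, mask], y)
    return mask, final


def train_classifier(
    train: TableData,
    target: str,
    kind: str = "bayes_glm",
    seed: int = 0,
) -> ScoringModel:
    """Fit a scoring model of *kind* for the binary *target*.

    Predictors are all other variables, numerically encoded (one-hot
    categoricals, z-scored continuous with missing indicators).  The
    returned model is deterministic given the seed.
    """
    if kind not in CLASSIFIER_KINDS:
        raise ValidationError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")
    y, positive = _target_labels(train, target)
    predictors = tuple(n for n in train.names if n != target)
    X, moments = encode_numeric(train, predictors)
    keep = X.std(axis=0) > 0  # drop constant encoded columns
    Xk = X[:, keep]
    if kind == "stepwise_logistic":
        sub_mask, model = _stepwise_logistic(Xk, y, seed)
    elif kind == "lda":
        model = LinearDiscriminantAnalysis()
        model.fit(Xk, y)
        sub_mask = np.ones(Xk.shape[1], dtype=bool)
    else:  # bayes_glm: Gaussian prior == L2 penalty
        model = LogisticRegression(C=1.0, max_iter=500, random_state=seed)
        model.fit(Xk, y)
        sub_mask = np.ones(Xk.shape[1], dtype=bool)
    selected = np.zeros(X.shape[1], dtype=bool)
    selected[np.flatnonzero(keep)[sub_mask]] = True
    return ScoringModel(kind, target, positive, predictors, moments, selected, model)


# ---------------------------------------------------------------------------
# curves


def roc_pr_curves(
    model: ScoringModel,
    test: TableData,
    target: str | None = None,
    grid_size: int = 100,
) -> tuple[CurveSet, CurveSet]:
    """ROC and PR curves on a shared score-quantile threshold grid.

    ROC AUC by the trapezoid rule over (FPR, TPR); PR AUC by step-wise
    interpolation over (recall, precision).  A one-class test set is an
    error.
    """
    target = target or model.target
    scores = np.asarray(model.score(test), dtype=float)
    y = model.labels(test)
    if y.min() == y.max():
        raise ValidationError("test set contains a single class")
    thresholds = np.quantile(scores, np.linspace(0.0, 1.0, grid_size))
    pos = y.sum()
    neg = len(y) - pos
    tp = np.array([(y[scores >= t] == 1).sum() for t in thresholds], dtype=float)
    fp = np.array([(y[scores >= t] == 0).sum() for t in thresholds], dtype=float)
    tpr = tp / pos
    fpr = fp / neg
    recall = tpr
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 1.0)

    # trapezoid over the curve augmented with its (0,0) / (1,1) endpoints;
    # ties in FPR are ordered by TPR, recovering the threshold path
    fx = np.concatenate([[0.0], fpr, [1.0]])
    fy = np.concatenate([[0.0], tpr, [1.0]])
    order = np.lexsort((fy, fx))
    roc_auc = float(np.trapezoid(fy[order], fx[order]))
    roc_auc = min(max(roc_auc, 0.0), 1.0)

    # step-wise PR area: walk thresholds high -> low (recall non-decreasing)
    # so each recall increment is credited with the precision at the
    # threshold that first achieves it
    pr_auc = 0.0
    prev_r = 0.0
    for j in range(len(thresholds) - 1, -1, -1):
        if recall[j] > prev_r:
            pr_auc += (recall[j] - prev_r) * precision[j]
            prev_r = recall[j]
    pr_auc = min(max(float(pr_auc), 0.0), 1.0)

    roc = CurveSet("ROC", np.column_stack([fpr, tpr]), thresholds, roc_auc, classifier=model.kind)
    pr = CurveSet("PR", np.column_stack([recall, precision]), thresholds, pr_auc, classifier=model.kind)
    return roc, pr


# ---------------------------------------------------------------------------
# Granger predictivity


def granger_predictivity(syn_curve: CurveSet, gt_curve: CurveSet, lag: int = 1) -> float:
    """F-test p-value: does the synthetic curve predict the ground-truth curve?

    The restricted model regresses the ground-truth y-sequence on its own
    *lag* lags; the augmented model adds the synthetic curve's lags.  A
    small p means the synthetic curve "Granger-causes" (predicts) the
    ground-truth one along the threshold grid.
    """
    gt = np.asarray(gt_curve.y, dtype=float)
    syn = np.asarray(syn_curve.y, dtype=float)
    if len(gt) != len(syn):
        raise ValidationError("curves must share the same grid")
    T = len(gt)
    if lag < 1 or T < lag + 3:
        raise ValidationError(f"grid of {T} points cannot support lag {lag}")
    if np.allclose(gt, gt[0]):
        raise ValidationError("constant ground-truth sequence: zero residual variance")
    y = gt[lag:]
    n = len(y)
    ones = np.ones((n, 1))
    gt_lags = np.column_stack([gt[lag - j - 1 : T - j - 1] for j in range(lag)])
    syn_lags = np.column_stack([syn[lag - j - 1 : T - j - 1] for j in range(lag)])
    Xr = np.hstack([ones, gt_lags])
    Xu = np.hstack([ones, gt_lags, syn_lags])

    def rss(Xm):
        beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        resid = y - Xm @ beta
        return float(resid @ resid)

    rss_r, rss_u = rss(Xr), rss(Xu)
    df_num = lag
    df_den = n - Xu.shape[1]
    if df_den <= 0:
        raise ValidationError("not enough grid points for the augmented regression")
    if rss_u <= 1e-300:
        return 0.0
    f = ((rss_r - rss_u) / df_num) / (rss_u / df_den)
    return float(stats.f.sf(max(f, 0.0), df_num, df_den))


# ---------------------------------------------------------------------------
# orchestration


def sensitivity_comparison(
    gt: TableData,
    syn: TableData,
    target: str,
    classifier_kinds: Sequence[str] = ("bayes_glm",),
    samples: int = 5,
    sample_size: int | None = None,
    grid_size: int = 100,
    lag: int = 1,
    seed: int = 0,
) -> dict:
    """Paired sensitivity analyses on synthetic vs ground-truth cohorts.

    For each classifier kind and each of *samples* draws: train on a
    synthetic subsample and evaluate on a held-out ground-truth
    subsample (the utility orientation), and vice versa (secondary).
    Rows with a missing target are dropped from each side first.  Emits
    paired ROC/PR curves, their AUCs, and Granger p-values per curve
    pair (SYN curve predicting the GT curve).
    """
    for table, label in ((gt, "gt"), (syn, "syn")):
        if target not in table.names:
            raise ValidationError(f"target {target!r} absent from the {label} table")
    gt_c = TableData(gt.variables, gt.df[~gt.df[target].isna()])
    syn_c = TableData(syn.variables, syn.df[~syn.df[target].isna()])
    rng = np.random.default_rng(seed)
    size = sample_size or min(gt_c.n_rows // 2, syn_c.n_rows // 2)
    report: dict = {"target": target, "samples": [], "orientation": "train SYN, test GT (primary)"}
    for kind in classifier_kinds:
        for draw in range(samples):
            entry = {"classifier": kind, "draw": draw}
            for train_t, test_t, direction in (
                (syn_c, gt_c, "syn_to_gt"),
                (gt_c, syn_c, "gt_to_syn"),
            ):
                tr_idx = rng.choice(train_t.n_rows, size=min(size, train_t.n_rows), replace=False)
                te_idx = rng.choice(test_t.n_rows, size=min(size, test_t.n_rows), replace=False)
                train = TableData(train_t.variables, train_t.df.iloc[tr_idx])
                test = TableData(test_t.variables, test_t.df.iloc[te_idx])
                model = train_classifier(train, target, kind, seed=seed + draw)
                roc, pr = roc_pr_curves(model, test, grid_size=grid_size)
                in_roc, in_pr = roc_pr_curves(model, train, grid_size=grid_size)
                entry[direction] = {
                    "test_roc_auc": roc.auc,
                    "test_pr_auc": pr.auc,
                    "train_roc_auc": in_roc.auc,
                    "train_pr_auc": in_pr.auc,
                }
                if direction == "syn_to_gt":
                    entry["roc_curves"] = {"syn": in_roc, "gt": roc}
                    entry["pr_curves"] = {"syn": in_pr, "gt": pr}
            entry["granger_p_roc"] = granger_predictivity(
                entry["roc_curves"]["syn"], entry["roc_curves"]["gt"], lag=lag
            )
            entry["granger_p_pr"] = granger_predictivity(
                entry["pr_curves"]["syn"], entry["pr_curves"]["gt"], lag=lag
            )
            report["samples"].append(entry)
    return report
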