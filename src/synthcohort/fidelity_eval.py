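"""Distributional fidelity of synthetic cohorts against ground truth.

Univariate checks: Pearson chi-squared for categorical variables
(synthetic frequencies as the expected distribution, ground-truth counts
as observed), two-sample Kolmogorov–Smirnov for continuous ones, and a
histogram Kullback–Leibler divergence.

The diff_KL protocol quantifies whether a generator is any further from
the ground truth than ground-truth resamples are from each other: with a
base sample ``GT_i`` of size ``i`` and resamples ``GT_i^n`` drawn without
replacement from the population,

    diff_KL = mean_{m,n} D_KL^2(GT_i^m || SY_i^n) - mean_n D_KL^2(GT_i || GT_i^n)

per variable and iteration; values near zero mean the synthetic sets are
statistically interchangeable with resampling noise.

Joint structure is tested with a kernel maximum mean discrepancy (RBF
kernel, permutation null): for every k-variable subset, equally sized
subsamples of both cohorts are compared and the percentage of subsets
where H0 ("same distribution") is not rejected is reported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .schema_io import CATEGORICAL, CONTINUOUS, TableData, ValidationError, VariableSpec

__all__ = [
    "KernelConfig",
    "FidelityReport",
    "chi_squared_compare",
    "ks_compare",
    "kld_histogram",
    "diff_kl",
    "diff_kl_protocol",
    "mmd_rbf",
    "joint_acceptance_sweep",
    "count_combinations",
    "encode_numeric",
]


# ---------------------------------------------------------------------------
# reports


@dataclass
class FidelityReport:
    """Collected per-variable and joint comparison results."""

    chi_squared: dict[str, float] = field(default_factory=dict)  # variable -> p
    ks: dict[str, dict[int, tuple[float, float]]] = field(default_factory=dict)  # var -> n -> (D, p)
    diff_kl: pd.DataFrame | None = None  # per-iteration table incl. mean/SD rows
    kmmd_acceptance: dict[int, float] = field(default_factory=dict)  # k -> % accepted

    def validate(self) -> None:
        for p in self.chi_squared.values():
            if not (0.0 <= p <= 1.0):
                raise ValueError("chi-squared p outside [0, 1]")
        for per_n in self.ks.values():
            for d, p in per_n.values():
                if not (0.0 <= d <= 1.0 and 0.0 <= p <= 1.0):
                    raise ValueError("KS result outside [0, 1]")
        for rate in self.kmmd_acceptance.values():
            if not (0.0 <= rate <= 100.0):
                raise ValueError("acceptance rate outside [0, 100]")

    def to_dict(self) -> dict:
        out = {
            "chi_squared_p": self.chi_squared,
            "ks": {v: {str(n): list(dp) for n, dp in per.items()} for v, per in self.ks.items()},
            "kmmd_acceptance_pct": {str(k): v for k, v in self.kmmd_acceptance.items()},
        }
        if self.diff_kl is not None:
            out["diff_kl"] = self.diff_kl.to_dict(orient="index")
        return out


@dataclass(frozen=True)
class KernelConfig:
    """RBF-kernel two-sample test configuration.

    ``bandwidth`` is the Gaussian kernel scale sigma (the kernel is
    ``exp(-||x-y||^2 / (2 sigma^2))``); the default ``"median"`` uses the
    median heuristic on pooled pairwise distances.  The H0 decision
    compares the biased MMD^2 estimate to the (1 - alpha) quantile of a
    permutation null.
    """

    bandwidth: float | str = "median"
    permutations: int = 200
    alpha: float = 0.05

    def __post_init__(self):
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "median":
                raise ValueError(f"unknown bandwidth rule {self.bandwidth!r}")
        elif self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# univariate tests


def chi_squared_compare(gt_counts: Mapping[str, float], syn_counts: Mapping[str, float]) -> float:
    """Pearson chi-squared p-value of ground-truth counts against synthetic frequencies.

    The synthetic relative frequencies, scaled to the ground-truth total,
    are the expected distribution; the ground-truth counts are observed.
    States with zero mass on both sides are dropped.  Returns p = 1.0 for
    a single shared state (degenerate, statistic 0).
    """
    states = set(gt_counts) | set(syn_counts)
    if not (set(gt_counts) & set(syn_counts)):
        raise ValidationError("disjoint state sets in chi-squared comparison")
    obs = np.array([float(gt_counts.get(s, 0.0)) for s in sorted(states)])
    syn = np.array([float(syn_counts.get(s, 0.0)) for s in sorted(states)])
    if obs.sum() <= 0 or syn.sum() <= 0:
        raise ValidationError("chi-squared comparison needs positive totals")
    keep = (obs > 0) | (syn > 0)
    obs, syn = obs[keep], syn[keep]
    expected = syn / syn.sum() * obs.sum()
    if len(obs) < 2:
        return 1.0
    if (expected == 0).any():  # observed mass where synthetic has none
        return 0.0
    statistic = float(((obs - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(statistic, df=len(obs) - 1))


def ks_compare(
    gt_values: np.ndarray,
    syn_values: np.ndarray,
    n: int | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sample KS statistic D and asymptotic p.

    With *n* given, both sides are first subsampled (without replacement)
    to *n* values with the given seed — the protocol used to report the
    test at several sample sizes, since at large n the test rejects on
    negligible differences.
    """
    gt = np.asarray(gt_values, dtype=float)
    syn = np.asarray(syn_values, dtype=float)
    gt, syn = gt[~np.isnan(gt)], syn[~np.isnan(syn)]
    if gt.size == 0 or syn.size == 0:
        raise ValidationError("KS comparison needs non-empty samples")
    if n is not None:
        rng = np.random.default_rng(seed)
        if n > gt.size or n > syn.size:
            raise ValidationError("subsample size exceeds available values")
        gt = rng.choice(gt, size=n, replace=False)
        syn = rng.choice(syn, size=n, replace=False)
    res = stats.ks_2samp(gt, syn, method="asymp")
    return float(res.statistic), float(res.pvalue)


def kld_histogram(
    p_sample: np.ndarray,
    q_sample: np.ndarray,
    bins: int = 20,
    epsilon: float = 1e-9,
) -> float:
    """D_KL(P || Q) over a shared equal-width binning of the pooled range.

    *epsilon* is added to every bin mass before normalisation so the
    divergence is finite.  A zero-width pooled range puts all mass in one
    bin and returns 0.
    """
    p = np.asarray(p_sample, dtype=float)
    q = np.asarray(q_sample, dtype=float)
    p, q = p[~np.isnan(p)], q[~np.isnan(q)]
    if p.size == 0 or q.size == 0:
        raise ValidationError("KLD needs non-empty samples")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    lo = min(p.min(), q.min())
    hi = max(p.max(), q.max())
    if hi <= lo:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    ph, _ = np.histogram(p, bins=edges)
    qh, _ = np.histogram(q, bins=edges)
    pm = ph.astype(float) + epsilon
    qm = qh.astype(float) + epsilon
    pm /= pm.sum()
    qm /= qm.sum()
    return float(np.sum(pm * np.log(pm / qm)))


def _kld_categorical(p_col: pd.Series, q_col: pd.Series, states, epsilon=1e-9) -> float:
    pc = np.array([(p_col == s).sum() for s in states], float) + epsilon
    qc = np.array([(q_col == s).sum() for s in states], float) + epsilon
    pc /= pc.sum()
    qc /= qc.sum()
    return float(np.sum(pc * np.log(pc / qc)))


# ---------------------------------------------------------------------------
# diff_KL protocol


def diff_kl(gt_terms: Sequence[float], sy_terms: Sequence[float]) -> pd.DataFrame:
    """Per-iteration diff_KL bookkeeping plus the mean/SD summary row.

    ``gt_terms[i]`` is the mean squared KLD among ground-truth resamples
    at iteration i, ``sy_terms[i]`` the mean squared KLD of synthetic
    sets scored against ground-truth resamples; the difference is
    ``sy - gt`` per iteration, summarised by mean and sample SD.
    """
    gt = np.asarray(gt_terms, dtype=float)
    sy = np.asarray(sy_terms, dtype=float)
    if gt.shape != sy.shape or gt.ndim != 1:
        raise ValueError("gt_terms and sy_terms must be equal-length vectors")
    d = sy - gt
    rows = {i + 1: {"gt": gt[i], "sy": sy[i], "diff_kl": d[i]} for i in range(len(d))}
    rows["mean"] = {"gt": gt.mean(), "sy": sy.mean(), "diff_kl": d.mean()}
    rows["sd"] = {
        "gt": gt.std(ddof=1) if len(d) > 1 else 0.0,
        "sy": sy.std(ddof=1) if len(d) > 1 else 0.0,
        "diff_kl": d.std(ddof=1) if len(d) > 1 else 0.0,
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def diff_kl_protocol(
    population: TableData,
    generator: Callable[[int, int], TableData],
    i: int,
    n_iterations: int = 10,
    n_resamples: int = 10,
    bins: int = 20,
    epsilon: float = 1e-9,
    seed: int = 0,
    squared: bool = True,
) -> dict[str, pd.DataFrame]:
    """Run the resampling-vs-generation KLD comparison per variable.

    Per iteration: draw a base sample ``GT_i`` plus ``n_resamples``
    disjoint resamples of size *i* without replacement from *population*;
    call ``generator(size, seed)`` for ``n_resamples`` synthetic sets of
    the same size; record the mean squared KLD among resamples
    (``GT_i`` vs each ``GT_i^n``) and across all (resample, synthetic)
    pairs, and their difference.  Returns one diff-KL table per variable
    (see :func:`diff_kl`).
    """
    need = i * (n_resamples + 1)
    if population.n_rows < need:
        raise ValidationError(
            f"population of {population.n_rows} rows cannot supply {n_resamples + 1} "
            f"disjoint samples of {i}"
        )
    rng = np.random.default_rng(seed)
    power = 2 if squared else 1
    gt_terms: dict[str, list[float]] = {v.name: [] for v in population.variables}
    sy_terms: dict[str, list[float]] = {v.name: [] for v in population.variables}

    def _kld_var(v: VariableSpec, a: TableData, b: TableData) -> float:
        if v.kind == CONTINUOUS:
            return kld_histogram(
                a.df[v.name].to_numpy(float), b.df[v.name].to_numpy(float), bins, epsilon
            )
        return _kld_categorical(a.df[v.name], b.df[v.name], v.states, epsilon)

    for it in range(n_iterations):
        perm = rng.permutation(population.n_rows)
        chunks = [perm[j * i : (j + 1) * i] for j in range(n_resamples + 1)]
        base = TableData(population.variables, population.df.iloc[chunks[0]])
        resamples = [
            TableData(population.variables, population.df.iloc[c]) for c in chunks[1:]
        ]
        syn_seed = int(rng.integers(0, 2**31 - 1))
        syn = [generator(i, syn_seed + j) for j in range(n_resamples)]
        for v in population.variables:
            gt_d = [_kld_var(v, base, r) ** power for r in resamples]
            sy_d = [_kld_var(v, r, s) ** power for r in resamples for s in syn]
            gt_terms[v.name].append(float(np.mean(gt_d)))
            sy_terms[v.name].append(float(np.mean(sy_d)))
    return {name: diff_kl(gt_terms[name], sy_terms[name]) for name in gt_terms}


# ---------------------------------------------------------------------------
# kernel MMD


def _rbf_kernel(sq_dists: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-sq_dists / (2.0 * sigma**2))


def mmd_rbf(
    X: np.ndarray,
    Y: np.ndarray,
    kconfig: KernelConfig | None = None,
    seed: int = 0,
) -> tuple[float, bool]:
    """Biased empirical MMD^2 between two samples, with a permutation H0 decision.

    Returns ``(mmd2, accepted)`` where *accepted* means the estimate is
    below the (1 - alpha) quantile of the permutation null (rows pooled
    and reassigned), i.e. "same distribution" is not rejected.
    """
    kcfg = kconfig or KernelConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValidationError("samples have different dimensions")
    if X.shape[0] < 2 or Y.shape[0] < 2:
        raise ValidationError("each sample needs at least 2 rows")
    m, n = X.shape[0], Y.shape[0]
    Z = np.vstack([X, Y])
    sq = np.sum((Z[:, None, :] - Z[None, :, :]) ** 2, axis=2)
    if kcfg.bandwidth == "median":
        off = sq[np.triu_indices_from(sq, k=1)]
        med = float(np.median(np.sqrt(off[off > 0]))) if (off > 0).any() else 1.0
        sigma = med if med > 0 else 1.0
    else:
        sigma = float(kcfg.bandwidth)
    K = _rbf_kernel(sq, sigma)

    def mmd2(idx_x, idx_y):
        kxx = K[np.ix_(idx_x, idx_x)].mean()
        kyy = K[np.ix_(idx_y, idx_y)].mean()
        kxy = K[np.ix_(idx_x, idx_y)].mean()
        return kxx + kyy - 2.0 * kxy

    ix = np.arange(m)
    iy = np.arange(m, m + n)
    estimate = float(mmd2(ix, iy))
    rng = np.random.default_rng(seed)
    null = np.empty(kcfg.permutations)
    for b in range(kcfg.permutations):
        perm = rng.permutation(m + n)
        null[b] = mmd2(perm[:m], perm[m:])
    threshold = float(np.quantile(null, 1.0 - kcfg.alpha))
    return estimate, bool(estimate <= threshold)


def count_combinations(V: int, k: int) -> int:
    """Binomial coefficient C(V, k) — the number of k-variable subsets."""
    if k < 0 or k > V:
        raise ValueError(f"k={k} outside [0, {V}]")
    return math.comb(V, k)


def encode_numeric(
    data: TableData,
    names: Sequence[str] | None = None,
    center: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, dict[str, tuple[float, float]]]:
    """Numeric matrix encoding of a mixed table.

    Categorical variables are one-hot over declared states (missing is an
    all-zero row plus nothing extra — an augmented table already carries
    an explicit missing category).  Continuous variables are z-scored
    (moments from *center* when given, e.g. from a training table) with a
    paired 0/1 missing-indicator column; missing values contribute 0
    after centering.  Returns the matrix and the moments used.
    """
    names = list(names or data.names)
    cols = []
    moments = dict(center or {})
    for name in names:
        v = data.spec(name)
        if v.kind == CATEGORICAL:
            col = data.df[name].astype(object)
            for s in v.states:
                cols.append((col == s).to_numpy(dtype=float))
        else:
            x = data.df[name].to_numpy(dtype=float)
            miss = np.isnan(x)
            if name not in moments:
                obs = x[~miss]
                mu = float(obs.mean()) if obs.size else 0.0
                sd = float(obs.std()) if obs.size else 1.0
                moments[name] = (mu, sd if sd > 0 else 1.0)
            mu, sd = moments[name]
            z = (x - mu) / sd
            z[miss] = 0.0
            cols.append(z)
            cols.append(miss.astype(float))
    return np.column_stack(cols), moments


def joint_acceptance_sweep(
    gt: TableData,
    syn: TableData,
    k: int,
    n: int = 1000,
    kconfig: KernelConfig | None = None,
    seed: int = 0,
    variables: Sequence[str] | None = None,
) -> float:
    """kMMD H0 acceptance percentage over every k-variable subset.

    For each subset: encode the sub-tables numerically, subsample *n*
    rows from each side, run :func:`mmd_rbf`, and count acceptances.
    Returns the acceptance rate in percent.
    """
    variables = list(variables or gt.names)
    if k > len(variables):
        raise ValidationError(f"k={k} exceeds the {len(variables)} modelled variables")
    if gt.n_rows == 0 or syn.n_rows == 0:
        raise ValidationError("both tables must be non-empty")
    if n > gt.n_rows or n > syn.n_rows:
        raise ValidationError("per-test sample size exceeds table size")
    rng = np.random.default_rng(seed)
    accepted = total = 0
    for subset in itertools.combinations(variables, k):
        gi = rng.choice(gt.n_rows, size=n, replace=False)
        si = rng.choice(syn.n_rows, size=n, replace=False)
        gsub = TableData(
            tuple(gt.spec(s) for s in subset), gt.df.iloc[gi][list(subset)]
        )
        ssub = TableData(
            tuple(syn.spec(s) for s in subset), syn.df.iloc[si][list(subset)]
        )
        Xg, moments = encode_numeric(gsub)
        Xs, _ = encode_numeric(ssub, center=moments)
        _, ok = mmd_rbf(Xg, Xs, kconfig, seed=int(rng.integers(0, 2**31 - 1)))
        accepted += int(ok)
        total += 1
    return 100.0 * accepted / total
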