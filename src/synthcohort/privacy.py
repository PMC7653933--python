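"""Re-identification risk audit of a synthetic cohort against real records.

A synthetic record endangers privacy when it is an exact copy of a real
record (a *clone*), when it sits unusually close to exactly one real
record (an *inlier* pair, nearest distance below the Pr-quantile of the
positive nearest-distance distribution), or when it is an isolated
extreme point whose unique nearest real record is thereby exposed (an
*outlier* pair, nearest distance above the Pt-quantile).  k-anonymity of
a record is the number of real records within a radius of it — releases
can be gated on the smallest k across flagged records.

Distances default to a Gower-style mixed metric: range-normalised
absolute difference for continuous variables, 0/1 mismatch for
categorical ones, with "missing" acting as its own category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .schema_io import CATEGORICAL, CONTINUOUS, TableData, ValidationError

__all__ = [
    "PrivacyConfig",
    "PrivacyReport",
    "nearest_gt_distances",
    "clone_rate",
    "flag_inliers_outliers",
    "k_anonymity",
    "epv_sample_size",
    "privacy_audit",
]

_METRICS = ("gower_mixed", "euclidean_continuous_only")


@dataclass(frozen=True)
class PrivacyConfig:
    """Audit parameters.

    ``pr``/``pt`` are the lower/upper quantile probabilities applied to
    the positive nearest-distance distribution (clone distances of zero
    are excluded and reported separately); ``epv`` is the
    events-per-variable target used to size audit samples.
    """

    metric: str = "gower_mixed"
    pr: float = 0.001
    pt: float = 0.999
    epv: float = 22.2
    inlier_rule: str = "count_within_radius"  # or "unique_nearest"

    def __post_init__(self):
        if self.metric not in _METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if not (0.0 < self.pr < self.pt < 1.0):
            raise ValueError("require 0 < Pr < Pt < 1")
        if self.epv <= 0:
            raise ValueError("EPV must be positive")
        if self.inlier_rule not in ("count_within_radius", "unique_nearest"):
            raise ValueError(f"unknown inlier rule {self.inlier_rule!r}")


@dataclass
class PrivacyReport:
    """Clone / inlier / outlier counts and rates for an audited cohort."""

    size: int
    clone_count: int
    r_clone: float
    inlier_count: int
    outlier_count: int
    inlier_pct: float
    outlier_pct: float
    k_anonymity: int
    thresholds: tuple[float, float] = (float("nan"), float("nan"))
    flagged_inliers: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    flagged_outliers: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        if not (0.0 <= self.r_clone <= 1.0):
            raise ValueError("R_clone outside [0, 1]")
        if max(self.clone_count, self.inlier_count, self.outlier_count) > self.size:
            raise ValueError("counts exceed audited cohort size")
        if self.k_anonymity < 0:
            raise ValueError("k must be >= 0")

    def to_row(self) -> dict:
        return {
            "S": self.size,
            "R_clone": self.r_clone,
            "inliers": self.inlier_count,
            "inlier_pct": self.inlier_pct,
            "outliers": self.outlier_count,
            "outlier_pct": self.outlier_pct,
            "k_anonymity": self.k_anonymity,
        }


# ---------------------------------------------------------------------------
# distances


def _check_schemas(syn: TableData, gt: TableData) -> None:
    if tuple(v.name for v in syn.variables) != tuple(v.name for v in gt.variables) or any(
        a.kind != b.kind for a, b in zip(syn.variables, gt.variables)
    ):
        raise ValidationError("synthetic and ground-truth tables have different schemas")


def _distance_block(syn: TableData, gt: TableData, rows: np.ndarray, metric: str) -> np.ndarray:
    """(len(rows), n_gt) distance matrix for a block of synthetic rows."""
    n_gt = gt.n_rows
    total = np.zeros((rows.size, n_gt))
    n_feat = 0
    for v in syn.variables:
        if v.kind == CONTINUOUS:
            g = gt.df[v.name].to_numpy(dtype=float)
            s = syn.df[v.name].to_numpy(dtype=float)[rows]
            obs = g[~np.isnan(g)]
            rng_w = float(obs.max() - obs.min()) if obs.size else 1.0
            rng_w = rng_w if rng_w > 0 else 1.0
            diff = np.abs(s[:, None] - g[None, :])
            if metric == "gower_mixed":
                diff = diff / rng_w
                # missing acts as its own category: 0 iff both missing, else 1
                sm = np.isnan(s)[:, None]
                gm = np.isnan(g)[None, :]
                diff = np.where(sm | gm, np.where(sm & gm, 0.0, 1.0), diff)
                total += diff
            else:
                z = diff / rng_w
                sm = np.isnan(s)[:, None]
                gm = np.isnan(g)[None, :]
                z = np.where(sm | gm, np.where(sm & gm, 0.0, 1.0), z)
                total += z**2
            n_feat += 1
        else:
            if metric != "gower_mixed":
                continue
            g = gt.df[v.name].astype(object).fillna("\0missing").to_numpy()
            s = syn.df[v.name].astype(object).fillna("\0missing").to_numpy()[rows]
            total += (s[:, None] != g[None, :]).astype(float)
            n_feat += 1
    if n_feat == 0:
        raise ValidationError("no usable features for the chosen metric")
    if metric == "gower_mixed":
        return total / n_feat
    return np.sqrt(total)


def nearest_gt_distances(
    syn: TableData,
    gt: TableData,
    metric: str = "gower_mixed",
    block: int = 256,
) -> pd.DataFrame:
    """Minimum distance from each synthetic row to the real cohort.

    Returns a frame with columns ``distance`` (the minimum), ``index``
    (lowest-index nearest real row — tie-stable) and ``n_ties`` (real
    rows at exactly that distance).  Computed by an exhaustive scan in
    blocks of *block* synthetic rows.
    """
    _check_schemas(syn, gt)
    if gt.n_rows == 0:
        raise ValidationError("ground-truth table is empty")
    dist = np.empty(syn.n_rows)
    idx = np.empty(syn.n_rows, dtype=int)
    ties = np.empty(syn.n_rows, dtype=int)
    for start in range(0, syn.n_rows, block):
        rows = np.arange(start, min(start + block, syn.n_rows))
        d = _distance_block(syn, gt, rows, metric)
        m = d.min(axis=1)
        dist[rows] = m
        idx[rows] = d.argmin(axis=1)
        ties[rows] = (d <= m[:, None] + 1e-12).sum(axis=1)
    return pd.DataFrame({"distance": dist, "index": idx, "n_ties": ties})


def clone_rate(syn: TableData, gt: TableData, denominator: str = "syn") -> float:
    """R_clone: rate of synthetic rows exactly equal to some real row.

    Equality is cell-wise over all variables and sentinel-sensitive (a
    missing cell only matches a missing cell).  With the default
    ``denominator="syn"`` the rate is the fraction of synthetic rows
    that are clones; ``"combined"`` divides the clone count by the size
    of the pooled synthetic + real data set instead — the reading under
    which, for a fixed synthetic cohort, the clone rate falls as the
    real population grows.
    """
    if denominator not in ("syn", "combined"):
        raise ValueError(f"unknown denominator {denominator!r}")
    _check_schemas(syn, gt)
    if syn.n_rows == 0:
        raise ValidationError("synthetic table is empty")

    def keys(t: TableData):
        parts = []
        for v in t.variables:
            col = t.df[v.name]
            if v.kind == CONTINUOUS:
                parts.append(col.map(lambda x: "\0" if math.isnan(x) else format(x, ".17g")))
            else:
                parts.append(col.astype(object).fillna("\0").astype(str))
        return parts[0].str.cat(parts[1:], sep="\x1f") if len(parts) > 1 else parts[0]

    gt_keys = set(keys(gt))
    syn_keys = keys(syn)
    clones = int(syn_keys.isin(gt_keys).sum())
    if denominator == "combined":
        return clones / (syn.n_rows + gt.n_rows)
    return clones / syn.n_rows


def flag_inliers_outliers(
    distances: pd.DataFrame,
    config: PrivacyConfig | None = None,
    within_pr_counts: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Flag inlier and outlier pairs from the nearest-distance audit.

    Thresholds are the empirical Pr- and Pt-quantiles of the *positive*
    nearest distances (exact-zero clone distances are excluded — clones
    are reported separately).  An inlier pair requires the nearest
    distance <= the Pr-quantile and exactly one real record within that
    radius (pass *within_pr_counts* from :func:`within_radius_counts`;
    without it, or under ``inlier_rule="unique_nearest"``, uniqueness of
    the nearest record is used).  An outlier pair requires the nearest
    distance >= the Pt-quantile and a unique nearest record.  Returns
    (inlier row indices, outlier row indices, (q_pr, q_pt)).
    """
    cfg = config or PrivacyConfig()
    d = distances["distance"].to_numpy(dtype=float)
    if d.size == 0:
        raise ValidationError("empty distance list")
    ties = distances["n_ties"].to_numpy(dtype=int)
    pos = d[d > 0]
    if pos.size == 0:  # every synthetic row is a clone
        return np.array([], dtype=int), np.array([], dtype=int), (0.0, 0.0)
    q_pr = float(np.quantile(pos, cfg.pr))
    q_pt = float(np.quantile(pos, cfg.pt))
    near = (d > 0) & (d <= q_pr)
    if within_pr_counts is not None and cfg.inlier_rule == "count_within_radius":
        unique_near = within_pr_counts == 1
    else:
        unique_near = ties == 1
    inliers = np.flatnonzero(near & unique_near)
    outliers = np.flatnonzero((d >= q_pt) & (ties == 1))
    return inliers, outliers, (q_pr, q_pt)


def within_radius_counts(
    syn: TableData,
    gt: TableData,
    radius: float,
    metric: str = "gower_mixed",
    block: int = 256,
) -> np.ndarray:
    """Number of real records within *radius* of each synthetic row."""
    _check_schemas(syn, gt)
    out = np.empty(syn.n_rows, dtype=int)
    for start in range(0, syn.n_rows, block):
        rows = np.arange(start, min(start + block, syn.n_rows))
        d = _distance_block(syn, gt, rows, metric)
        out[rows] = (d <= radius + 1e-12).sum(axis=1)
    return out


def k_anonymity(
    syn_row: TableData,
    gt: TableData,
    radius: float,
    metric: str = "gower_mixed",
) -> int:
    """k = number of real records within *radius* of the synthetic record.

    The default radius rule of the audit is the Pt-quantile of the global
    positive nearest-distance distribution; the smallest k over an
    audited set is its k-anonymisation value.
    """
    if gt.n_rows == 0:
        raise ValidationError("ground-truth table is empty")
    if syn_row.n_rows != 1:
        raise ValidationError("k_anonymity audits a single synthetic record")
    d = _distance_block(syn_row, gt, np.array([0]), metric)[0]
    return int((d <= radius + 1e-12).sum())


def epv_sample_size(events_fraction: float, df: int, epv: float = 22.2) -> int:
    """Smallest n with (n * events_fraction) / df >= epv."""
    if not (0.0 < events_fraction <= 1.0):
        raise ValidationError("events fraction must be in (0, 1]")
    if df < 1:
        raise ValidationError("df must be >= 1")
    if epv <= 0:
        raise ValidationError("EPV must be positive")
    n = math.ceil(epv * df / events_fraction)
    # guard the boundary: ceil of an exactly attained product stays there
    while (n * events_fraction) / df < epv:
        n += 1
    return int(n)


def privacy_audit(
    syn: TableData,
    gt: TableData,
    config: PrivacyConfig | None = None,
) -> PrivacyReport:
    """Full audit: clones, inlier/outlier pairs, and the k-anonymisation value.

    k-anonymity is evaluated for every flagged record at the Pt-quantile
    radius; the report carries the smallest such k (0 when nothing is
    flagged but distances exist beyond the radius).
    """
    cfg = config or PrivacyConfig()
    dist = nearest_gt_distances(syn, gt, cfg.metric)
    r_clone = clone_rate(syn, gt)
    clone_count = int(round(r_clone * syn.n_rows))
    d = dist["distance"].to_numpy()
    pos = d[d > 0]
    if pos.size == 0:
        return PrivacyReport(syn.n_rows, clone_count, r_clone, 0, 0, 0.0, 0.0, 0)
    q_pr = float(np.quantile(pos, cfg.pr))
    counts_pr = None
    if cfg.inlier_rule == "count_within_radius":
        counts_pr = within_radius_counts(syn, gt, q_pr, cfg.metric)
    inliers, outliers, (q_pr, q_pt) = flag_inliers_outliers(dist, cfg, counts_pr)
    flagged = np.concatenate([inliers, outliers])
    k_min = 0
    if flagged.size:
        ks = []
        for i in flagged:
            row = TableData(syn.variables, syn.df.iloc[[int(i)]])
            ks.append(k_anonymity(row, gt, q_pt, cfg.metric))
        k_min = int(min(ks))
    return PrivacyReport(
        size=syn.n_rows,
        clone_count=clone_count,
        r_clone=r_clone,
        inlier_count=int(inliers.size),
        outlier_count=int(outliers.size),
        inlier_pct=100.0 * inliers.size / syn.n_rows,
        outlier_pct=100.0 * outliers.size / syn.n_rows,
        k_anonymity=k_min,
        thresholds=(q_pr, q_pt),
        flagged_inliers=inliers,
        flagged_outliers=outliers,
    )
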