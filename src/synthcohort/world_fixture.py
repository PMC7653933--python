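"""A fully known simulated primary-care world for end-to-end testing.

Real primary-care extracts are access-restricted, so every pipeline
stage is exercised against a hand-specified "true" Bayesian network over
a cardiovascular-risk feature set: 18 categorical and 5 continuous
variables (age, bmi, choleratio, sbp, sbps), with ``strokeha`` as the
dependent outcome.  The network encodes a subset of clinically
recognised dependencies (smoking -> impotence, age -> type 2 diabetes,
atrial fibrillation -> stroke/heart attack, age -> systolic blood
pressure, ...); all parameters are invented fixture constants, not
clinical claims.

Missingness is applied on top of the complete population: per-variable
rates follow the profile (age 0%, choleratio 88.47%, bmi 15.85%,
sbp 8.37%, sbps 38.25%, categorical variables 5%), and choleratio is
missing *not* at random — a hidden binary health-seeking factor both
shifts its value and drives whether it is measured.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .bn_core import (
    BayesNetwork,
    CategoricalCPD,
    GaussianMixtureCPD,
    NetworkStructure,
    logic_sample,
)
from .schema_io import CATEGORICAL, CONTINUOUS, TableData, ValidationError, VariableSpec

__all__ = ["WorldFixture", "make_world", "inject_privacy_cases", "DEFAULT_MISSING_RATES"]

_YN = ("no", "yes")

#: per-variable missing rates of the default profile
DEFAULT_MISSING_RATES: dict[str, float] = {
    "age": 0.0,
    "choleratio": 0.8847,
    "bmi": 0.1585,
    "sbp": 0.0837,
    "sbps": 0.3825,
}
_CATEGORICAL_MISS_RATE = 0.05

# MNAR mechanism for choleratio: P(health-seeking) = 0.3;
# P(missing | seeking) and P(missing | not) solve the overall 88.47% rate.
_P_SEEK = 0.3
_P_MISS_SEEK = 0.72
_P_MISS_NOSEEK = (DEFAULT_MISSING_RATES["choleratio"] - _P_SEEK * _P_MISS_SEEK) / (1 - _P_SEEK)


@dataclass
class WorldFixture:
    """True network + complete population + observed (masked) population."""

    network: BayesNetwork
    population: TableData  # complete values, hidden factor dropped
    observed: TableData  # with missingness applied
    missingness: Mapping[str, dict]
    seed: int

    def realized_missing_rates(self) -> dict[str, float]:
        return {
            v.name: float(self.observed.df[v.name].isna().mean())
            for v in self.observed.variables
        }


def _cpt(parent_cards: list[int], fn) -> np.ndarray:
    """Build a CPT; configs iterate parents in order, last varying fastest
    (matching ``np.ravel_multi_index``)."""
    rows = [fn(*combo) for combo in itertools.product(*[range(c) for c in parent_cards])]
    return np.array(rows, dtype=float)


def _binary(p_yes: float) -> list[float]:
    return [1.0 - p_yes, p_yes]


def _true_network() -> BayesNetwork:
    specs = [
        VariableSpec("age", CONTINUOUS, units="years"),
        VariableSpec("gender", CATEGORICAL, ("female", "male")),
        VariableSpec("strokeha", CATEGORICAL, _YN, role="dependent"),
        VariableSpec("af", CATEGORICAL, _YN),
        VariableSpec("atyantip", CATEGORICAL, _YN),
        VariableSpec("steroid", CATEGORICAL, _YN),
        VariableSpec("impot", CATEGORICAL, _YN),
        VariableSpec("migr", CATEGORICAL, _YN),
        VariableSpec("ra", CATEGORICAL, _YN),
        VariableSpec("ckidney", CATEGORICAL, _YN),
        VariableSpec("semi", CATEGORICAL, _YN),
        VariableSpec("sle", CATEGORICAL, _YN),
        VariableSpec("treathyp", CATEGORICAL, _YN),
        VariableSpec("type1", CATEGORICAL, _YN),
        VariableSpec("type2", CATEGORICAL, _YN),
        VariableSpec("bmi", CONTINUOUS, units="kg/m^2"),
        VariableSpec("ethr", CATEGORICAL, ("white", "south_asian", "black", "east_asian", "other")),
        VariableSpec("choleratio", CONTINUOUS, units="ratio"),
        VariableSpec("sbp", CONTINUOUS, units="mmHg"),
        VariableSpec("sbps", CONTINUOUS, units="mmHg"),
        VariableSpec("smoking", CATEGORICAL, ("non", "ex", "current")),
        VariableSpec("fh_cad", CATEGORICAL, _YN),
        VariableSpec("region", CATEGORICAL, ("north", "midlands", "london", "south", "other")),
        VariableSpec("healthseek", CATEGORICAL, _YN),
    ]
    nodes = tuple(v.name for v in specs)
    edges = {
        ("age", "af"),
        ("age", "ckidney"),
        ("age", "treathyp"),
        ("age", "type2"),
        ("age", "sbp"),
        ("af", "strokeha"),
        ("ckidney", "strokeha"),
        ("fh_cad", "strokeha"),
        ("semi", "atyantip"),
        ("semi", "migr"),
        ("smoking", "semi"),
        ("smoking", "impot"),
        ("smoking", "sbp"),
        ("gender", "impot"),
        ("type1", "impot"),
        ("ra", "sle"),
        ("sle", "steroid"),
        ("ra", "steroid"),
        ("ethr", "bmi"),
        ("type2", "choleratio"),
        ("healthseek", "choleratio"),
        ("sbp", "sbps"),
        ("region", "smoking"),
    }
    structure = NetworkStructure(nodes, frozenset(edges))

    # discretisers for continuous parents (fixed profile constants)
    discretizers = {
        "age": np.array([40.0, 55.0, 65.0, 75.0]),
        "bmi": np.array([22.0, 25.0, 28.0, 32.0]),
        "choleratio": np.array([3.2, 3.8, 4.4, 5.2]),
        "sbp": np.array([115.0, 125.0, 135.0, 148.0]),
        "sbps": np.array([4.0, 6.0, 8.0, 10.0]),
    }

    cpds: dict[str, object] = {}
    # --- roots -----------------------------------------------------------
    cpds["age"] = GaussianMixtureCPD(
        "age", (),
        weights=[[0.55, 0.35, 0.10]],
        means=[[44.0, 66.0, 30.0]],
        variances=[[121.0, 64.0, 25.0]],
    )
    cpds["gender"] = CategoricalCPD("gender", (), [[0.51, 0.49]])
    cpds["ra"] = CategoricalCPD("ra", (), [_binary(0.03)])
    cpds["type1"] = CategoricalCPD("type1", (), [_binary(0.005)])
    cpds["fh_cad"] = CategoricalCPD("fh_cad", (), [_binary(0.12)])
    cpds["ethr"] = CategoricalCPD("ethr", (), [[0.78, 0.08, 0.05, 0.04, 0.05]])
    cpds["region"] = CategoricalCPD("region", (), [[0.26, 0.22, 0.18, 0.24, 0.10]])
    cpds["healthseek"] = CategoricalCPD("healthseek", (), [_binary(_P_SEEK)])

    # --- categorical children -------------------------------------------
    cpds["af"] = CategoricalCPD(
        "af", ("age",), _cpt([5], lambda a: _binary([0.002, 0.01, 0.03, 0.07, 0.12][a]))
    )
    cpds["ckidney"] = CategoricalCPD(
        "ckidney", ("age",), _cpt([5], lambda a: _binary([0.002, 0.012, 0.035, 0.08, 0.15][a]))
    )
    cpds["treathyp"] = CategoricalCPD(
        "treathyp", ("age",), _cpt([5], lambda a: _binary([0.02, 0.09, 0.22, 0.36, 0.46][a]))
    )
    cpds["type2"] = CategoricalCPD(
        "type2", ("age",), _cpt([5], lambda a: _binary([0.01, 0.045, 0.09, 0.14, 0.17][a]))
    )
    cpds["smoking"] = CategoricalCPD(
        "smoking",
        ("region",),
        _cpt(
            [5],
            lambda r: [
                [0.56, 0.24, 0.20],
                [0.53, 0.25, 0.22],
                [0.58, 0.22, 0.20],
                [0.60, 0.24, 0.16],
                [0.52, 0.24, 0.24],
            ][r],
        ),
    )
    cpds["semi"] = CategoricalCPD(
        "semi", ("smoking",), _cpt([3], lambda s: _binary([0.03, 0.05, 0.09][s]))
    )
    cpds["atyantip"] = CategoricalCPD(
        "atyantip", ("semi",), _cpt([2], lambda s: _binary([0.008, 0.35][s]))
    )
    cpds["migr"] = CategoricalCPD(
        "migr", ("semi",), _cpt([2], lambda s: _binary([0.12, 0.25][s]))
    )
    cpds["sle"] = CategoricalCPD(
        "sle", ("ra",), _cpt([2], lambda r: _binary([0.004, 0.05][r]))
    )
    # parents of steroid in declaration order: (ra, sle)
    cpds["steroid"] = CategoricalCPD(
        "steroid",
        ("ra", "sle"),
        _cpt([2, 2], lambda r, s: _binary(0.03 + 0.27 * r + 0.40 * s)),
    )
    # parents of impot in declaration order: (gender, type1, smoking)
    cpds["impot"] = CategoricalCPD(
        "impot",
        ("gender", "type1", "smoking"),
        _cpt(
            [2, 2, 3],
            lambda g, t, s: _binary(
                0.001 if g == 0 else min(0.05 + 0.10 * t + [0.0, 0.03, 0.08][s], 0.95)
            ),
        ),
    )
    # parents of strokeha in declaration order: (af, ckidney, fh_cad)
    cpds["strokeha"] = CategoricalCPD(
        "strokeha",
        ("af", "ckidney", "fh_cad"),
        _cpt([2, 2, 2], lambda a, c, f: _binary(min(0.025 + 0.14 * a + 0.10 * c + 0.05 * f, 0.9))),
    )

    # --- continuous children --------------------------------------------
    cpds["bmi"] = GaussianMixtureCPD(
        "bmi",
        ("ethr",),
        weights=_cpt([5], lambda e: [[0.55, 0.35, 0.10], [0.45, 0.40, 0.15],
                                     [0.40, 0.42, 0.18], [0.60, 0.32, 0.08],
                                     [0.50, 0.38, 0.12]][e]),
        means=_cpt([5], lambda e: [m + [0.0, 0.8, 1.4, -1.2, 0.4][e] for m in (24.0, 28.5, 34.0)]),
        variances=_cpt([5], lambda e: [5.3, 7.8, 13.0]),
    )
    # parents of choleratio in declaration order: (type2, healthseek)
    cpds["choleratio"] = GaussianMixtureCPD(
        "choleratio",
        ("type2", "healthseek"),
        weights=_cpt([2, 2], lambda t, h: [0.70, 0.25, 0.05]),
        means=_cpt(
            [2, 2],
            lambda t, h: [
                m + 0.7 * t + (0.9 if h == 0 else 0.0) for m in (3.6, 4.8, 6.1)
            ],
        ),
        variances=_cpt([2, 2], lambda t, h: [0.49, 1.00, 2.25]),
    )
    # parents of sbp in declaration order: (age, smoking)
    cpds["sbp"] = GaussianMixtureCPD(
        "sbp",
        ("age", "smoking"),
        weights=_cpt([5, 3], lambda a, s: [0.85, 0.15]),
        means=_cpt(
            [5, 3],
            lambda a, s: [m + 3.5 * a + [0.0, -1.0, 4.0][s] for m in (116.0, 134.0)],
        ),
        variances=_cpt([5, 3], lambda a, s: [121.0, 256.0]),
    )
    cpds["sbps"] = GaussianMixtureCPD(
        "sbps",
        ("sbp",),
        weights=_cpt([5], lambda b: [0.80, 0.20]),
        means=_cpt([5], lambda b: [5.5 + 1.1 * b, 9.5 + 1.1 * b]),
        variances=_cpt([5], lambda b: [4.84, 12.25]),
    )

    return BayesNetwork(
        structure,
        cpds,
        tuple(specs),
        latent=frozenset({"healthseek"}),
        discretizers=discretizers,
    )


def make_world(size: int, seed: int = 0, profile: str = "cprd_cvd") -> WorldFixture:
    """Build the true network, sample a complete population of *size*
    records, and apply the missingness profile.

    Same seed, same world.  The hidden health-seeking factor is sampled
    alongside the population, drives the choleratio MNAR mask, and is
    then dropped from both emitted tables.
    """
    if profile != "cprd_cvd":
        raise ValidationError(f"unknown world profile {profile!r}")
    if size < 1:
        raise ValidationError("population size must be >= 1")
    net = _true_network()
    full = logic_sample(net, size, seed=seed, include_latent=True)
    seeking = full.df["healthseek"].to_numpy(dtype=object) == "yes"
    emit_specs = tuple(v for v in full.variables if v.name != "healthseek")
    complete = TableData(emit_specs, full.df[[v.name for v in emit_specs]])

    rng = np.random.default_rng(seed + 1)
    observed_df = complete.df.copy()
    missingness: dict[str, dict] = {}
    for v in emit_specs:
        if v.name == "choleratio":
            p = np.where(seeking, _P_MISS_SEEK, _P_MISS_NOSEEK)
            mask = rng.random(size) < p
            missingness[v.name] = {
                "mechanism": "MNAR",
                "rate": DEFAULT_MISSING_RATES[v.name],
                "driver": "hidden health-seeking factor (also shifts the value)",
            }
        else:
            rate = DEFAULT_MISSING_RATES.get(v.name, _CATEGORICAL_MISS_RATE)
            mask = rng.random(size) < rate
            missingness[v.name] = {"mechanism": "MCAR", "rate": rate}
        if mask.any():
            col = observed_df[v.name].copy()
            if v.kind == CONTINUOUS:
                col[mask] = np.nan
            else:
                col = col.astype(object)
                col[mask] = np.nan
            observed_df[v.name] = col
    observed = TableData(emit_specs, observed_df)
    return WorldFixture(net, complete, observed, missingness, seed)


def inject_privacy_cases(
    syn: TableData,
    gt: TableData,
    clones: int = 0,
    outliers: int = 0,
    seed: int = 0,
) -> tuple[TableData, dict[str, np.ndarray]]:
    """Plant known privacy risks into a synthetic cohort for audit tests.

    Replaces *clones* random synthetic rows with exact copies of random
    real rows, and *outliers* rows with records pushed far outside the
    real data cloud (continuous values beyond the observed range).
    Returns the edited table and the planted row indices.
    """
    if clones + outliers > syn.n_rows:
        raise ValidationError("planted counts exceed the synthetic cohort size")
    rng = np.random.default_rng(seed)
    df = syn.df.copy()
    targets = rng.choice(syn.n_rows, size=clones + outliers, replace=False)
    clone_idx = np.sort(targets[:clones])
    outlier_idx = np.sort(targets[clones:])
    if clones:
        src = rng.choice(gt.n_rows, size=clones, replace=True)
        for t, s in zip(clone_idx, src):
            df.iloc[int(t)] = gt.df.iloc[int(s)]
    for t in outlier_idx:
        for v in syn.variables:
            if v.kind == CONTINUOUS:
                col = gt.df[v.name].to_numpy(dtype=float)
                obs = col[~np.isnan(col)]
                lo, hi = float(obs.min()), float(obs.max())
                span = max(hi - lo, 1.0)
                df.loc[df.index[int(t)], v.name] = hi + span * (2.0 + rng.random())
    return TableData(syn.variables, df), {"clones": clone_idx, "outliers": outlier_idx}
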