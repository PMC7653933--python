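"""Hybrid Bayesian network core.

A Bayesian network factorises the joint distribution of a patient cohort
as ``p(x) = prod_i p(x_i | pa_i)`` over a directed acyclic graph.  This
module provides:

* a hybrid representation — categorical nodes carry conditional
  probability tables, continuous nodes carry per-parent-configuration
  Gaussian mixtures (continuous parents are discretised into quantile
  bins for conditioning);
* ``joint_probability`` (the factorised joint / density);
* ``logic_sample`` — ancestral forward sampling with clamped evidence;
* ``fit_parameters`` — maximum-likelihood fitting, closed-form on
  complete data and EM when latent nodes or missing cells are present;
* ``learn_structure`` — greedy BIC hill-climbing on bootstrap resamples
  with per-arc confidence (fraction of resamples containing the arc);
* ``whitelist_edit`` — expert add/remove edits with acyclicity checks.

All randomness flows from explicit integer seeds; resample ``i`` of a
bootstrap uses ``seed + i``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .schema_io import (
    CATEGORICAL,
    CONTINUOUS,
    SchemaError,
    TableData,
    ValidationError,
    VariableSpec,
    is_missing,
)

__all__ = [
    "NetworkStructure",
    "CategoricalCPD",
    "GaussianMixtureCPD",
    "BayesNetwork",
    "EMConfig",
    "StructureConfig",
    "joint_probability",
    "logic_sample",
    "fit_parameters",
    "learn_structure",
    "whitelist_edit",
    "export_edge_list",
    "network_to_dict",
    "network_from_dict",
]

_VAR_FLOOR = 1e-9


# ---------------------------------------------------------------------------
# structure


@dataclass(frozen=True)
class NetworkStructure:
    """A DAG over named nodes with per-arc confidence in [0, 1].

    Confidence 1.0 corresponds to an arc recovered in every bootstrap
    resample (or asserted by an expert edit).
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    arc_confidence: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", frozenset(tuple(e) for e in self.edges))
        conf = {tuple(k): float(v) for k, v in dict(self.arc_confidence).items()}
        for e in self.edges:
            conf.setdefault(e, 1.0)
        object.__setattr__(self, "arc_confidence", conf)
        known = set(self.nodes)
        for p, c in self.edges:
            if p not in known or c not in known:
                raise SchemaError(f"edge ({p!r}, {c!r}) references undeclared node")
        for e, v in conf.items():
            if not (0.0 <= v <= 1.0):
                raise SchemaError(f"arc confidence {v} for {e} outside [0, 1]")
        cyc = _find_cycle(self.nodes, self.edges)
        if cyc:
            raise SchemaError(f"structure contains a cycle: {' -> '.join(cyc)}")

    def parents(self, node: str) -> tuple[str, ...]:
        order = {n: i for i, n in enumerate(self.nodes)}
        return tuple(sorted((p for p, c in self.edges if c == node), key=order.get))

    def children(self, node: str) -> tuple[str, ...]:
        order = {n: i for i, n in enumerate(self.nodes)}
        return tuple(sorted((c for p, c in self.edges if p == node), key=order.get))

    def topological_order(self) -> tuple[str, ...]:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        # stable: break ties by declaration order
        order = {n: i for i, n in enumerate(self.nodes)}
        return tuple(nx.lexicographical_topological_sort(g, key=order.get))


def _find_cycle(nodes, edges) -> list[str] | None:
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    try:
        cyc = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return None
    return [e[0] for e in cyc] + [cyc[-1][1]]


def whitelist_edit(
    structure: NetworkStructure,
    add: Iterable[tuple[str, str]] = (),
    remove: Iterable[tuple[str, str]] = (),
) -> NetworkStructure:
    """Apply expert edits: drop known-false arcs, assert known-true ones.

    Added arcs receive confidence 1.0; adding an existing arc is
    idempotent.  An edit that would create a cycle raises
    :class:`SchemaError` naming the cycle.
    """
    add = [tuple(e) for e in add]
    remove = {tuple(e) for e in remove}
    known = set(structure.nodes)
    for p, c in list(add) + list(remove):
        if p not in known or c not in known:
            raise SchemaError(f"edit references undeclared node in ({p!r}, {c!r})")
    edges = set(structure.edges) - remove
    conf = {e: v for e, v in structure.arc_confidence.items() if e in edges}
    for e in add:
        edges.add(e)
        conf[e] = 1.0
    return NetworkStructure(structure.nodes, frozenset(edges), conf)


def export_edge_list(structure: NetworkStructure, path) -> None:
    """Write ``parent,child,confidence`` lines for external graph viewers."""
    lines = [
        f"{p},{c},{structure.arc_confidence.get((p, c), 1.0):.3f}"
        for p, c in sorted(structure.edges)
    ]
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# conditional distributions


@dataclass
class CategoricalCPD:
    """CPT of a categorical child: rows are parent configurations."""

    child: str
    parents: tuple[str, ...]
    table: np.ndarray  # (n_configs, n_states)
    smoothed: np.ndarray | None = None  # configs that fell back to the prior

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim != 2:
            raise SchemaError(f"CPT of {self.child!r} must be 2-D")
        if (self.table < 0).any():
            raise SchemaError(f"negative probability in CPT of {self.child!r}")
        sums = self.table.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise SchemaError(f"CPT rows of {self.child!r} do not sum to 1")


@dataclass
class GaussianMixtureCPD:
    """Gaussian-mixture density of a continuous child per parent configuration."""

    child: str
    parents: tuple[str, ...]
    weights: np.ndarray  # (n_configs, k)
    means: np.ndarray  # (n_configs, k)
    variances: np.ndarray  # (n_configs, k)
    smoothed: np.ndarray | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if not (self.weights.shape == self.means.shape == self.variances.shape):
            raise SchemaError(f"mixture arrays of {self.child!r} have mismatched shapes")
        if (self.variances <= 0).any():
            raise SchemaError(f"non-positive variance in mixture of {self.child!r}")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-9):
            raise SchemaError(f"mixture weights of {self.child!r} do not sum to 1")

    def logpdf(self, config: np.ndarray, x: np.ndarray) -> np.ndarray:
        w = self.weights[config]
        mu = self.means[config]
        var = self.variances[config]
        comp = (
            -0.5 * np.log(2 * np.pi * var)
            - 0.5 * (x[:, None] - mu) ** 2 / var
            + np.log(np.maximum(w, 1e-300))
        )
        return logsumexp(comp, axis=1)

    def bin_mass(self, edges: np.ndarray) -> np.ndarray:
        """Probability mass of each discretiser bin, per parent config."""
        cuts = np.concatenate(([-np.inf], edges, [np.inf]))
        sd = np.sqrt(self.variances)
        # (n_configs, k, n_edges+2)
        cdf = norm.cdf((cuts[None, None, :] - self.means[:, :, None]) / sd[:, :, None])
        mass = (self.weights[:, :, None] * np.diff(cdf, axis=2)).sum(axis=1)
        mass = np.maximum(mass, 1e-12)
        return mass / mass.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# the network


@dataclass
class BayesNetwork:
    """Structure + CPDs + schema (+ quantile discretisers for continuous parents)."""

    structure: NetworkStructure
    cpds: dict[str, CategoricalCPD | GaussianMixtureCPD]
    schema: tuple[VariableSpec, ...]
    latent: frozenset[str] = frozenset()
    discretizers: dict[str, np.ndarray] = field(default_factory=dict)
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.schema = tuple(self.schema)
        by_name = {v.name: v for v in self.schema}
        for n in self.structure.nodes:
            if n not in by_name:
                raise SchemaError(f"node {n!r} has no variable declaration")
            if n not in self.cpds:
                raise SchemaError(f"node {n!r} has no conditional distribution")
        for n, cpd in self.cpds.items():
            if tuple(cpd.parents) != self.structure.parents(n):
                raise SchemaError(f"CPD parents of {n!r} disagree with the structure")
            n_cfg = int(np.prod([self._cond_card(p) for p in cpd.parents], initial=1.0))
            got = cpd.table.shape[0] if isinstance(cpd, CategoricalCPD) else cpd.weights.shape[0]
            if got != n_cfg:
                raise SchemaError(
                    f"CPD of {n!r} covers {got} parent configurations, expected {n_cfg}"
                )
            if isinstance(cpd, CategoricalCPD) and cpd.table.shape[1] != by_name[n].n_states:
                raise SchemaError(f"CPT of {n!r} has wrong number of states")

    def spec(self, name: str) -> VariableSpec:
        for v in self.schema:
            if v.name == name:
                return v
        raise KeyError(name)

    def _cond_card(self, name: str) -> int:
        v = self.spec(name)
        if v.kind == CATEGORICAL:
            return v.n_states
        edges = self.discretizers.get(name)
        if edges is None:
            raise SchemaError(f"continuous parent {name!r} has no discretiser")
        return len(edges) + 1

    def _cond_code(self, name: str, values: np.ndarray) -> np.ndarray:
        """Conditioning code of observed values (state index or quantile bin)."""
        v = self.spec(name)
        if v.kind == CATEGORICAL:
            lut = {s: i for i, s in enumerate(v.states)}
            return np.array([lut[x] for x in values], dtype=np.int64)
        return np.searchsorted(self.discretizers[name], np.asarray(values, float), side="right")

    def _config_index(self, name: str, value_columns: Mapping[str, np.ndarray]) -> np.ndarray:
        parents = self.structure.parents(name)
        if not parents:
            return np.zeros(len(next(iter(value_columns.values()))) if value_columns else 1, dtype=np.int64)
        cards = [self._cond_card(p) for p in parents]
        codes = [self._cond_code(p, value_columns[p]) for p in parents]
        return np.ravel_multi_index(codes, cards)


# ---------------------------------------------------------------------------
# joint probability (chain-rule factorisation)


def joint_probability(net: BayesNetwork, record: Mapping[str, object]) -> float:
    """Probability (density, if continuous nodes are present) of a complete record.

    The value is the product over nodes of ``p(x_i | pa_i)``.  A record
    that leaves any node unassigned raises :class:`ValidationError`
    listing the unassigned nodes.
    """
    missing = [n for n in net.structure.nodes if n not in record]
    if missing:
        raise ValidationError(f"record leaves nodes unassigned: {missing}")
    logp = 0.0
    cols = {n: np.array([record[n]], dtype=object) for n in net.structure.nodes}
    for n in net.structure.nodes:
        v = net.spec(n)
        parent_cols = {
            p: (np.array([float(record[p])]) if net.spec(p).kind == CONTINUOUS else np.array([record[p]], dtype=object))
            for p in net.structure.parents(n)
        }
        cfg = net._config_index(n, parent_cols)[0] if net.structure.parents(n) else 0
        cpd = net.cpds[n]
        if v.kind == CATEGORICAL:
            logp += math.log(max(cpd.table[cfg, v.state_index(str(record[n]))], 1e-300))
        else:
            logp += float(cpd.logpdf(np.array([cfg]), np.array([float(record[n])]))[0])
    return math.exp(logp)


# ---------------------------------------------------------------------------
# logic sampling


def logic_sample(
    net: BayesNetwork,
    n: int,
    evidence: Mapping[str, object] | None = None,
    seed: int = 0,
    include_latent: bool = False,
) -> TableData:
    """Ancestral (logic) sampling of *n* records, with clamped evidence.

    Nodes are sampled in topological order from their CPDs; nodes named
    in *evidence* are clamped to the given value in every row, so the
    sample is drawn from the mutilated network (e.g. female-only
    cohorts).  Identical seeds give identical samples.  Latent nodes are
    dropped from the emitted table unless *include_latent*.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    evidence = dict(evidence or {})
    for k, val in evidence.items():
        if k not in net.structure.nodes:
            raise ValidationError(f"evidence names undeclared node {k!r}")
        v = net.spec(k)
        if v.kind == CATEGORICAL and str(val) not in v.states:
            raise ValidationError(f"evidence value {val!r} outside declared states of {k!r}")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for name in net.structure.topological_order():
        v = net.spec(name)
        if name in evidence:
            if v.kind == CATEGORICAL:
                cols[name] = np.full(n, str(evidence[name]), dtype=object)
            else:
                cols[name] = np.full(n, float(evidence[name]))
            continue
        parents = net.structure.parents(name)
        cfg = net._config_index(name, {p: cols[p] for p in parents}) if parents else np.zeros(n, dtype=np.int64)
        cpd = net.cpds[name]
        if v.kind == CATEGORICAL:
            probs = cpd.table[cfg]  # (n, n_states)
            u = rng.random(n)
            idx = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
            idx = np.minimum(idx, v.n_states - 1)
            states = np.asarray(v.states, dtype=object)
            cols[name] = states[idx]
        else:
            w = cpd.weights[cfg]
            u = rng.random(n)
            comp = (u[:, None] > np.cumsum(w, axis=1)).sum(axis=1)
            comp = np.minimum(comp, w.shape[1] - 1)
            mu = cpd.means[cfg, comp]
            sd = np.sqrt(cpd.variances[cfg, comp])
            cols[name] = rng.normal(mu, sd)
    keep = [
        v
        for v in net.schema
        if v.name in net.structure.nodes and (include_latent or v.name not in net.latent)
    ]
    return TableData(tuple(keep), pd.DataFrame({v.name: cols[v.name] for v in keep}))


# ---------------------------------------------------------------------------
# parameter fitting


@dataclass(frozen=True)
class EMConfig:
    """Controls for (EM) parameter fitting.

    ``smoothing`` is the pseudo-count added to every CPT cell (add-one-half
    by default) so unseen parent configurations fall back to a flat prior.
    ``max_enum`` caps the per-row enumeration of unobserved discrete
    configurations; rows needing more are partially hard-imputed to their
    column mode before EM.
    """

    max_iter: int = 50
    tol: float = 1e-4
    seed: int = 0
    n_mix: int = 3
    smoothing: float = 0.5
    n_bins: int = 5
    max_enum: int = 1024
    restarts: int = 1

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


def _quantile_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    obs = values[~np.isnan(values)]
    if obs.size == 0:
        raise ValidationError("continuous column with no observed values")
    qs = np.quantile(obs, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.unique(qs)


def _fit_weighted_gmm(
    x: np.ndarray,
    w: np.ndarray,
    k: int,
    rng: np.random.Generator,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    n_iter: int = 60,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted-sample EM for a 1-D Gaussian mixture (weights, means, vars)."""
    wsum = w.sum()
    mean = float(np.average(x, weights=w))
    var = float(np.average((x - mean) ** 2, weights=w)) + _VAR_FLOOR
    k = int(min(k, max(1, np.unique(x).size)))
    if k == 1 or wsum <= 0:
        return np.ones(1), np.array([mean]), np.array([var])
    if init is not None and init[0].size == k:
        pi, mu, v = (a.copy() for a in init)
    else:
        # spread initial means over weighted quantiles
        order = np.argsort(x)
        cw = np.cumsum(w[order]) / wsum
        mu = np.interp(np.linspace(0.15, 0.85, k), cw, x[order])
        mu = mu + rng.normal(0, 1e-3 * math.sqrt(var), k)
        v = np.full(k, var)
        pi = np.full(k, 1.0 / k)
    floor = _VAR_FLOOR + 1e-6 * var
    prev = -np.inf
    for _ in range(n_iter):
        logc = (
            -0.5 * np.log(2 * np.pi * v)[None, :]
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / v[None, :]
            + np.log(np.maximum(pi, 1e-300))[None, :]
        )
        ll_row = logsumexp(logc, axis=1)
        ll = float(np.dot(w, ll_row))
        r = np.exp(logc - ll_row[:, None]) * w[:, None]
        nk = r.sum(axis=0)
        if (nk < 1e-10).any():
            break
        pi = nk / nk.sum()
        mu = (r * x[:, None]).sum(axis=0) / nk
        v = np.maximum((r * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk, floor)
        if ll - prev < 1e-8 * (abs(prev) + 1.0):
            break
        prev = ll
    return pi, mu, v


class _FitEngine:
    """Shared machinery for closed-form counting and EM."""

    def __init__(self, structure, data, config, latents):
        self.structure = structure
        self.config = config
        latents = latents or {}
        self.latent_cards = dict(latents)
        data_specs = {v.name: v for v in data.variables}
        schema = []
        for n in structure.nodes:
            if n in data_specs:
                schema.append(data_specs[n])
            elif n in self.latent_cards:
                m = int(self.latent_cards[n])
                if m < 2:
                    raise ValueError(f"latent {n!r} needs cardinality >= 2")
                schema.append(
                    VariableSpec(n, CATEGORICAL, tuple(f"s{i}" for i in range(m)))
                )
            else:
                raise SchemaError(f"node {n!r} is neither in the data nor declared latent")
        self.schema = tuple(schema)
        self.specs = {v.name: v for v in self.schema}
        self.nodes = structure.nodes
        self.n = data.n_rows
        if self.n == 0:
            raise ValidationError("cannot fit parameters on an empty table")

        # discretisers for every continuous node (used when it conditions others)
        self.discretizers = {}
        self.values = {}
        for v in self.schema:
            if v.kind == CONTINUOUS:
                col = data.df[v.name].to_numpy(dtype=float)
                self.values[v.name] = col
                self.discretizers[v.name] = _quantile_edges(col, config.n_bins)

        # integer conditioning codes; -1 = unobserved
        self.codes = {}
        for v in self.schema:
            if v.name in self.latent_cards:
                self.codes[v.name] = np.full(self.n, -1, dtype=np.int64)
            elif v.kind == CATEGORICAL:
                lut = {s: i for i, s in enumerate(v.states)}
                col = data.df[v.name].to_numpy(dtype=object)
                self.codes[v.name] = np.array(
                    [lut[x] if not is_missing(x) else -1 for x in col], dtype=np.int64
                )
            else:
                col = self.values[v.name]
                c = np.searchsorted(self.discretizers[v.name], col, side="right")
                c[np.isnan(col)] = -1
                self.codes[v.name] = c

    def card(self, name: str) -> int:
        v = self.specs[name]
        return v.n_states if v.kind == CATEGORICAL else len(self.discretizers[name]) + 1

    def family(self, name: str):
        parents = self.structure.parents(name)
        cards = [self.card(p) for p in parents]
        return parents, cards, int(np.prod(cards, initial=1.0))


def fit_parameters(
    net_structure: NetworkStructure,
    data: TableData,
    em_config: EMConfig | None = None,
    latents: Mapping[str, int] | None = None,
) -> BayesNetwork:
    """Fit CPDs for *net_structure* from *data* by maximum likelihood.

    With complete data the categorical CPDs are (add-``smoothing``)
    empirical conditional frequencies and continuous CPDs are Gaussian
    mixtures fitted per parent configuration.  When the structure
    contains latent nodes (declare their cardinalities in *latents*) or
    the data contain missing cells, EM is run: the E-step enumerates the
    unobserved discrete configuration of each row (latent states, missing
    categorical states, and the quantile bin of missing continuous
    parents), and the observed-data log-likelihood — recorded in
    ``fit_info["loglik"]`` — is non-decreasing across iterations.

    Parent configurations never observed in the data fall back to the
    smoothing prior and are flagged in the CPD's ``smoothed`` mask and in
    ``fit_info["smoothed_configs"]``.
    """
    cfg = em_config or EMConfig()
    eng = _FitEngine(net_structure, data, cfg, latents)

    has_unobserved = any((eng.codes[n] < 0).any() for n in eng.nodes)
    if not has_unobserved:
        rng = np.random.default_rng(cfg.seed)
        net = _m_step(eng, _complete_weights(eng), rng, prev=None)
        net.fit_info["loglik"] = [_observed_loglik(eng, net)]
        return net

    # EM; with latents the likelihood is multimodal, so keep the best of
    # ``restarts`` seeded initialisations (restart r uses seed + r)
    best = None
    for r in range(cfg.restarts):
        rng = np.random.default_rng(cfg.seed + r)
        net = _m_step(eng, _complete_weights(eng, observed_only=True), rng, prev=None)
        _perturb_latent_cpds(eng, net, rng)
        trace = []
        for _ in range(cfg.max_iter):
            weights, ll = _e_step(eng, net)
            trace.append(ll)
            net = _m_step(eng, weights, rng, prev=net)
            if len(trace) >= 2 and trace[-1] - trace[-2] < cfg.tol * (abs(trace[-2]) + 1.0):
                break
        net.fit_info["loglik"] = trace
        if best is None or trace[-1] > best.fit_info["loglik"][-1]:
            best = net
    return best


def _perturb_latent_cpds(eng: _FitEngine, net: BayesNetwork, rng) -> None:
    """Break the label symmetry of hidden states before EM.

    With uniform initial CPDs every latent posterior is flat — a saddle
    point EM cannot leave; a small seeded multiplicative jitter on the
    latent-affected CPDs starts the climb.
    """
    affected = set(eng.latent_cards)
    for latent in eng.latent_cards:
        affected.update(eng.structure.children(latent))
    for n in sorted(affected):  # fixed order keeps rng use deterministic
        cpd = net.cpds[n]
        if isinstance(cpd, CategoricalCPD):
            jitter = rng.uniform(0.6, 1.4, size=cpd.table.shape)
            table = cpd.table * jitter
            cpd.table = table / table.sum(axis=1, keepdims=True)
        else:
            spread = np.sqrt(cpd.variances.mean())
            cpd.means = cpd.means + rng.normal(0.0, 0.15 * spread, size=cpd.means.shape)


def _complete_weights(eng: _FitEngine, observed_only: bool = False):
    """Degenerate 'posterior': unit weight on the observed configuration.

    With ``observed_only`` rows with unobserved cells contribute nothing
    for the affected families (used to initialise EM); latent codes are
    randomised later by the M-step smoothing prior.
    """
    out = {}
    for n in eng.nodes:
        parents, cards, _ = eng.family(n)
        cols = [eng.codes[p] for p in parents]
        ok = np.ones(eng.n, dtype=bool)
        for c in cols:
            if not observed_only:
                ok &= c >= 0
            # for EM initialisation, unobserved parents are clipped to
            # config 0 so child marginals seed the CPDs
        if eng.specs[n].kind == CATEGORICAL:
            ok &= eng.codes[n] >= 0
        else:
            ok &= ~np.isnan(eng.values[n])
        cfg_idx = (
            np.ravel_multi_index([c.clip(0) for c in cols], cards)
            if parents
            else np.zeros(eng.n, dtype=np.int64)
        )
        out[n] = [(np.flatnonzero(ok), cfg_idx[ok], np.ones(int(ok.sum())))]
    return out


def _m_step(eng: _FitEngine, weights, rng, prev: BayesNetwork | None) -> BayesNetwork:
    """Maximise CPD parameters against expected family counts.

    *weights* maps node -> list of ``(row_idx, config_idx, weight)``
    contributions (a complete pass yields one entry; EM yields one per
    enumerated configuration block).
    """
    cpds = {}
    smoothed_report = {}
    for n in eng.nodes:
        v = eng.specs[n]
        parents, cards, n_cfg = eng.family(n)
        if v.kind == CATEGORICAL:
            counts = np.zeros((n_cfg, v.n_states))
            for rows, cfg_idx, w, *state in weights[n]:
                st = state[0] if state else eng.codes[n][rows]
                np.add.at(counts, (cfg_idx, st), w)
            smoothed = counts.sum(axis=1) < 1e-9
            table = counts + eng.config.smoothing
            table /= table.sum(axis=1, keepdims=True)
            cpds[n] = CategoricalCPD(n, parents, table, smoothed=smoothed)
        else:
            vals_all, w_all, cfg_all = [], [], []
            for rows, cfg_idx, w, *_ in weights[n]:
                x = eng.values[n][rows]
                ok = ~np.isnan(x)
                vals_all.append(x[ok])
                w_all.append(np.broadcast_to(w, x.shape)[ok])
                cfg_all.append(cfg_idx[ok] if np.ndim(cfg_idx) else np.full(int(ok.sum()), cfg_idx))
            x = np.concatenate(vals_all) if vals_all else np.array([])
            w = np.concatenate(w_all) if w_all else np.array([])
            cfg_idx = np.concatenate(cfg_all) if cfg_all else np.array([], dtype=np.int64)
            if x.size == 0:
                raise ValidationError(f"no observed values to fit continuous node {n!r}")
            g_pi, g_mu, g_var = _fit_weighted_gmm(x, w, eng.config.n_mix, rng)
            k = eng.config.n_mix
            W = np.zeros((n_cfg, k))
            M = np.zeros((n_cfg, k))
            V = np.ones((n_cfg, k))
            smoothed = np.zeros(n_cfg, dtype=bool)
            for c in range(n_cfg):
                sel = cfg_idx == c
                wsel = w[sel]
                if wsel.sum() < 3 * eng.config.smoothing + 1e-9:
                    pi, mu, var = g_pi, g_mu, g_var
                    smoothed[c] = True
                else:
                    init = None
                    if prev is not None and isinstance(prev.cpds.get(n), GaussianMixtureCPD):
                        pc = prev.cpds[n]
                        live = pc.weights[c] > 0
                        init = (pc.weights[c][live], pc.means[c][live], pc.variances[c][live])
                    pi, mu, var = _fit_weighted_gmm(x[sel], wsel, k, rng, init=init)
                kk = pi.size
                W[c, :kk], M[c, :kk], V[c, :kk] = pi, mu, var
                if kk < k:  # pad with zero-weight copies of the first component
                    M[c, kk:], V[c, kk:] = mu[0], var[0]
            cpds[n] = GaussianMixtureCPD(n, parents, W, M, V, smoothed=smoothed)
        if cpds[n].smoothed is not None and cpds[n].smoothed.any():
            smoothed_report[n] = int(cpds[n].smoothed.sum())
    structure = eng.structure
    net = BayesNetwork(
        structure,
        cpds,
        eng.schema,
        latent=frozenset(eng.latent_cards),
        discretizers=dict(eng.discretizers),
    )
    net.fit_info["smoothed_configs"] = smoothed_report
    return net


def _row_patterns(eng: _FitEngine):
    """Group rows by their set of unobserved discrete variables."""
    needed = []
    children = {n: eng.structure.children(n) for n in eng.nodes}
    unobs_cols = {}
    for n in eng.nodes:
        v = eng.specs[n]
        miss = eng.codes[n] < 0
        if v.kind == CONTINUOUS:
            # a missing continuous value only needs enumeration of its bin
            # when it conditions some other node
            if not children[n]:
                miss = np.zeros(eng.n, dtype=bool)
        unobs_cols[n] = miss
    mat = np.column_stack([unobs_cols[n] for n in eng.nodes])
    # pattern id per row
    uniq, inv = np.unique(mat, axis=0, return_inverse=True)
    for pid in range(uniq.shape[0]):
        uvars = [eng.nodes[j] for j in np.flatnonzero(uniq[pid])]
        yield uvars, np.flatnonzero(inv == pid)


def _e_step(eng: _FitEngine, net: BayesNetwork):
    """Posterior weights over unobserved discrete configurations, per row group.

    Returns (weights, observed-data log-likelihood).
    """
    cfg = eng.config
    bin_mass = {
        n: net.cpds[n].bin_mass(eng.discretizers[n])
        for n in eng.nodes
        if eng.specs[n].kind == CONTINUOUS
    }
    weights = {n: [] for n in eng.nodes}
    total_ll = 0.0
    parents_of = {n: eng.family(n) for n in eng.nodes}

    for uvars, rows in _row_patterns(eng):
        nr = rows.size
        if not uvars:
            for n in eng.nodes:
                parents, cards, _ = parents_of[n]
                cfg_idx = _cfg_codes(eng, parents, cards, rows, {})
                weights[n].append((rows, cfg_idx, np.ones(nr)))
            total_ll += _group_loglik(eng, net, bin_mass, rows, {}, parents_of)
            continue
        # cap enumeration: hard-impute surplus unobserved vars (latents first to keep)
        uvars = sorted(uvars, key=lambda v: (v not in eng.latent_cards, v))
        kept, budget = [], 1
        hard = {}
        for v in uvars:
            c = eng.card(v)
            if budget * c <= cfg.max_enum:
                kept.append(v)
                budget *= c
            else:
                hard[v] = _mode_code(eng, v)
        configs = list(itertools.product(*[range(eng.card(v)) for v in kept]))
        logp = np.zeros((nr, len(configs)))
        for ci, assignment in enumerate(configs):
            a = dict(zip(kept, assignment))
            a.update(hard)
            logp[:, ci] = _group_loglik(
                eng, net, bin_mass, rows, a, parents_of, reduce=False
            )
        ll_rows = logsumexp(logp, axis=1)
        total_ll += float(ll_rows.sum())
        post = np.exp(logp - ll_rows[:, None])  # (nr, n_cfg)
        affected = set()
        for v in list(kept) + list(hard):
            affected.add(v)
            affected.update(eng.structure.children(v))
        for n in eng.nodes:
            parents, cards, _ = parents_of[n]
            if n not in affected:
                cfg_idx = _cfg_codes(eng, parents, cards, rows, {})
                weights[n].append((rows, cfg_idx, np.ones(nr)))
                continue
            for ci, assignment in enumerate(configs):
                a = dict(zip(kept, assignment))
                a.update(hard)
                cfg_idx = _cfg_codes(eng, parents, cards, rows, a)
                w = post[:, ci]
                if eng.specs[n].kind == CATEGORICAL:
                    st = eng.codes[n][rows].copy()
                    if n in a:
                        st[:] = a[n]
                    weights[n].append((rows, cfg_idx, w, st))
                else:
                    weights[n].append((rows, cfg_idx, w))
    return weights, total_ll


def _mode_code(eng: _FitEngine, name: str) -> int:
    c = eng.codes[name]
    obs = c[c >= 0]
    if obs.size == 0:
        return 0
    return int(np.bincount(obs, minlength=eng.card(name)).argmax())


def _cfg_codes(eng, parents, cards, rows, assignment):
    if not parents:
        return np.zeros(rows.size, dtype=np.int64)
    cols = []
    for p in parents:
        c = eng.codes[p][rows]
        if p in assignment:
            c = np.full(rows.size, assignment[p], dtype=np.int64)
        cols.append(c.clip(0))  # clipped values only occur for hard-imputed cells
    return np.ravel_multi_index(cols, cards)


def _group_loglik(eng, net, bin_mass, rows, assignment, parents_of, reduce=True):
    """Log joint of the rows under a (partial) assignment of unobserved vars."""
    out = np.zeros(rows.size)
    for n in eng.nodes:
        v = eng.specs[n]
        parents, cards, _ = parents_of[n]
        cfg_idx = _cfg_codes(eng, parents, cards, rows, assignment)
        cpd = net.cpds[n]
        if v.kind == CATEGORICAL:
            st = eng.codes[n][rows]
            if n in assignment:
                st = np.full(rows.size, assignment[n], dtype=np.int64)
            ok = st >= 0
            t = np.log(np.maximum(cpd.table[cfg_idx.clip(0), st.clip(0)], 1e-300))
            out += np.where(ok, t, 0.0)
        else:
            x = eng.values[n][rows]
            obs = ~np.isnan(x)
            if obs.any():
                contrib = np.zeros(rows.size)
                contrib[obs] = cpd.logpdf(cfg_idx[obs], x[obs])
                out += contrib
            if n in assignment:  # enumerated bin of a missing continuous parent
                mass = bin_mass[n][cfg_idx, assignment[n]]
                out += np.where(obs, 0.0, np.log(np.maximum(mass, 1e-300)))
    return float(out.sum()) if reduce else out


def _observed_loglik(eng: _FitEngine, net: BayesNetwork) -> float:
    _, ll = _e_step(eng, net)
    return ll


# ---------------------------------------------------------------------------
# structure learning


@dataclass(frozen=True)
class StructureConfig:
    """Controls for bootstrap structure learning.

    ``resamples`` bootstrap data sets are drawn (resample *i* uses
    ``seed + i``); a greedy BIC hill-climb with ``restarts`` random
    restarts runs on each; arc confidence is the fraction of resamples
    containing the arc in either orientation, the consensus orientation
    is the majority one, and arcs below ``confidence_threshold`` are
    dropped.  Search runs on at most ``max_rows`` rows (a uniform
    subsample) for tractability on large cohorts.
    """

    resamples: int = 10
    score: str = "bic"
    max_parents: int = 3
    restarts: int = 3
    confidence_threshold: float = 0.5
    seed: int = 0
    n_bins: int = 5
    max_rows: int = 20000

    def __post_init__(self):
        if self.resamples < 1:
            raise ValueError("resamples must be >= 1")
        if self.score != "bic":
            raise ValueError(f"unknown score {self.score!r}")


def learn_structure(data: TableData, config: StructureConfig | None = None) -> NetworkStructure:
    """Learn a consensus DAG with bootstrap arc confidences.

    Continuous columns are discretised into quantile bins for scoring;
    missing cells are completed by seeded draws from the column's
    observed empirical distribution before each search.  Constant columns
    are excluded with a warning.  The result is invariant to the row
    order of the input for a fixed seed (rows are canonically sorted
    before resampling).
    """
    cfg = config or StructureConfig()
    if len(data.variables) < 2:
        raise ValidationError("structure learning needs at least 2 variables")

    # canonical row order -> row-order invariance
    df = data.df.copy()
    order = df.astype(str).apply(tuple, axis=1).sort_values().index
    df = df.loc[order].reset_index(drop=True)

    names, codes_cols, cards = [], [], []
    isolated = []  # constant columns stay in the model as edgeless roots
    for v in data.variables:
        if v.kind == CATEGORICAL:
            lut = {s: i for i, s in enumerate(v.states)}
            col = df[v.name].to_numpy(dtype=object)
            c = np.array([lut[x] if not is_missing(x) else -1 for x in col], dtype=np.int64)
            card = v.n_states
        else:
            col = df[v.name].to_numpy(dtype=float)
            edges = _quantile_edges(col, cfg.n_bins)
            c = np.searchsorted(edges, col, side="right").astype(np.int64)
            c[np.isnan(col)] = -1
            card = len(edges) + 1
        obs = c[c >= 0]
        if obs.size == 0 or np.unique(obs).size < 2:
            warnings.warn(f"constant column {v.name!r} excluded from structure search")
            isolated.append(v.name)
            continue
        names.append(v.name)
        codes_cols.append(c)
        cards.append(card)
    if len(names) < 2:
        raise ValidationError("fewer than 2 non-constant variables for structure search")
    codes = np.column_stack(codes_cols)
    n = codes.shape[0]

    pair_counts: dict[tuple[str, str], int] = {}
    orient_counts: dict[tuple[str, str], int] = {}
    for b in range(cfg.resamples):
        rng = np.random.default_rng(cfg.seed + b)
        idx = rng.integers(0, n, size=min(n, cfg.max_rows))
        sample = codes[idx].copy()
        for j in range(sample.shape[1]):  # complete missing cells by marginal draws
            col = sample[:, j]
            miss = col < 0
            if miss.any():
                obs = col[~miss]
                col[miss] = rng.choice(obs, size=int(miss.sum()))
        edges = _hill_climb(sample, cards, cfg, rng, names)
        for u, v in edges:
            key = (u, v) if u < v else (v, u)
            pair_counts[key] = pair_counts.get(key, 0) + 1
            if (u, v) == key:
                orient_counts[key] = orient_counts.get(key, 0) + 1
            else:
                orient_counts.setdefault(key, 0)

    result_edges, conf = [], {}
    order_pairs = sorted(pair_counts, key=lambda k: (-pair_counts[k], k))
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for key in order_pairs:
        support = pair_counts[key] / cfg.resamples
        if support < cfg.confidence_threshold or support == 0:
            continue
        u, v = key
        fwd = orient_counts.get(key, 0)
        edge = (u, v) if fwd * 2 >= pair_counts[key] else (v, u)
        if nx.has_path(g, edge[1], edge[0]):
            edge = (edge[1], edge[0])  # flip rather than drop if consensus cycles
            if nx.has_path(g, edge[1], edge[0]):
                continue
        g.add_edge(*edge)
        result_edges.append(edge)
        conf[edge] = support
    return NetworkStructure(tuple(names) + tuple(isolated), frozenset(result_edges), conf)


def _bic_family(codes, cards, child, parents, cache, n):
    key = (child, parents)
    hit = cache.get(key)
    if hit is not None:
        return hit
    r = cards[child]
    if parents:
        pc = [cards[p] for p in parents]
        q = int(np.prod(pc))
        idx = np.ravel_multi_index([codes[:, p] for p in parents], pc) * r + codes[:, child]
        counts = np.bincount(idx, minlength=q * r).reshape(q, r)
    else:
        q = 1
        counts = np.bincount(codes[:, child], minlength=r)[None, :]
    nij = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * (np.log(counts) - np.log(nij)), 0.0).sum()
    score = ll - 0.5 * math.log(n) * (r - 1) * q
    cache[key] = score
    return score


def _hill_climb(codes, cards, cfg, rng, names):
    p = len(cards)
    n = codes.shape[0]
    cache: dict = {}

    def total(parent_sets):
        return sum(
            _bic_family(codes, cards, c, parent_sets[c], cache, n) for c in range(p)
        )

    best_edges, best_score = None, -np.inf
    for r in range(cfg.restarts):
        parent_sets = [() for _ in range(p)]
        g = nx.DiGraph()
        g.add_nodes_from(range(p))
        if r > 0:  # random restart: seed a few random edges
            for _ in range(p):
                u, v = rng.integers(0, p, 2)
                if u != v and len(parent_sets[v]) < cfg.max_parents and not nx.has_path(g, v, u) and not g.has_edge(u, v):
                    g.add_edge(u, v)
                    parent_sets[v] = tuple(sorted(parent_sets[v] + (u,)))
        while True:
            cur = [
                _bic_family(codes, cards, c, parent_sets[c], cache, n) for c in range(p)
            ]
            best_delta, best_move = 1e-9, None
            for u in range(p):
                for v in range(p):
                    if u == v:
                        continue
                    if g.has_edge(u, v):
                        # delete
                        new_pa = tuple(x for x in parent_sets[v] if x != u)
                        d = _bic_family(codes, cards, v, new_pa, cache, n) - cur[v]
                        if d > best_delta:
                            best_delta, best_move = d, ("del", u, v)
                        # reverse
                        if len(parent_sets[u]) < cfg.max_parents:
                            g.remove_edge(u, v)
                            cyclic = nx.has_path(g, u, v)
                            g.add_edge(u, v)
                            if not cyclic:
                                pa_u = tuple(sorted(parent_sets[u] + (v,)))
                                d = (
                                    _bic_family(codes, cards, v, new_pa, cache, n)
                                    - cur[v]
                                    + _bic_family(codes, cards, u, pa_u, cache, n)
                                    - cur[u]
                                )
                                if d > best_delta:
                                    best_delta, best_move = d, ("rev", u, v)
                    else:
                        if len(parent_sets[v]) >= cfg.max_parents:
                            continue
                        if nx.has_path(g, v, u):
                            continue
                        new_pa = tuple(sorted(parent_sets[v] + (u,)))
                        d = _bic_family(codes, cards, v, new_pa, cache, n) - cur[v]
                        if d > best_delta:
                            best_delta, best_move = d, ("add", u, v)
            if best_move is None:
                break
            op, u, v = best_move
            if op == "add":
                g.add_edge(u, v)
                parent_sets[v] = tuple(sorted(parent_sets[v] + (u,)))
            elif op == "del":
                g.remove_edge(u, v)
                parent_sets[v] = tuple(x for x in parent_sets[v] if x != u)
            else:
                g.remove_edge(u, v)
                g.add_edge(v, u)
                parent_sets[v] = tuple(x for x in parent_sets[v] if x != u)
                parent_sets[u] = tuple(sorted(parent_sets[u] + (v,)))
        score = total(parent_sets)
        if score > best_score + 1e-9:
            best_score = score
            best_edges = {(names[u], names[v]) for v in range(p) for u in parent_sets[v]}
    return best_edges or set()


# ---------------------------------------------------------------------------
# (de)serialisation used by schema_io


def network_to_dict(net: BayesNetwork) -> dict:
    cpds = {}
    for n, cpd in net.cpds.items():
        if isinstance(cpd, CategoricalCPD):
            cpds[n] = {"kind": "categorical", "parents": list(cpd.parents), "table": cpd.table.tolist()}
        else:
            cpds[n] = {
                "kind": "gaussian_mixture",
                "parents": list(cpd.parents),
                "weights": cpd.weights.tolist(),
                "means": cpd.means.tolist(),
                "variances": cpd.variances.tolist(),
            }
    return {
        "nodes": list(net.structure.nodes),
        "edges": [[p, c, net.structure.arc_confidence.get((p, c), 1.0)] for p, c in sorted(net.structure.edges)],
        "schema": [
            {
                "name": v.name,
                "kind": v.kind,
                "states": list(v.states),
                "units": v.units,
                "role": v.role,
                "missing_allowed": v.missing_allowed,
            }
            for v in net.schema
        ],
        "latent": sorted(net.latent),
        "discretizers": {k: list(map(float, v)) for k, v in net.discretizers.items()},
    } | {"cpds": cpds}


def network_from_dict(doc: dict) -> BayesNetwork:
    try:
        nodes = tuple(doc["nodes"])
        edges = frozenset((e[0], e[1]) for e in doc["edges"])
        conf = {(e[0], e[1]): float(e[2]) for e in doc["edges"]}
        structure = NetworkStructure(nodes, edges, conf)
        schema = tuple(
            VariableSpec(
                b["name"],
                b["kind"],
                tuple(b.get("states") or ()),
                b.get("units", ""),
                b.get("role", "independent"),
                bool(b.get("missing_allowed", True)),
            )
            for b in doc["schema"]
        )
        cpds = {}
        for n in nodes:
            if n not in doc["cpds"]:
                raise SchemaError(f"document lacks a CPD for node {n!r}")
            c = doc["cpds"][n]
            if c["kind"] == "categorical":
                cpds[n] = CategoricalCPD(n, tuple(c["parents"]), np.array(c["table"]))
            else:
                cpds[n] = GaussianMixtureCPD(
                    n,
                    tuple(c["parents"]),
                    np.array(c["weights"]),
                    np.array(c["means"]),
                    np.array(c["variances"]),
                )
        return BayesNetwork(
            structure,
            cpds,
            schema,
            latent=frozenset(doc.get("latent", ())),
            discretizers={k: np.asarray(v, float) for k, v in doc.get("discretizers", {}).items()},
        )
    except SchemaError:
        raise
    except Exception as e:  # malformed document
        raise SchemaError(f"malformed network document: {e}") from e
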