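"""Strategies for handling missing data inside the network.

Three approaches are supported, mirroring standard practice for
structurally missing (possibly MNAR) clinical data:

1. **deletion** — drop every record with any missing cell;
2. **Miss Nodes / Miss States** — make missingness part of the model:
   each categorical variable gains an extra ``"Miss State"`` category,
   and each continuous variable gains a paired binary indicator node
   (its "Miss Node", intended as a parent of the continuous node) so
   the network learns and reproduces the missingness pattern;
3. **latent variables** — a constraint-based search tolerant of hidden
   common causes proposes discrete latent parents over groups of
   observed variables; fitted by EM, these can absorb missing-not-at-
   random effects so the generator infers values instead of emitting
   sentinels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .bn_core import NetworkStructure
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
    "MISS_STATE",
    "MISS_NODE_SUFFIX",
    "LatentSpec",
    "LatentSearchConfig",
    "delete_missing",
    "augment_missing",
    "strip_missing_markers",
    "required_miss_arcs",
    "discover_latents",
    "attach_latents",
    "export_latent_report",
]

#: extra category appended to categorical variables
MISS_STATE = "Miss State"
#: suffix of the paired binary indicator of a continuous variable
MISS_NODE_SUFFIX = "__miss"
_OBSERVED, _MISSING = "observed", "missing"


@dataclass(frozen=True)
class LatentSpec:
    """A proposed discrete latent variable.

    ``children`` are the observed variables it points at (a latent is
    always a root); ``cardinality`` is the number of hidden states
    (``m >= 2``); ``support`` is the fraction of bootstrap resamples in
    which the proposal appeared.
    """

    name: str
    cardinality: int
    children: frozenset[str]
    support: float = 1.0

    def __post_init__(self):
        if self.cardinality < 2:
            raise ValueError(f"latent {self.name!r} needs cardinality >= 2")
        if not self.children:
            raise ValueError(f"latent {self.name!r} has no children")
        if not (0.0 <= self.support <= 1.0):
            raise ValueError(f"latent support {self.support} outside [0, 1]")
        object.__setattr__(self, "children", frozenset(self.children))


# ---------------------------------------------------------------------------
# deletion


def delete_missing(data: TableData) -> TableData:
    """Complete-case analysis: keep only rows with no missing cell."""
    keep = ~data.df.isna().any(axis=1)
    return TableData(data.variables, data.df[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Miss Nodes / Miss States


def augment_missing(
    schema: Sequence[VariableSpec], data: TableData
) -> tuple[tuple[VariableSpec, ...], TableData]:
    """Encode missingness into the variables themselves.

    Categorical variables gain the extra state :data:`MISS_STATE` and
    their sentinels become that state.  Each continuous variable gains a
    paired binary miss-node column (``<name>__miss``) recording
    observed/missing; its own missing cells stay ``NaN`` (a placeholder
    that parameter fitting excludes from continuous likelihoods).  The
    mapping is inverted exactly by :func:`strip_missing_markers`.
    """
    schema = tuple(schema)
    names = {v.name for v in schema}
    out_specs: list[VariableSpec] = []
    cols: dict[str, pd.Series] = {}
    for v in schema:
        if v.kind == CATEGORICAL:
            if MISS_STATE in v.states:
                raise SchemaError(f"variable {v.name!r} already declares {MISS_STATE!r}")
            out_specs.append(
                VariableSpec(v.name, CATEGORICAL, v.states + (MISS_STATE,), v.units, v.role, v.missing_allowed)
            )
            cols[v.name] = data.df[v.name].astype(object).where(~data.df[v.name].isna(), MISS_STATE)
        else:
            aux = v.name + MISS_NODE_SUFFIX
            if aux in names:
                raise SchemaError(f"auxiliary name {aux!r} collides with an existing variable")
            out_specs.append(v)
            cols[v.name] = data.df[v.name]
            out_specs.append(VariableSpec(aux, CATEGORICAL, (_OBSERVED, _MISSING)))
            cols[aux] = pd.Series(
                np.where(data.df[v.name].isna(), _MISSING, _OBSERVED), dtype=object
            )
    return tuple(out_specs), TableData(tuple(out_specs), pd.DataFrame(cols))


def strip_missing_markers(data: TableData, warn_conflicts: bool = False) -> TableData:
    """Invert :func:`augment_missing` on real or sampled augmented tables.

    ``Miss State`` categories and miss-node ``missing`` indicators become
    sentinels again and the auxiliary columns are dropped.  A row whose
    miss node says ``missing`` while a continuous value is present is
    resolved in favour of the miss node — the normal path for sampled
    tables, where the network draws a value that the miss node then
    discards.  Conflicts are counted and reported via a warning when
    *warn_conflicts* is set (useful when round-tripping real tables,
    where they indicate an inconsistency).
    """
    aux = {v.name for v in data.variables if v.name.endswith(MISS_NODE_SUFFIX)}
    out_specs: list[VariableSpec] = []
    cols = {}
    conflicts = 0
    for v in data.variables:
        if v.name in aux:
            continue
        if v.kind == CATEGORICAL:
            states = tuple(s for s in v.states if s != MISS_STATE)
            out_specs.append(VariableSpec(v.name, CATEGORICAL, states, v.units, v.role, v.missing_allowed))
            col = data.df[v.name].astype(object)
            cols[v.name] = col.where(col != MISS_STATE, np.nan)
        else:
            out_specs.append(v)
            col = data.df[v.name].astype(float).copy()
            miss_col = v.name + MISS_NODE_SUFFIX
            if miss_col in aux:
                miss = data.df[miss_col].to_numpy(dtype=object) == _MISSING
                conflicts += int((miss & ~np.isnan(col.to_numpy())).sum())
                col[miss] = np.nan
            cols[v.name] = col
    if conflicts and warn_conflicts:
        warnings.warn(f"{conflicts} continuous cells overridden to missing by their miss node")
    return TableData(tuple(out_specs), pd.DataFrame(cols))


def required_miss_arcs(schema: Sequence[VariableSpec]) -> list[tuple[str, str]]:
    """Arcs ``<var>__miss -> <var>`` every augmented network must contain."""
    names = {v.name for v in schema}
    return [
        (v.name, v.name[: -len(MISS_NODE_SUFFIX)])
        for v in schema
        if v.name.endswith(MISS_NODE_SUFFIX) and v.name[: -len(MISS_NODE_SUFFIX)] in names
    ]


# ---------------------------------------------------------------------------
# latent discovery


@dataclass(frozen=True)
class LatentSearchConfig:
    """Controls for the latent-adjacency search.

    The search runs on ``resamples`` bootstrap data sets; a variable pair
    is a confounding candidate when it is dependent marginally and stays
    dependent conditioned on every single other observed variable
    (tested by a G-statistic on discretised data at ``alpha``).
    Candidate pairs with support >= ``support_threshold`` across
    resamples are merged into connected clusters; each cluster becomes
    one latent of ``cardinality`` states.
    """

    resamples: int = 10
    support_threshold: float = 0.6
    max_latents: int = 10
    cardinality: int = 2
    alpha: float = 0.01
    n_bins: int = 5
    seed: int = 0
    max_rows: int = 20000


def _g_test(x: np.ndarray, y: np.ndarray, cx: int, cy: int) -> tuple[float, int]:
    """G (likelihood-ratio) independence statistic and df for coded pairs."""
    counts = np.bincount(x * cy + y, minlength=cx * cy).reshape(cx, cy).astype(float)
    n = counts.sum()
    if n == 0:
        return 0.0, 0
    rows = counts.sum(axis=1, keepdims=True)
    colt = counts.sum(axis=0, keepdims=True)
    expect = rows * colt / n
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 2.0 * np.where(counts > 0, counts * np.log(counts / expect), 0.0).sum()
    df = (np.count_nonzero(rows) - 1) * (np.count_nonzero(colt) - 1)
    return float(g), max(int(df), 0)


def _dependent(x, y, cx, cy, alpha, z=None, cz=None) -> bool:
    """True when the pair is dependent (optionally within strata of z)."""
    if z is None:
        g, df = _g_test(x, y, cx, cy)
    else:
        g, df = 0.0, 0
        for s in range(cz):
            sel = z == s
            if sel.sum() < 10:
                continue
            gs, dfs = _g_test(x[sel], y[sel], cx, cy)
            g += gs
            df += dfs
    if df <= 0:
        return False
    return chi2.sf(g, df) < alpha


def discover_latents(data: TableData, config: LatentSearchConfig | None = None) -> list[LatentSpec]:
    """Propose latent confounders robust across bootstrap resamples.

    Full constraint-based orientation is out of scope; the search keeps
    the conservative core — pairs whose dependence no single observed
    variable explains away — and aggregates them across resamples into
    clusters of variables sharing an inferred hidden cause.
    """
    cfg = config or LatentSearchConfig()
    if len(data.variables) < 3:
        raise ValidationError("latent search needs at least 3 variables")
    if cfg.resamples < 1:
        raise ValueError("resamples must be >= 1")

    names, codes_cols, cards = [], [], []
    for v in data.variables:
        if v.kind == CATEGORICAL:
            lut = {s: i for i, s in enumerate(v.states)}
            col = data.df[v.name].to_numpy(dtype=object)
            c = np.array([lut[x] if not is_missing(x) else -1 for x in col], dtype=np.int64)
            card = v.n_states
        else:
            col = data.df[v.name].to_numpy(dtype=float)
            obs = col[~np.isnan(col)]
            if obs.size == 0:
                continue
            edges = np.unique(np.quantile(obs, np.linspace(0, 1, cfg.n_bins + 1)[1:-1]))
            c = np.searchsorted(edges, col, side="right").astype(np.int64)
            c[np.isnan(col)] = -1
            card = len(edges) + 1
        obs = c[c >= 0]
        if obs.size and np.unique(obs).size >= 2:
            names.append(v.name)
            codes_cols.append(c)
            cards.append(card)
    codes = np.column_stack(codes_cols)
    p = len(names)
    n = codes.shape[0]

    pair_hits: dict[tuple[int, int], int] = {}
    for b in range(cfg.resamples):
        rng = np.random.default_rng(cfg.seed + b)
        idx = rng.integers(0, n, size=min(n, cfg.max_rows))
        sample = codes[idx]
        for i, j in itertools.combinations(range(p), 2):
            sel = (sample[:, i] >= 0) & (sample[:, j] >= 0)
            x, y = sample[sel, i], sample[sel, j]
            if not _dependent(x, y, cards[i], cards[j], cfg.alpha):
                continue
            shielded = False
            for k in range(p):
                if k in (i, j):
                    continue
                sel3 = sel & (sample[:, k] >= 0)
                if not _dependent(
                    sample[sel3, i],
                    sample[sel3, j],
                    cards[i],
                    cards[j],
                    cfg.alpha,
                    z=sample[sel3, k],
                    cz=cards[k],
                ):
                    shielded = True
                    break
            if not shielded:
                pair_hits[(i, j)] = pair_hits.get((i, j), 0) + 1

    kept = {
        pair: hits / cfg.resamples
        for pair, hits in pair_hits.items()
        if hits / cfg.resamples >= cfg.support_threshold
    }
    # connected components of kept pairs -> one latent per cluster
    adj: dict[int, set[int]] = {}
    for i, j in kept:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    seen: set[int] = set()
    clusters = []
    for start in sorted(adj):
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        supports = [s for pr, s in kept.items() if pr[0] in comp and pr[1] in comp]
        clusters.append((comp, float(np.mean(supports))))
    clusters.sort(key=lambda cs: (-cs[1], sorted(cs[0])))
    out = []
    for k, (comp, support) in enumerate(clusters[: cfg.max_latents], start=1):
        out.append(
            LatentSpec(
                f"L{k}",
                cfg.cardinality,
                frozenset(names[i] for i in comp),
                support=support,
            )
        )
    return out


def attach_latents(structure: NetworkStructure, latents: Sequence[LatentSpec]) -> NetworkStructure:
    """Add latent root nodes with arcs latent -> child.

    Parameters for the extended structure are subsequently fitted with
    :func:`synthcohort.bn_core.fit_parameters` (pass the latent
    cardinalities), which runs EM over the hidden states.
    """
    names = list(structure.nodes)
    edges = set(structure.edges)
    conf = dict(structure.arc_confidence)
    seen = set(names)
    for latent in latents:
        if latent.name in seen:
            raise SchemaError(f"duplicate latent id {latent.name!r}")
        missing = latent.children - seen
        if missing:
            raise SchemaError(f"latent {latent.name!r} points at undeclared nodes {sorted(missing)}")
        seen.add(latent.name)
        names.append(latent.name)
        for child in sorted(latent.children):
            edges.add((latent.name, child))
            conf[(latent.name, child)] = latent.support
    return NetworkStructure(tuple(names), frozenset(edges), conf)


def export_latent_report(latents: Sequence[LatentSpec], path) -> None:
    """Write discovered links, one ``"Lk" -> "child"`` line per arc."""
    from pathlib import Path

    lines = []
    for latent in latents:
        for child in sorted(latent.children):
            lines.append(f'"{latent.name}" -> "{child}"')
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
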