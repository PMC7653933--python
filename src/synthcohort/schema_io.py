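"""Cohort data model and file I/O.

A cohort is a rectangular table of mixed categorical/continuous patient
variables with an explicit missing marker.  The in-memory representation
wraps a :class:`pandas.DataFrame` (``NaN`` is the internal missing marker
for both kinds of column); on disk a cohort is an RFC-4180 CSV with a
header row and a reserved missing token (default ``"NA"``), and the
variable schema lives in a separate YAML document — types are never
inferred from the data, to avoid silent miscoding.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CATEGORICAL",
    "CONTINUOUS",
    "MISSING_TOKEN",
    "SchemaError",
    "ValidationError",
    "VariableSpec",
    "TableData",
    "is_missing",
    "read_schema",
    "write_schema",
    "read_table",
    "write_table",
    "serialize_network",
    "deserialize_network",
]

CATEGORICAL = "categorical"
CONTINUOUS = "continuous"

#: default on-disk missing token
MISSING_TOKEN = "NA"


class SchemaError(ValueError):
    """A table or document does not conform to its declared schema."""


class ValidationError(ValueError):
    """Cell-level data that violates the declared variable states.

    ``errors`` lists every offending ``(row, column, message)`` found, so
    callers can count and report all corruptions, not just the first.
    """

    def __init__(self, message: str, errors: list | None = None):
        super().__init__(message)
        self.errors = errors if errors is not None else [message]


def is_missing(value) -> bool:
    """True if *value* is the internal missing marker (``NaN``/``None``)."""
    return value is None or (isinstance(value, float) and math.isnan(value))


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one cohort variable.

    Parameters
    ----------
    name:
        Column identifier.
    kind:
        ``"categorical"`` or ``"continuous"``.
    states:
        Ordered state labels; required (non-empty, unique) for categorical
        variables and must be empty for continuous ones.  The missing
        marker is never a state.
    units:
        Free-text units, e.g. ``"mmHg"``.
    role:
        ``"independent"`` or ``"dependent"`` (the classification target).
    missing_allowed:
        Whether the variable may carry missing cells.
    """

    name: str
    kind: str
    states: tuple[str, ...] = ()
    units: str = ""
    role: str = "independent"
    missing_allowed: bool = True

    def __post_init__(self):
        if self.kind not in (CATEGORICAL, CONTINUOUS):
            raise SchemaError(f"unknown kind {self.kind!r} for variable {self.name!r}")
        if self.role not in ("independent", "dependent"):
            raise SchemaError(f"unknown role {self.role!r} for variable {self.name!r}")
        object.__setattr__(self, "states", tuple(str(s) for s in self.states))
        if self.kind == CATEGORICAL:
            if not self.states:
                raise SchemaError(f"categorical variable {self.name!r} declares no states")
            if len(set(self.states)) != len(self.states):
                raise SchemaError(f"duplicate states in variable {self.name!r}")
        elif self.states:
            raise SchemaError(f"continuous variable {self.name!r} must not declare states")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, value: str) -> int:
        try:
            return self.states.index(value)
        except ValueError:
            raise ValidationError(
                f"value {value!r} outside declared states of {self.name!r}"
            ) from None


def _check_schema(variables: Sequence[VariableSpec]) -> tuple[VariableSpec, ...]:
    variables = tuple(variables)
    names = [v.name for v in variables]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate variable names in schema")
    dependent = [v.name for v in variables if v.role == "dependent"]
    if len(dependent) > 1:
        raise SchemaError(f"more than one dependent variable: {dependent}")
    return variables


@dataclass
class TableData:
    """A validated cohort: schema plus records.

    ``df`` holds one column per declared variable, in schema order.
    Categorical columns are ``object`` dtype holding state labels (or
    ``NaN``); continuous columns are ``float64``.
    """

    variables: tuple[VariableSpec, ...]
    df: pd.DataFrame

    def __post_init__(self):
        self.variables = _check_schema(self.variables)
        self.df = _normalise_frame(self.variables, self.df)

    # -- convenience ---------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def spec(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def missing_mask(self) -> pd.DataFrame:
        return self.df.isna()

    def copy(self) -> "TableData":
        return TableData(self.variables, self.df.copy())

    def subset(self, names: Sequence[str]) -> "TableData":
        """Project onto *names*, in the order given."""
        by_name = {v.name: v for v in self.variables}
        keep = [by_name[n] for n in names if n in by_name]
        return TableData(tuple(keep), self.df[[v.name for v in keep]].copy())

    def equals(self, other: "TableData") -> bool:
        if self.variables != other.variables or self.n_rows != other.n_rows:
            return False
        for v in self.variables:
            a, b = self.df[v.name], other.df[v.name]
            if v.kind == CONTINUOUS:
                if not np.array_equal(a.to_numpy(), b.to_numpy(), equal_nan=True):
                    return False
            else:
                if not (a.fillna("\0") == b.fillna("\0")).all():
                    return False
        return True


def _normalise_frame(variables: Sequence[VariableSpec], df: pd.DataFrame) -> pd.DataFrame:
    for v in variables:
        if v.name not in df.columns:
            raise SchemaError(f"column {v.name!r} required by schema is absent")
    df = df[[v.name for v in variables]].reset_index(drop=True)
    out = {}
    errors: list[tuple[int, str, str]] = []
    for v in variables:
        col = df[v.name]
        if v.kind == CONTINUOUS:
            if col.dtype.kind in "fiu":
                arr = col.astype(float)
            else:
                # Python's float() is correctly rounded (pandas' fast string
                # parser is not), which the bit-faithful round trip relies on
                def _conv(x):
                    if is_missing(x):
                        return np.nan
                    try:
                        return float(x)
                    except (TypeError, ValueError):
                        return np.nan

                arr = col.map(_conv).astype(float)
            finite = np.isfinite(arr.to_numpy()) | np.isnan(arr.to_numpy())
            for i in np.flatnonzero(~finite):
                errors.append((int(i), v.name, f"non-finite value in {v.name!r} at row {i}"))
            out[v.name] = arr
        else:
            vals = col.astype(object).where(~col.isna(), np.nan)
            allowed = set(v.states)
            obj = vals.to_numpy(dtype=object)
            for i, x in enumerate(obj):
                if is_missing(x):
                    continue
                x = str(x)
                if x not in allowed:
                    errors.append(
                        (i, v.name, f"value {x!r} outside declared states of {v.name!r} at row {i}")
                    )
                obj[i] = x
            out[v.name] = pd.Series(obj, dtype=object)
    if errors:
        raise ValidationError(
            f"{len(errors)} invalid cells, first: {errors[0][2]}", errors=errors
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# schema documents


def write_schema(variables: Sequence[VariableSpec], path) -> None:
    """Write a schema as a YAML document (one block per variable)."""
    doc = [
        {
            "name": v.name,
            "kind": v.kind,
            "states": list(v.states),
            "units": v.units,
            "role": v.role,
            "missing_allowed": v.missing_allowed,
        }
        for v in _check_schema(variables)
    ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_schema(path) -> tuple[VariableSpec, ...]:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, list):
        raise SchemaError(f"schema document {path} is not a list of variable blocks")
    return _check_schema(
        VariableSpec(
            name=b["name"],
            kind=b["kind"],
            states=tuple(b.get("states") or ()),
            units=b.get("units", ""),
            role=b.get("role", "independent"),
            missing_allowed=bool(b.get("missing_allowed", True)),
        )
        for b in doc
    )


# ---------------------------------------------------------------------------
# cohort CSV


def read_table(path, schema: Sequence[VariableSpec], missing_token: str = MISSING_TOKEN) -> TableData:
    """Read a CSV cohort against *schema*.

    Cells equal to *missing_token* (and unparseable continuous cells) map
    to the internal missing marker; column order is normalised to schema
    order.  A column required by the schema but absent from the file is a
    :class:`SchemaError`; a categorical value outside the declared states
    is a :class:`ValidationError` carrying the row index.
    """
    schema = _check_schema(schema)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for v in schema:
        if v.name not in raw.columns:
            raise SchemaError(f"column {v.name!r} required by schema is absent from {path}")
    raw = raw.replace(missing_token, np.nan)
    return TableData(schema, raw)


def write_table(data: TableData, path, missing_token: str = MISSING_TOKEN) -> None:
    """Write a cohort CSV; ``read_table(write_table(x))`` round-trips exactly.

    Continuous values are written with 17 significant digits so the float
    round trip is bit-faithful.
    """
    cols = {}
    for v in data.variables:
        col = data.df[v.name]
        if v.kind == CONTINUOUS:
            cols[v.name] = [
                missing_token if math.isnan(x) else format(x, ".17g") for x in col.to_numpy()
            ]
        else:
            cols[v.name] = [missing_token if is_missing(x) else str(x) for x in col.to_numpy()]
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# network documents (JSON-shaped)


def serialize_network(net, path) -> None:
    """Write a Bayesian network (structure, arc confidences, CPDs) as JSON."""
    from . import bn_core  # local import: bn_core depends on this module

    doc = bn_core.network_to_dict(net)
    Path(path).write_text(json.dumps(doc, indent=1))


def deserialize_network(path):
    """Read a network document written by :func:`serialize_network`.

    Raises :class:`SchemaError` naming the offending node on a malformed
    document (declared cycle, missing CPD, ...).
    """
    from . import bn_core

    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"malformed network document {path}: {e}") from e
    return bn_core.network_from_dict(doc)
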