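"""CSV input/output with schema validation.

Every table the pipeline reads or writes has a registered schema: required
columns, dtype coercion, range checks, and uniqueness keys.  Violations are
reported with their row numbers rather than silently coerced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str  # int | float | str | bool
    required: bool = True
    minimum: float | None = None
    maximum: float | None = None
    allowed: tuple | None = None
    nullable: bool = False


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[ColumnSpec, ...]
    keys: tuple[str, ...] = ()

    def column(self, name: str) -> ColumnSpec:
        return next(c for c in self.columns if c.name == name)


def _cols(*specs) -> tuple[ColumnSpec, ...]:
    return tuple(specs)


SCHEMAS: dict[str, TableSchema] = {
    "population": TableSchema(
        "population",
        _cols(
            ColumnSpec("municipality_id", "str"),
            ColumnSpec("age_band", "str"),
            ColumnSpec("sex", "str", allowed=("F", "M")),
            ColumnSpec("year", "int"),
            ColumnSpec("population", "float", minimum=0),
        ),
        keys=("municipality_id", "age_band", "sex", "year"),
    ),
    "deaths": TableSchema(
        "deaths",
        _cols(
            ColumnSpec("municipality_id", "str"),
            ColumnSpec("age_band", "str"),
            ColumnSpec("sex", "str", allowed=("F", "M")),
            ColumnSpec("year", "int"),
            ColumnSpec("deaths", "int", minimum=0),
        ),
        keys=("municipality_id", "age_band", "sex", "year"),
    ),
    "ifr": TableSchema(
        "ifr",
        _cols(
            ColumnSpec("age_band", "str"),
            ColumnSpec("sex", "str", allowed=("F", "M")),
            ColumnSpec("ifr", "float", minimum=0.0, maximum=1.0),
        ),
        keys=("age_band", "sex"),
    ),
    "election_panel": TableSchema(
        "election_panel",
        _cols(
            ColumnSpec("municipality_id", "str"),
            ColumnSpec("county_id", "str"),
            ColumnSpec("incumbent_running", "bool"),
            ColumnSpec("share_2020", "float", minimum=0.0, maximum=100.0, nullable=True),
            ColumnSpec("share_2014", "float", minimum=0.0, maximum=100.0, nullable=True),
            ColumnSpec("share_2008", "float", minimum=0.0, maximum=100.0,
                       required=False, nullable=True),
            ColumnSpec("turnout_2014", "float", minimum=0.0, maximum=100.0),
            ColumnSpec("n_candidates_2020", "int", minimum=1),
            ColumnSpec("affiliation", "str", allowed=("left", "right", "other")),
        ),
        keys=("municipality_id",),
    ),
    "covariates": TableSchema(
        "covariates",
        _cols(
            ColumnSpec("municipality_id", "str"),
            ColumnSpec("county_id", "str"),
            ColumnSpec("pop_density", "float", minimum=0.0),
            ColumnSpec("male_female_ratio", "float", minimum=0.0),
            ColumnSpec("share_65plus", "float", minimum=0.0, maximum=1.0),
            ColumnSpec("share_immigrants", "float", minimum=0.0, maximum=1.0),
            ColumnSpec("share_blue_collar", "float", minimum=0.0, maximum=1.0),
            ColumnSpec("share_unemployed", "float", minimum=0.0, maximum=1.0),
            ColumnSpec("median_income", "float", minimum=0.0),
            ColumnSpec("share_junior_hs", "float", minimum=0.0, maximum=1.0),
            ColumnSpec("share_bachelor", "float", minimum=0.0, maximum=1.0),
            ColumnSpec("median_income_2014", "float", minimum=0.0, required=False),
            ColumnSpec("unemployment_2014", "float", minimum=0.0, maximum=1.0,
                       required=False),
            ColumnSpec("size_category", "str", required=False),
        ),
        keys=("municipality_id",),
    ),
    "survey_cells": TableSchema(
        "survey_cells",
        _cols(
            ColumnSpec("county_id", "str"),
            ColumnSpec("size_category", "str"),
            ColumnSpec("anxiety_mean", "float", minimum=0.0, maximum=1.0),
            ColumnSpec("n_respondents", "int", minimum=1),
        ),
        keys=("county_id", "size_category"),
    ),
    "prevalence_estimates": TableSchema(
        "prevalence_estimates",
        _cols(
            ColumnSpec("municipality_id", "str"),
            ColumnSpec("pi_hat", "float", minimum=0.0, maximum=1.0),
            ColumnSpec("ci_low", "float", minimum=0.0, maximum=1.0),
            ColumnSpec("ci_high", "float", minimum=0.0, maximum=1.0),
            ColumnSpec("expected_baseline_deaths_2020", "float", minimum=0.0,
                       required=False),
            ColumnSpec("boundary", "bool", required=False),
            ColumnSpec("converged", "bool", required=False),
        ),
        keys=("municipality_id",),
    ),
}

_KIND_DTYPE = {"int": "int64", "float": "float64", "str": "object", "bool": "bool"}


def validate_table(df: pd.DataFrame, schema_name: str) -> pd.DataFrame:
    """Coerce ``df`` to the named schema, raising :class:`SchemaError` with
    row numbers for every violation found."""
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema '{schema_name}'")
    schema = SCHEMAS[schema_name]
    problems: list[str] = []
    missing = [c.name for c in schema.columns if c.required and c.name not in df.columns]
    if missing:
        raise SchemaError(f"{schema.name}: missing required column(s) {missing}")

    out = df.copy()
    for spec in schema.columns:
        if spec.name not in out.columns:
            continue
        s = out[spec.name]
        if spec.kind in ("int", "float"):
            s = pd.to_numeric(s, errors="coerce")
            newly_bad = s.isna() & out[spec.name].notna()
            if newly_bad.any():
                problems.append(
                    f"column '{spec.name}': non-numeric values at rows "
                    f"{_rows(newly_bad)}"
                )
            if not spec.nullable and s.isna().any() and spec.required:
                nas = s.isna() & ~newly_bad
                if nas.any():
                    problems.append(
                        f"column '{spec.name}': missing values at rows {_rows(nas)}"
                    )
            if spec.minimum is not None:
                bad = s.notna() & (s < spec.minimum)
                if bad.any():
                    problems.append(
                        f"column '{spec.name}': values below {spec.minimum} "
                        f"at rows {_rows(bad)}"
                    )
            if spec.maximum is not None:
                bad = s.notna() & (s > spec.maximum)
                if bad.any():
                    problems.append(
                        f"column '{spec.name}': values above {spec.maximum} "
                        f"at rows {_rows(bad)}"
                    )
            if spec.kind == "int":
                nonint = s.notna() & (s != np.floor(s))
                if nonint.any():
                    problems.append(
                        f"column '{spec.name}': non-integer values at rows "
                        f"{_rows(nonint)}"
                    )
                elif not s.isna().any():
                    s = s.astype("int64")
        elif spec.kind == "bool":
            if s.dtype == object:
                s = s.map(
                    {"True": True, "False": False, True: True, False: False,
                     1: True, 0: False, "1": True, "0": False}
                )
            if s.isna().any():
                problems.append(
                    f"column '{spec.name}': non-boolean values at rows "
                    f"{_rows(s.isna())}"
                )
            else:
                s = s.astype(bool)
        else:
            s = s.astype(object).where(s.notna(), None)
        if spec.allowed is not None:
            bad = s.notna() & ~s.isin(spec.allowed)
            if bad.any():
                problems.append(
                    f"column '{spec.name}': values outside {spec.allowed} "
                    f"at rows {_rows(bad)}"
                )
        out[spec.name] = s

    if schema.keys:
        dup = out.duplicated(subset=list(schema.keys), keep=False)
        if dup.any():
            problems.append(
                f"duplicate {schema.keys} keys at rows {_rows(dup)}"
            )
    if problems:
        raise SchemaError(f"{schema.name}: " + "; ".join(problems))
    return out


def _rows(mask: pd.Series, limit: int = 10) -> str:
    rows = [int(i) for i in np.flatnonzero(mask.to_numpy())[:limit]]
    suffix = "..." if int(mask.sum()) > limit else ""
    return f"{rows}{suffix}"


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read a CSV and validate it against the named schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return validate_table(df, schema_name)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return path
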