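"""Cohort data model: per-subject records with diagnostic group labels.

Subjects belong to one of four diagnostic cells written in A+/-D+/- notation
(A = Alzheimer's disease present, D = type 2 diabetes present), which
decompose into two binary factors AD and T2DM.  Measured variables are
declared in a packaged data dictionary; steroid concentrations are in
nmol/L, clinical variables in their conventional units.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("A-D-", "A+D-", "A-D+", "A+D+")
META_COLUMNS = ("subject_id", "sex", "group", "age")


class CohortValidationError(ValueError):
    """Raised when a cohort file violates the data model."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one measured or derived variable."""

    name: str
    label: str
    unit: str
    block: str
    assay: str
    positive_only: bool = True
    transform: str = "identity"
    derived_from: tuple[str, ...] | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSpec":
        d = dict(d)
        df = d.get("derived_from")
        d["derived_from"] = tuple(df) if df else None
        return cls(**d)


def default_variables() -> list[VariableSpec]:
    """The packaged data dictionary (one entry per declared variable)."""
    text = resources.files("steroidopls.data").joinpath(
        "variables.json").read_text()
    specs = [VariableSpec.from_dict(d) for d in json.loads(text)]
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise CohortValidationError("duplicate names in data dictionary")
    for s in specs:
        if s.block == "steroid" and s.unit != "nmol/L":
            raise CohortValidationError(
                f"steroid variable {s.name} must be in nmol/L")
    return specs


def decompose_group(group: str) -> tuple[int, int]:
    """Split an A+/-D+/- label into binary (AD, T2DM) factors."""
    if group not in GROUPS:
        raise CohortValidationError(f"malformed group label {group!r}")
    return int(group[1] == "+"), int(group[3] == "+")


def compose_group(ad: int, t2dm: int) -> str:
    return f"A{'+' if ad else '-'}D{'+' if t2dm else '-'}"


class CohortTable:
    """A validated per-subject cohort table.

    Thin wrapper around a :class:`pandas.DataFrame` whose rows are subjects
    and whose columns are the metadata (`subject_id`, `sex`, `group`, `age`)
    plus declared variables.  Missing cells are NaN.
    """

    def __init__(self, df: pd.DataFrame, spec: Sequence[VariableSpec]):
        self.spec = list(spec)
        self._by_name = {s.name: s for s in self.spec}
        df = df.copy()
        self._validate(df)
        df["ad"] = [decompose_group(g)[0] for g in df["group"]]
        df["t2dm"] = [decompose_group(g)[1] for g in df["group"]]
        self.df = df.reset_index(drop=True)

    # -- construction / validation ------------------------------------
    def _validate(self, df: pd.DataFrame) -> None:
        for col in META_COLUMNS:
            if col not in df.columns:
                raise CohortValidationError(f"missing required column {col!r}")
        dup = df["subject_id"][df["subject_id"].duplicated()]
        if len(dup):
            raise CohortValidationError(
                f"duplicated subject_id(s): {sorted(set(dup))}")
        for i, g in enumerate(df["group"]):
            if g not in GROUPS:
                raise CohortValidationError(
                    f"row {i} (subject {df['subject_id'].iloc[i]!r}): "
                    f"malformed group label {g!r}")
        bad_sex = set(df["sex"]) - {"F", "M"}
        if bad_sex:
            raise CohortValidationError(f"invalid sex value(s) {bad_sex}")
        age = pd.to_numeric(df["age"], errors="coerce")
        if (age[age.notna()] <= 0).any():
            raise CohortValidationError("age must be positive")
        known = set(META_COLUMNS) | set(self._by_name) | {"ad", "t2dm"}
        unknown = [c for c in df.columns if c not in known]
        if unknown:
            raise CohortValidationError(
                f"unknown column(s) not in the data dictionary: {unknown}")
        for s in self.spec:
            if s.name in df.columns and s.positive_only:
                v = pd.to_numeric(df[s.name], errors="coerce")
                if (v[v.notna()] < 0).any():
                    raise CohortValidationError(
                        f"negative values in positive-only variable {s.name}")

    # -- basic accessors ----------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def variable_names(self) -> list[str]:
        return [s.name for s in self.spec if s.name in self.df.columns]

    def variable(self, name: str) -> VariableSpec:
        return self._by_name[name]

    def factor_counts(self) -> dict[str, int]:
        return {"AD": int(self.df["ad"].sum()),
                "T2DM": int(self.df["t2dm"].sum())}

    def group_sizes(self) -> dict[str, int]:
        counts = self.df["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}

    def subset(self, groups: Iterable[str]) -> "CohortTable":
        groups = list(groups)
        sub = self.df[self.df["group"].isin(groups)]
        return CohortTable(sub.drop(columns=["ad", "t2dm"]), self.spec)


def read_cohort(path, spec: Sequence[VariableSpec] | None = None,
                sep: str | None = None) -> CohortTable:
    """Read a CSV/TSV cohort file and validate it against the dictionary.

    ``""`` and ``NA`` cells are treated as missing.  The delimiter is
    sniffed from the extension unless given explicitly.
    """
    if spec is None:
        spec = default_variables()
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str},
                     na_values=["", "NA"], keep_default_na=False)
    return CohortTable(df, spec)


def write_cohort(table: CohortTable, path, sep: str | None = None) -> None:
    """Write a cohort table; round-trips through :func:`read_cohort`."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    out = table.df.drop(columns=["ad", "t2dm"])
    out.to_csv(path, sep=sep, index=False, na_rep="")


def split_by_sex(table: CohortTable) -> tuple[CohortTable, CohortTable]:
    """Partition into (women, men); exhaustive and disjoint."""
    if table.df["sex"].isna().any():
        raise CohortValidationError("sex must be populated for all rows")
    base = table.df.drop(columns=["ad", "t2dm"])
    women = CohortTable(base[base["sex"] == "F"], table.spec)
    men = CohortTable(base[base["sex"] == "M"], table.spec)
    return women, men


def _safe_div(num: pd.Series, den: pd.Series) -> pd.Series:
    """Elementwise ratio, NaN where the denominator is missing or <= 0."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = num / den
    return out.where(den > 0)


def derive_indices(table: CohortTable) -> CohortTable:
    """Compute the derived clinical indices where their inputs exist.

    BMI = weight/height^2 (kg, m); WHR = waist/hip; BAI = hip/height^1.5 - 18
    (hip cm, height m); HOMA R = glucose*insulin/22.5 and
    HOMA F = 20*insulin/(glucose - 3.5) (glucose mmol/L, insulin mIU/L);
    LDL cholesterol by the Friedewald formula TC - HDL - TG/2.2 (mmol/L);
    AST/ALT activity ratio.

    Already-populated cells are never overwritten, so the operation is
    idempotent and leaves measured columns untouched.  HOMA F is undefined
    at glucose <= 3.5 mmol/L: those cells stay missing and a warning is
    logged rather than raising.
    """
    df = table.df.drop(columns=["ad", "t2dm"]).copy()

    def col(name: str) -> pd.Series:
        if name in df.columns:
            return pd.to_numeric(df[name], errors="coerce")
        return pd.Series(np.nan, index=df.index)

    derived: dict[str, pd.Series] = {}
    derived["bmi"] = _safe_div(col("weight"), col("height") ** 2)
    derived["whr"] = _safe_div(col("waist_circumference"),
                               col("hip_circumference"))
    derived["bai"] = _safe_div(col("hip_circumference"),
                               col("height") ** 1.5) - 18.0
    derived["homa_r"] = col("glucose") * col("insulin") / 22.5
    gm = col("glucose") - 3.5
    n_undef = int(((col("glucose") <= 3.5) & col("insulin").notna()).sum())
    if n_undef:
        logger.warning(
            "HOMA F undefined for %d subject(s) with glucose <= 3.5 mmol/L; "
            "cells left missing", n_undef)
    derived["homa_f"] = _safe_div(20.0 * col("insulin"), gm)
    derived["ldl_cholesterol"] = (col("total_cholesterol")
                                  - col("hdl_cholesterol")
                                  - col("triacylglycerols") / 2.2)
    derived["ast_alt_ratio"] = _safe_div(col("ast"), col("alt"))

    for name, values in derived.items():
        if name in df.columns:
            existing = pd.to_numeric(df[name], errors="coerce")
            df[name] = existing.where(existing.notna(), values)
        else:
            df[name] = values
    return CohortTable(df, table.spec)
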