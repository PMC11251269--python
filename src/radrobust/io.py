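"""Long-format feature tables and their CSV round-trip.

The pipeline's universal input is a long-format table with one row per
(subject, feature, scheme, algorithm, parameter value): the value a radiomic
feature took for that subject when the image was processed with that
parameter setting. Tables are carried as a thin wrapper over a pandas
DataFrame so every downstream stage can rely on validated keys and explicit
completeness accounting — missing cells are reported, never imputed.

CSV format: UTF-8, comma-separated, header row
``subject_id,feature_name,scheme,algorithm,parameter_value,value``.
Floats are written with :data:`FLOAT_FORMAT` (17 significant digits), which
round-trips IEEE doubles losslessly through decimal text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .grids import Algorithm, ParameterGrid, Scheme

__all__ = [
    "FeatureTable",
    "CompletenessReport",
    "read_feature_table",
    "write_feature_table",
]

logger = logging.getLogger("radrobust")

COLUMNS = [
    "subject_id",
    "feature_name",
    "scheme",
    "algorithm",
    "parameter_value",
    "value",
]
KEY_COLUMNS = COLUMNS[:-1]

#: decimal float format that round-trips IEEE-754 doubles exactly
FLOAT_FORMAT = "%.17g"


@dataclass
class CompletenessReport:
    """Missing (subject, parameter) cells for one feature/scenario."""

    feature_name: str
    algorithm: str
    missing: list[tuple[str, float]] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.missing


class FeatureTable:
    """Validated long-format table of radiomic feature values.

    Parameters
    ----------
    data
        DataFrame with columns ``subject_id, feature_name, scheme,
        algorithm, parameter_value, value``. Keys (all columns but
        ``value``) must be unique.
    corrected
        Metadata flag marking tables produced by dependency correction;
        correcting an already-corrected table is refused downstream.
    """

    def __init__(self, data: pd.DataFrame, corrected: bool = False) -> None:
        missing_cols = [c for c in COLUMNS if c not in data.columns]
        if missing_cols:
            raise ValueError(f"feature table is missing columns {missing_cols}")
        df = data.loc[:, COLUMNS].copy()
        df["subject_id"] = df["subject_id"].astype(str)
        df["feature_name"] = df["feature_name"].astype(str)
        df["scheme"] = df["scheme"].astype(str)
        df["algorithm"] = df["algorithm"].astype(str)
        for col in ("parameter_value", "value"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
        if dup.any():
            rows = df.index[dup].tolist()
            key = df.loc[rows[0], KEY_COLUMNS].tolist()
            raise ValueError(
                f"duplicate (subject, feature, scheme, algorithm, parameter) "
                f"keys at rows {rows[:10]}: first duplicate key {key}"
            )
        if not np.isfinite(df["value"]).all():
            bad = df.index[~np.isfinite(df["value"])].tolist()
            raise ValueError(f"non-finite feature values at rows {bad[:10]}")
        self.data = df.reset_index(drop=True)
        self.corrected = bool(corrected)

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        a = self.data.sort_values(KEY_COLUMNS).reset_index(drop=True)
        b = other.data.sort_values(KEY_COLUMNS).reset_index(drop=True)
        return a.equals(b) and self.corrected == other.corrected

    @property
    def feature_names(self) -> list[str]:
        return sorted(self.data["feature_name"].unique())

    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject_id"].unique())

    def scenario(self, grid: ParameterGrid) -> "FeatureTable":
        """Rows belonging to one scenario, with parameters canonicalised.

        Parameter values are matched to grid values by exact equality after
        rounding to the grid's decimal precision (2 d.p. SUV, integer bins,
        1 d.p. mm), preventing silent nearest-match errors.
        """
        df = self.data
        sel = (df["scheme"] == grid.scheme.value) & (
            df["algorithm"] == grid.algorithm.value
        )
        sub = df.loc[sel].copy()
        sub["parameter_value"] = grid.canonicalise(
            sub["parameter_value"].to_numpy()
        )
        unknown = set(sub["parameter_value"]) - set(grid.values)
        if unknown:
            raise ValueError(
                f"parameter values {sorted(unknown)[:5]} are not on the "
                f"{grid.name} grid"
            )
        return FeatureTable(sub, corrected=self.corrected)

    def feature_slice(self, feature: str) -> pd.DataFrame:
        return self.data.loc[self.data["feature_name"] == feature]

    def completeness(
        self, grid: ParameterGrid, features: Iterable[str] | None = None
    ) -> list[CompletenessReport]:
        """Report every missing (subject, parameter) cell per feature.

        A complete scenario has a value for every subject at every grid
        parameter. Gaps are surfaced, never imputed.
        """
        sub = self.scenario(grid)
        reports = []
        feats = list(features) if features is not None else sub.feature_names
        subjects = sub.subjects
        for feat in feats:
            fs = sub.feature_slice(feat)
            have = set(zip(fs["subject_id"], fs["parameter_value"]))
            missing = [
                (s, v)
                for s in subjects
                for v in grid.values
                if (s, v) not in have
            ]
            reports.append(
                CompletenessReport(feat, grid.algorithm.value, missing)
            )
        return reports

    def require_complete(self, grid: ParameterGrid) -> "FeatureTable":
        """Return the scenario slice, erroring on any missing cell."""
        sub = self.scenario(grid)
        gaps = [r for r in sub.completeness(grid) if not r.complete]
        if gaps:
            detail = "; ".join(
                f"{r.feature_name}: {r.missing[:3]}" for r in gaps[:5]
            )
            raise ValueError(
                f"incomplete scenario {grid.name}: missing cells {detail}"
            )
        return sub

    def wide(self, feature: str, grid: ParameterGrid) -> pd.DataFrame:
        """Subjects x grid-values matrix for one feature (complete data)."""
        fs = self.scenario(grid).feature_slice(feature)
        mat = fs.pivot(
            index="subject_id", columns="parameter_value", values="value"
        )
        mat = mat.reindex(columns=list(grid.values))
        if mat.isna().any().any():
            missing = [
                (s, c)
                for s in mat.index
                for c in mat.columns
                if pd.isna(mat.at[s, c])
            ]
            raise ValueError(
                f"feature {feature!r} incomplete on {grid.name}: "
                f"missing {missing[:5]}"
            )
        return mat


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV (lossless decimal float text)."""
    df = table.data.copy()
    if table.corrected:
        df["corrected"] = True
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    logger.info(
        "wrote %d rows (%d features) to %s",
        len(df),
        df["feature_name"].nunique(),
        path,
    )


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature-table CSV, rejecting malformed rows with row numbers."""
    try:
        # round_trip parser: decimal text written by %.17g restores the
        # exact IEEE double
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    for col in ("parameter_value", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise ValueError(
                f"{path}: non-numeric {col!r} at file line(s) "
                f"{[int(i) + 2 for i in bad[:10]]}"
            )
        df[col] = coerced
    if df[COLUMNS[:-1] + ["value"]].isna().any().any():
        bad = df.index[df[COLUMNS].isna().any(axis=1)]
        raise ValueError(
            f"{path}: empty fields at file line(s) "
            f"{[int(i) + 2 for i in bad[:10]]}"
        )
    corrected = bool(df["corrected"].all()) if "corrected" in df.columns else False
    try:
        table = FeatureTable(df, corrected=corrected)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    logger.info("read %d rows from %s", len(table), path)
    return table
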