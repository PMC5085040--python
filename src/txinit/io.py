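"""Readers/writers for the study's table schemas.

Two CSV tables describe a study: ``conditions.csv`` (one row per
measurement condition: promoter, inducer concentrations, temperature) and
``intervals.csv`` (one row per observed inter-production interval, with
lower/upper bounds in seconds; an empty upper bound marks a right-censored
interval).  Durations are seconds, temperatures deg C, UTF-8, comma
separated, header row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

SCHEMA_VERSION = "1.0"

CONDITION_REQUIRED = ["condition_id"]
INTERVAL_REQUIRED = ["interval_id", "condition_id", "lb_s", "ub_s"]


class SchemaError(ValueError):
    """Raised when a study table violates the schema or its invariants."""


@dataclass
class StudyDataset:
    conditions: pd.DataFrame
    intervals: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def records_for(self, condition_id: str) -> pd.DataFrame:
        return self.intervals[self.intervals["condition_id"] == condition_id]

    def by_temperature(self, condition_ids=None) -> dict[float, pd.DataFrame]:
        """Group interval records by the temperature of their condition."""
        conds = self.conditions
        if condition_ids is not None:
            conds = conds[conds["condition_id"].isin(condition_ids)]
        out: dict[float, pd.DataFrame] = {}
        for T, sub in conds.groupby("temperature_C"):
            recs = self.intervals[self.intervals["condition_id"].isin(sub["condition_id"])]
            if len(recs):
                out[float(T)] = recs
        return out


def _validate(conditions: pd.DataFrame, intervals: pd.DataFrame) -> None:
    for col in CONDITION_REQUIRED:
        if col not in conditions.columns:
            raise SchemaError(f"conditions table missing column {col!r}")
    for col in INTERVAL_REQUIRED:
        if col not in intervals.columns:
            raise SchemaError(f"intervals table missing column {col!r}")
    if conditions["condition_id"].duplicated().any():
        dup = conditions.loc[conditions["condition_id"].duplicated(), "condition_id"].iloc[0]
        raise SchemaError(f"duplicate condition_id {dup!r}")
    known = set(conditions["condition_id"])
    bad = ~intervals["condition_id"].isin(known)
    if bad.any():
        row = intervals.index[bad][0]
        raise SchemaError(
            f"interval row {row} references unknown condition "
            f"{intervals.loc[row, 'condition_id']!r}"
        )
    lb = intervals["lb_s"].to_numpy(dtype=float)
    ub = intervals["ub_s"].to_numpy(dtype=float)
    malformed = (lb < 0) | (lb >= ub) | ~np.isfinite(lb)
    if malformed.any():
        row = intervals.index[np.asarray(malformed)][0]
        raise SchemaError(f"interval row {row} has malformed bounds "
                          f"({intervals.loc[row, 'lb_s']}, {intervals.loc[row, 'ub_s']})")
    if "prev_interval_id" in intervals.columns:
        ids = set(intervals["interval_id"])
        prev = intervals["prev_interval_id"].dropna()
        missing = ~prev.isin(ids)
        if missing.any():
            raise SchemaError(
                f"prev_interval_id {prev[missing].iloc[0]!r} does not exist"
            )


def read_study(conditions_path, intervals_path) -> StudyDataset:
    """Read and validate the conditions/intervals CSV pair.

    An empty ``ub_s`` cell is parsed as +inf (right-censored).
    """
    conditions = pd.read_csv(conditions_path)
    intervals = pd.read_csv(intervals_path)
    if "ub_s" in intervals.columns:
        intervals["ub_s"] = pd.to_numeric(intervals["ub_s"], errors="coerce").fillna(math.inf)
    _validate(conditions, intervals)
    return StudyDataset(
        conditions,
        intervals,
        provenance={
            "conditions_path": str(conditions_path),
            "intervals_path": str(intervals_path),
            "schema_version": SCHEMA_VERSION,
        },
    )


def write_study(dataset: StudyDataset, conditions_path, intervals_path) -> None:
    """Write the pair of CSVs; +inf upper bounds become empty cells."""
    _validate(dataset.conditions, dataset.intervals)
    dataset.conditions.to_csv(conditions_path, index=False)
    out = dataset.intervals.copy()
    out["ub_s"] = out["ub_s"].map(lambda v: "" if math.isinf(v) else v)
    out.to_csv(intervals_path, index=False)


def read_rnap_profile(path) -> "RNAPProfile":
    """Read a two-column (temperature_C, relative_abundance) CSV."""
    from .temperature import RNAPProfile

    df = pd.read_csv(path)
    if not {"temperature_C", "relative_abundance"}.issubset(df.columns):
        raise SchemaError("RNAP profile needs columns temperature_C, relative_abundance")
    return RNAPProfile(tuple(df["temperature_C"].astype(float)),
                       tuple(df["relative_abundance"].astype(float)))


def write_laws(law, path) -> None:
    """Serialize a TemperatureLaw as a CSV (parameter, order, A, B, C)."""
    frame = law.to_frame()
    frame["schema_version"] = SCHEMA_VERSION
    frame.to_csv(path, index=False)
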