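"""Trial-table interchange format.

Trial-wise spike counts travel as plain delimited text with one row per
trial: unit/region/subject metadata, the stimulus condition fields, a
trial index and the three window counts.  Orientation columns are empty
where a part is absent; ``anchor_orientation`` tags isolated parts with
the matched configuration's location.  Unknown extra columns are
preserved on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd

from .simulate import UnitRecording
from .stimuli import (
    CENTERINGS,
    INVERSIONS,
    ORIENTATIONS,
    PARTS,
    POSES,
    StimulusCondition,
)

SCHEMA_COLUMNS = [
    "unit_id", "region", "subject", "experiment", "pose", "part",
    "body_orientation", "head_orientation", "anchor_orientation",
    "centering", "inversion", "trial_index",
    "baseline100_count", "baseline200_count", "response_count",
]

_ORIENTATION_COLS = ("body_orientation", "head_orientation", "anchor_orientation")
_COUNT_COLS = ("baseline100_count", "baseline200_count", "response_count")


class TrialTableError(ValueError):
    """Schema violation in a trial table, naming the offending row/column."""


def units_to_table(units: Iterable[UnitRecording], experiment: str = "E1") -> pd.DataFrame:
    """Flatten unit recordings into the tabular trial format."""
    rows = []
    for u in units:
        for cond, counts in u.counts.items():
            for t in range(counts.shape[0]):
                rows.append({
                    "unit_id": u.unit_id, "region": u.region, "subject": u.subject,
                    "experiment": experiment, "pose": cond.pose, "part": cond.part,
                    "body_orientation": cond.body_orientation,
                    "head_orientation": cond.head_orientation,
                    "anchor_orientation": cond.anchor_orientation,
                    "centering": cond.centering, "inversion": cond.inversion,
                    "trial_index": t,
                    "baseline100_count": int(counts[t, 0]),
                    "baseline200_count": int(counts[t, 1]),
                    "response_count": int(counts[t, 2]),
                })
    df = pd.DataFrame(rows, columns=SCHEMA_COLUMNS)
    for col in _ORIENTATION_COLS:
        df[col] = df[col].astype("Int64")
    return df


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema, counts, orientations and key uniqueness in place."""
    for col in SCHEMA_COLUMNS:
        if col not in df.columns:
            raise TrialTableError(f"missing column {col!r}")
    for col in _COUNT_COLS:
        bad = df.index[(df[col] < 0) | (df[col] != df[col].astype(int))]
        if len(bad):
            raise TrialTableError(
                f"column {col!r} row {int(bad[0])}: counts must be nonnegative integers")
    for col in _ORIENTATION_COLS:
        vals = df[col].dropna()
        bad = vals.index[~vals.isin(ORIENTATIONS)]
        if len(bad):
            raise TrialTableError(
                f"column {col!r} row {int(bad[0])}: orientation "
                f"{df.loc[bad[0], col]} off the 45-degree grid")
    for col, allowed in (("pose", POSES), ("part", PARTS), ("centering", CENTERINGS),
                         ("inversion", INVERSIONS)):
        bad = df.index[~df[col].isin(allowed)]
        if len(bad):
            raise TrialTableError(
                f"column {col!r} row {int(bad[0])}: value {df.loc[bad[0], col]!r}")
    key_cols = ["unit_id", "pose", "part", "body_orientation", "head_orientation",
                "anchor_orientation", "centering", "inversion", "trial_index"]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        raise TrialTableError(
            f"duplicate (unit, condition, trial_index) at row {int(df.index[dup][0])}")
    return df


def write_trials(table: pd.DataFrame, path: str | Path) -> None:
    """Write a validated trial table as CSV."""
    validate_trials(table)
    table.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial table; unknown columns are preserved."""
    df = pd.read_csv(path, dtype={"unit_id": str, "subject": str, "region": str})
    for col in _ORIENTATION_COLS:
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return validate_trials(df)


def _row_condition(row) -> StimulusCondition:
    def opt(v):
        return None if pd.isna(v) else int(v)

    return StimulusCondition(
        pose=row.pose, part=row.part,
        body_orientation=opt(row.body_orientation),
        head_orientation=opt(row.head_orientation),
        centering=row.centering, inversion=row.inversion,
        anchor_orientation=opt(row.anchor_orientation),
    )


def table_to_units(df: pd.DataFrame) -> List[UnitRecording]:
    """Rebuild unit recordings (trials ordered by trial_index) from a table."""
    units: List[UnitRecording] = []
    for unit_id, udf in df.groupby("unit_id", sort=True):
        rec = UnitRecording(
            unit_id=str(unit_id),
            region=str(udf["region"].iloc[0]),
            subject=str(udf["subject"].iloc[0]),
        )
        cond_cols = ["pose", "part", "body_orientation", "head_orientation",
                     "anchor_orientation", "centering", "inversion"]
        for _, cdf in udf.groupby(cond_cols, dropna=False, sort=True):
            cdf = cdf.sort_values("trial_index")
            cond = _row_condition(cdf.iloc[0])
            rec.counts[cond] = cdf[list(_COUNT_COLS)].to_numpy(dtype=np.int64)
        units.append(rec)
    return units
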