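"""CSV/JSON/YAML input and output for the analysis pipeline.

Time courses travel as CSV with header ``time_days,csc_percent`` and an
optional ``ratio`` column; when both percentage and ratio are present they
must agree (the percentage implied by the ratio within printing precision),
otherwise the file is rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import TimeCourse
from .model import percent_to_ratio, ratio_to_percent

__all__ = ["read_timecourse", "write_timecourse", "write_json", "read_json"]


def read_timecourse(path) -> TimeCourse:
    """Read a time-course CSV; derive the missing percent/ratio column."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty time-course file") from exc
    if "time_days" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_days'")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no observations")
    times = df["time_days"].to_numpy(float)
    if np.unique(times).size != times.size:
        raise ValueError(f"{path}: duplicate times")
    has_percent = "csc_percent" in df.columns
    has_ratio = "ratio" in df.columns
    if not (has_percent or has_ratio):
        raise ValueError(f"{path}: need a 'csc_percent' or 'ratio' column")
    for col in [c for c in ("csc_percent", "ratio") if c in df.columns]:
        bad = df.index[df[col].isna()]
        if bad.size:
            raise ValueError(f"{path}: missing value in column {col!r}, "
                             f"row {int(bad[0])}")
    try:
        if has_percent and has_ratio:
            return TimeCourse(times=times,
                              ratio=df["ratio"].to_numpy(float),
                              percent=df["csc_percent"].to_numpy(float))
        if has_percent:
            return TimeCourse.from_percent(times,
                                           df["csc_percent"].to_numpy(float))
        return TimeCourse.from_ratio(times, df["ratio"].to_numpy(float))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_timecourse(path, tc: TimeCourse) -> None:
    """Write a time course in the same CSV dialect ``read_timecourse`` reads."""
    df = tc.to_frame()
    df.to_csv(path, index=False, float_format="%.6g")


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=False)
                          + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
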