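"""Tumor volume and tumor growth inhibition (TGI) from caliper tables.

Volume follows the modified-ellipsoid caliper formula V = L x W^2 / 2
(mm^3), with L the longer of the two measured dimensions.  TGI compares
group volumes on the last day measured in both groups:

    TGI (%) = (1 - V_T / V_C) x 100

where V_T and V_C are the treatment and control group volumes (mean
across animals by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ["animal", "group", "day", "length_mm", "width_mm"]


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper volume L x W^2 / 2 in mm^3; swaps (with a warning) if the
    stated width exceeds the stated length."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError(
            f"tumor dimensions must be positive, got L={length_mm}, W={width_mm}"
        )
    if width_mm > length_mm:
        warnings.warn(
            f"width {width_mm} > length {length_mm}; swapping to keep L >= W",
            stacklevel=2,
        )
        length_mm, width_mm = width_mm, length_mm
    return length_mm * width_mm**2 / 2.0


@dataclass
class TGIResult:
    treatment_group: str
    control_group: str
    day: float
    v_treatment: float
    v_control: float
    tgi: float
    n_treatment: int
    n_control: int

    def summary_row(self) -> dict:
        return {
            "treatment_group": self.treatment_group,
            "control_group": self.control_group,
            "day": self.day,
            "v_treatment": self.v_treatment,
            "v_control": self.v_control,
            "tgi": self.tgi,
            "n_treatment": self.n_treatment,
            "n_control": self.n_control,
        }


def _with_volumes(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(MEASUREMENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"measurement table missing columns: {sorted(missing)}")
    df = table.copy()
    df["volume"] = [
        tumor_volume(l, w) for l, w in zip(df["length_mm"], df["width_mm"])
    ]
    return df


def tgi(
    treatment: pd.DataFrame,
    control: pd.DataFrame,
    summary: str = "mean",
) -> TGIResult:
    """Tumor growth inhibition on the last day present in both groups.

    Animals without a measurement on that day are excluded (logged).
    ``summary`` selects the group summary statistic (mean or median).
    """
    if summary not in ("mean", "median"):
        raise ValueError("summary must be 'mean' or 'median'")
    t = _with_volumes(treatment)
    c = _with_volumes(control)
    common_days = set(t["day"]) & set(c["day"])
    if not common_days:
        raise ValueError("treatment and control share no measurement day")
    day = max(common_days)
    agg = np.mean if summary == "mean" else np.median
    t_day = t[t["day"] == day]
    c_day = c[c["day"] == day]
    for name, full, on_day in (("treatment", t, t_day), ("control", c, c_day)):
        n_missing = full["animal"].nunique() - on_day["animal"].nunique()
        if n_missing:
            logger.info(
                "%s group: %d animal(s) missing on day %s, excluded",
                name, n_missing, day,
            )
    v_t = float(agg(t_day["volume"]))
    v_c = float(agg(c_day["volume"]))
    if v_c == 0:
        raise ValueError("control group volume is zero on the evaluation day")
    return TGIResult(
        treatment_group=str(t_day["group"].iloc[0]),
        control_group=str(c_day["group"].iloc[0]),
        day=float(day),
        v_treatment=v_t,
        v_control=v_c,
        tgi=(1.0 - v_t / v_c) * 100.0,
        n_treatment=t_day["animal"].nunique(),
        n_control=c_day["animal"].nunique(),
    )


def tgi_table(
    measurements: pd.DataFrame, control_group: str, summary: str = "mean"
) -> pd.DataFrame:
    """TGI of every treatment group against the named control group."""
    groups = measurements["group"].unique()
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not in table")
    control = measurements[measurements["group"] == control_group]
    rows = []
    for g in groups:
        if g == control_group:
            continue
        res = tgi(measurements[measurements["group"] == g], control, summary=summary)
        rows.append(res.summary_row())
    return pd.DataFrame(rows)


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
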