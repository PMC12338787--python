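"""Readers and writers for dose-combination screening data.

The central container is :class:`CombinationMatrix`: one replicate of a
two-drug dose grid, including the zero-dose row/column (single agents) and
the zero/zero DMSO corner.  Activity is stored as percentage change from
the DMSO control: 0 means untreated growth, -100 means no viable cells.
Positive values (growth stimulation) can occur through noise.

Two on-disk layouts are supported, both plain CSV with '.' decimals:

* ``wide`` — first row holds the doses of drug B, first column the doses
  of drug A, cell [0, 0] is a label; the body is the activity grid.
* ``long`` — columns ``compound_a, dose_a, compound_b, dose_b, value,
  replicate`` (optionally ``cell_line``), one well per row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LONG_COLUMNS = ["compound_a", "dose_a", "compound_b", "dose_b", "value", "replicate"]

#: default tolerance (activity %) for the DMSO corner check
DMSO_CORNER_TOLERANCE = 25.0

#: relative tolerance used when comparing dose vectors across replicates
DOSE_RTOL = 1e-9


class PlateValidationError(ValueError):
    """Raised when a plate or matrix violates its structural contract."""


@dataclass
class CombinationMatrix:
    """One replicate of a drug-pair dose grid on the activity (%) scale.

    ``activity[i, j]`` is the well at ``doses_a[i]`` of compound A and
    ``doses_b[j]`` of compound B; ``activity[0, 0]`` is the DMSO corner.
    """

    compound_a_id: str
    compound_b_id: str
    cell_line_id: str
    replicate_id: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    activity: np.ndarray
    raw_luminescence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)

    def validate(self, corner_tolerance: float = DMSO_CORNER_TOLERANCE) -> None:
        for name, doses in (("a", self.doses_a), ("b", self.doses_b)):
            if doses.ndim != 1 or len(doses) < 2:
                raise PlateValidationError(f"dose axis {name} needs >= 2 doses")
            if not np.all(np.diff(doses) > 0):
                raise PlateValidationError(f"doses_{name} must be strictly ascending")
            n_zero = int(np.sum(doses == 0))
            if n_zero != 1:
                raise PlateValidationError(
                    f"axis {name}: expected exactly one zero dose, found {n_zero}"
                )
        if self.activity.shape != (len(self.doses_a), len(self.doses_b)):
            raise PlateValidationError(
                f"activity grid {self.activity.shape} does not match dose vectors "
                f"({len(self.doses_a)}, {len(self.doses_b)})"
            )
        if not np.all(np.isfinite(self.activity)):
            raise PlateValidationError("activity grid contains non-finite values")
        corner = self.activity[0, 0]
        if abs(corner) > corner_tolerance:
            raise PlateValidationError(
                f"DMSO corner activity {corner:.2f} exceeds tolerance "
                f"{corner_tolerance} (normalization suspect)"
            )

    def to_long(self) -> pd.DataFrame:
        """One row per well, columns as in the long CSV layout."""
        ii, jj = np.meshgrid(
            np.arange(len(self.doses_a)), np.arange(len(self.doses_b)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "compound_a": self.compound_a_id,
                "dose_a": self.doses_a[ii.ravel()],
                "compound_b": self.compound_b_id,
                "dose_b": self.doses_b[jj.ravel()],
                "value": self.activity.ravel(),
                "replicate": self.replicate_id,
                "cell_line": self.cell_line_id,
            }
        )


@dataclass
class CompoundMap:
    """Plate/well coordinates mapped to (compound id, concentration).

    Mirrors an acoustic-dispenser transfer log reduced to the generic
    columns ``plate, well, compound, conc``.
    """

    wells: dict[tuple[str, str], tuple[str, float]] = field(default_factory=dict)

    @classmethod
    def read(cls, path: str | Path) -> "CompoundMap":
        df = pd.read_csv(path, dtype={"plate": str, "well": str, "compound": str})
        required = {"plate", "well", "compound", "conc"}
        missing = required - set(df.columns)
        if missing:
            raise PlateValidationError(f"compound map missing columns: {sorted(missing)}")
        wells: dict[tuple[str, str], tuple[str, float]] = {}
        for row in df.itertuples(index=False):
            key = (row.plate, row.well)
            if key in wells:
                raise PlateValidationError(f"well {key} mapped twice in compound map")
            conc = float(row.conc)
            if conc < 0:
                raise PlateValidationError(f"well {key}: negative concentration {conc}")
            wells[key] = (row.compound, conc)
        return cls(wells=wells)

    def write(self, path: str | Path) -> None:
        rows = [
            {"plate": p, "well": w, "compound": c, "conc": conc}
            for (p, w), (c, conc) in self.wells.items()
        ]
        pd.DataFrame(rows, columns=["plate", "well", "compound", "conc"]).to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# matrix readers / writers
# ---------------------------------------------------------------------------


def read_matrix(
    path: str | Path,
    format: str = "wide",
    compound_a_id: str = "A",
    compound_b_id: str = "B",
    cell_line_id: str = "",
    replicate_id: str = "1",
) -> CombinationMatrix:
    """Read a single combination matrix from CSV.

    For ``wide`` files the compound/cell-line identities are not stored in
    the file and are taken from the keyword arguments.  For ``long`` files
    they are read from the columns; the file must contain exactly one
    (compound_a, compound_b, replicate) combination.
    """
    if format == "wide":
        return _read_wide(path, compound_a_id, compound_b_id, cell_line_id, replicate_id)
    if format == "long":
        return _read_long(path)
    raise ValueError(f"unknown format {format!r}; expected 'wide' or 'long'")


def _read_wide(path, compound_a_id, compound_b_id, cell_line_id, replicate_id):
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    doses_a = df.index.to_numpy(dtype=float)
    doses_b = df.columns.to_numpy(dtype=float)
    activity = df.to_numpy(dtype=float)
    order_a = np.argsort(doses_a)
    order_b = np.argsort(doses_b)
    mat = CombinationMatrix(
        compound_a_id=compound_a_id,
        compound_b_id=compound_b_id,
        cell_line_id=cell_line_id,
        replicate_id=replicate_id,
        doses_a=doses_a[order_a],
        doses_b=doses_b[order_b],
        activity=activity[np.ix_(order_a, order_b)],
    )
    _require_zero_axes(mat)
    mat.validate()
    return mat


def _read_long(path):
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise PlateValidationError(f"long CSV missing columns: {sorted(missing)}")
    for col in ("compound_a", "compound_b", "replicate"):
        if df[col].astype(str).nunique() > 1:
            raise PlateValidationError(
                f"long CSV mixes multiple values in column {col!r}; "
                "one matrix per file"
            )
    cell_line = str(df["cell_line"].iloc[0]) if "cell_line" in df.columns else ""
    dup = df.duplicated(subset=["dose_a", "dose_b"], keep=False)
    if dup.any():
        logger.warning(
            "%s: %d duplicate (dose_a, dose_b) wells averaged", path, int(dup.sum())
        )
        df = df.groupby(["dose_a", "dose_b"], as_index=False).agg(
            {
                "compound_a": "first",
                "compound_b": "first",
                "value": "mean",
                "replicate": "first",
            }
        )
    doses_a = np.sort(df["dose_a"].unique())
    doses_b = np.sort(df["dose_b"].unique())
    grid = df.pivot(index="dose_a", columns="dose_b", values="value")
    grid = grid.reindex(index=doses_a, columns=doses_b)
    if grid.isna().any().any():
        raise PlateValidationError(
            f"{path}: ragged grid — not every (dose_a, dose_b) pair is present"
        )
    mat = CombinationMatrix(
        compound_a_id=str(df["compound_a"].iloc[0]),
        compound_b_id=str(df["compound_b"].iloc[0]),
        cell_line_id=cell_line,
        replicate_id=str(df["replicate"].iloc[0]),
        doses_a=doses_a,
        doses_b=doses_b,
        activity=grid.to_numpy(dtype=float),
    )
    _require_zero_axes(mat)
    mat.validate()
    return mat


def _require_zero_axes(mat: CombinationMatrix) -> None:
    has_a = np.any(mat.doses_a == 0)
    has_b = np.any(mat.doses_b == 0)
    if not has_a and not has_b:
        raise PlateValidationError("missing control corner: no zero dose on either axis")
    if not has_a:
        raise PlateValidationError("missing zero-dose row for axis a (compound A)")
    if not has_b:
        raise PlateValidationError("missing zero-dose column for axis b (compound B)")


def write_matrix(matrix: CombinationMatrix, path: str | Path, format: str = "wide") -> None:
    if format == "wide":
        df = pd.DataFrame(
            matrix.activity,
            index=pd.Index(matrix.doses_a, name="dose_a\\dose_b"),
            columns=matrix.doses_b,
        )
        df.to_csv(path)
    elif format == "long":
        matrix.to_long().to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'wide' or 'long'")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_activity(
    raw_luminescence: np.ndarray, dmso_reference: float
) -> np.ndarray:
    """Percent change from the DMSO control: (raw / ref - 1) x 100.

    DMSO wells map to ~0, complete kill to -100.  ``dmso_reference`` is
    normally the mean of the plate's DMSO wells.
    """
    raw = np.asarray(raw_luminescence, dtype=float)
    if not dmso_reference > 0:
        raise ValueError(f"DMSO reference must be positive, got {dmso_reference}")
    if np.any(raw < 0):
        raise ValueError("raw luminescence contains negative values")
    return (raw / float(dmso_reference) - 1.0) * 100.0


def activity_to_inhibition(activity: np.ndarray) -> tuple[np.ndarray, int]:
    """Map activity (%) to fractional inhibition f = clamp(-activity/100, 0, 1).

    Returns the inhibition grid and the number of wells clamped at either
    bound (growth stimulation above 0 activity, or activity below -100).
    """
    act = np.asarray(activity, dtype=float)
    f_raw = -act / 100.0
    f = np.clip(f_raw, 0.0, 1.0)
    n_clamped = int(np.sum((f_raw < 0) | (f_raw > 1)))
    return f, n_clamped


# ---------------------------------------------------------------------------
# panel score tables (compounds x cell lines)
# ---------------------------------------------------------------------------


def write_score_table(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a compound x cell-line table of overall Bliss scores."""
    scores.to_csv(path, index_label="compound")


def read_score_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="compound")
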