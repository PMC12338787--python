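"""Bliss-independence synergy statistics for dose-combination matrices.

For two non-interacting drugs with fractional inhibitions fa and fb the
Bliss null expects combined inhibition fa + fb - fa*fb.  Synergy is the
excess of the observed combination inhibition over this expectation:

* ``bliss_score``    — 100 x mean excess over combination wells (both
  doses > 0), on the percentage-point scale of screening score tables.
* ``volume_average`` — the excess-over-Bliss volume statistic, defined
  here as the same per-well mean so that its cutoff is comparable across
  6x6 and 10x10 matrices; reported separately because hit calling treats
  it as its own criterion.
* ``median_ci``      — the median Chou-Talalay combination index over
  eligible combination wells.  The median-effect model
  fa/(1-fa) = (D/Dm)^m is fitted per single agent by ordinary least
  squares in logit-log coordinates, and each well contributes
  CI = d1/Dx1 + d2/Dx2 with Dx_i = Dm_i (f/(1-f))^(1/m_i).

Replicate matrices are scored separately and then averaged, giving the
overall Bliss score of a drug combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .plate_io import CombinationMatrix, activity_to_inhibition

logger = logging.getLogger(__name__)

#: inhibition window for wells entering the median-effect fit
MEDIAN_EFFECT_WINDOW = (0.01, 0.99)
#: inhibition window for wells entering the combination index
CI_WINDOW = (0.05, 0.95)


def bliss_expected(fa, fb):
    """Bliss-independent combined inhibition fa + fb - fa*fb.

    Accepts scalars or arrays; inputs must lie in [0, 1].
    """
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    if np.any((fa < 0) | (fa > 1)) or np.any((fb < 0) | (fb > 1)):
        raise ValueError("inhibition fractions must lie in [0, 1]")
    out = fa + fb - fa * fb
    return out if out.ndim else float(out)


@dataclass
class MedianEffectFit:
    """Chou-Talalay median-effect parameters for one single agent."""

    dm: float  # median-effect dose
    m: float  # slope
    r_squared: float
    n_points: int

    def dx(self, f: float) -> float:
        """Single-agent dose producing inhibition f under this fit."""
        return float(self.dm * (f / (1.0 - f)) ** (1.0 / self.m))


def fit_median_effect(
    doses: np.ndarray,
    inhibitions: np.ndarray,
    window: tuple[float, float] = MEDIAN_EFFECT_WINDOW,
) -> MedianEffectFit | None:
    """OLS of log(f/(1-f)) on log(d); returns None with < 3 eligible wells.

    Only wells with dose > 0 and inhibition strictly inside ``window``
    (default (0.01, 0.99)) enter the fit, keeping the logit finite.
    """
    doses = np.asarray(doses, dtype=float)
    f = np.asarray(inhibitions, dtype=float)
    mask = (doses > 0) & (f > window[0]) & (f < window[1])
    if int(mask.sum()) < 3:
        return None
    x = np.log(doses[mask])
    y = np.log(f[mask] / (1.0 - f[mask]))
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        return None  # non-monotone data; median-effect model inapplicable
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dm = float(np.exp(-intercept / slope))
    return MedianEffectFit(dm=dm, m=float(slope), r_squared=r2, n_points=int(mask.sum()))


def combination_index(
    d1: float,
    d2: float,
    observed_f: float,
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    window: tuple[float, float] = CI_WINDOW,
) -> float | None:
    """CI = d1/Dx1 + d2/Dx2 at one combination well; None if the observed
    effect falls outside the eligibility window (the well is skipped)."""
    if not (window[0] < observed_f < window[1]):
        return None
    return float(d1 / fit1.dx(observed_f) + d2 / fit2.dx(observed_f))


@dataclass
class SynergyResult:
    """Per-matrix Bliss statistics for one replicate."""

    compound_a_id: str
    compound_b_id: str
    cell_line_id: str
    replicate_id: str
    expected_inhibition: np.ndarray
    excess: np.ndarray  # observed - expected, fraction; full grid
    bliss_score: float  # 100 x mean excess over combination wells
    volume_average: float  # excess-over-Bliss volume statistic (same mean)
    median_ci: float | None
    ci_values: list[float] = field(default_factory=list)
    n_combo_wells: int = 0
    n_ci_wells: int = 0
    n_clamped: int = 0

    def summary_row(self) -> dict:
        return {
            "compound_a": self.compound_a_id,
            "compound_b": self.compound_b_id,
            "cell_line": self.cell_line_id,
            "replicate": self.replicate_id,
            "bliss_score": self.bliss_score,
            "volume_average": self.volume_average,
            "median_ci": self.median_ci,
            "n_combo_wells": self.n_combo_wells,
            "n_ci_wells": self.n_ci_wells,
        }


def score_matrix(
    matrix: CombinationMatrix,
    single_agent_source: str = "measured",
    curve_a=None,
    curve_b=None,
    ci_window: tuple[float, float] = CI_WINDOW,
) -> SynergyResult:
    """Score one replicate matrix against the Bliss null.

    Single-agent inhibitions come from the zero-dose row/column
    (``measured``, the default — robust to fit failures) or from fitted
    4PL curves (``fitted``, smoothing out single-agent noise).
    """
    matrix.validate()
    observed, n_clamped = activity_to_inhibition(matrix.activity)

    if single_agent_source == "measured":
        fa = observed[:, 0]
        fb = observed[0, :]
    elif single_agent_source == "fitted":
        if curve_a is None or curve_b is None or not (
            curve_a.converged and curve_b.converged
        ):
            raise ValueError("fitted single-agent source requires two converged curves")
        fa = np.clip(curve_a.inhibition(matrix.doses_a), 0.0, 1.0)
        fb = np.clip(curve_b.inhibition(matrix.doses_b), 0.0, 1.0)
    else:
        raise ValueError("single_agent_source must be 'measured' or 'fitted'")

    expected = bliss_expected(fa[:, None], fb[None, :])
    excess = observed - expected
    combo = (matrix.doses_a[:, None] > 0) & (matrix.doses_b[None, :] > 0)
    mean_excess = float(np.mean(excess[combo]))

    fit_a = fit_median_effect(matrix.doses_a, fa)
    fit_b = fit_median_effect(matrix.doses_b, fb)
    ci_values: list[float] = []
    if fit_a is not None and fit_b is not None:
        for i, j in zip(*np.where(combo)):
            ci = combination_index(
                matrix.doses_a[i], matrix.doses_b[j], observed[i, j],
                fit_a, fit_b, window=ci_window,
            )
            if ci is not None:
                ci_values.append(ci)
    median_ci = float(np.median(ci_values)) if ci_values else None

    return SynergyResult(
        compound_a_id=matrix.compound_a_id,
        compound_b_id=matrix.compound_b_id,
        cell_line_id=matrix.cell_line_id,
        replicate_id=matrix.replicate_id,
        expected_inhibition=expected,
        excess=excess,
        bliss_score=100.0 * mean_excess,
        volume_average=100.0 * mean_excess,
        median_ci=median_ci,
        ci_values=ci_values,
        n_combo_wells=int(combo.sum()),
        n_ci_wells=len(ci_values),
        n_clamped=n_clamped,
    )


@dataclass
class CombinationSummary:
    """Replicate-averaged statistics for one drug pair on one cell line."""

    compound_a_id: str
    compound_b_id: str
    cell_line_id: str
    n_replicates: int
    bliss_score: float  # overall Bliss score: mean across replicates
    volume_average: float
    median_ci: float | None  # pooled median of all per-well CI values
    n_ci_wells: int

    def summary_row(self) -> dict:
        return {
            "compound_a": self.compound_a_id,
            "compound_b": self.compound_b_id,
            "cell_line": self.cell_line_id,
            "n_replicates": self.n_replicates,
            "bliss_score": self.bliss_score,
            "volume_average": self.volume_average,
            "median_ci": self.median_ci,
            "n_ci_wells": self.n_ci_wells,
        }


def average_replicates(results: list[SynergyResult]) -> CombinationSummary:
    """Overall Bliss score: arithmetic mean of per-replicate scores; the
    median CI is pooled over all eligible wells of all replicates."""
    if not results:
        raise ValueError("need at least one replicate result")
    keys = {(r.compound_a_id, r.compound_b_id, r.cell_line_id) for r in results}
    if len(keys) > 1:
        raise ValueError(f"mixed drug pairs or cell lines in replicate set: {keys}")
    pooled_ci = [ci for r in results for ci in r.ci_values]
    return CombinationSummary(
        compound_a_id=results[0].compound_a_id,
        compound_b_id=results[0].compound_b_id,
        cell_line_id=results[0].cell_line_id,
        n_replicates=len(results),
        bliss_score=float(np.mean([r.bliss_score for r in results])),
        volume_average=float(np.mean([r.volume_average for r in results])),
        median_ci=float(np.median(pooled_ci)) if pooled_ci else None,
        n_ci_wells=len(pooled_ci),
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def excess_to_long(result: SynergyResult, matrix: CombinationMatrix) -> pd.DataFrame:
    """Well-level excess table (one row per combination well)."""
    rows = []
    for i, da in enumerate(matrix.doses_a):
        for j, db in enumerate(matrix.doses_b):
            rows.append(
                {
                    "compound_a": result.compound_a_id,
                    "dose_a": da,
                    "compound_b": result.compound_b_id,
                    "dose_b": db,
                    "replicate": result.replicate_id,
                    "expected_inhibition": result.expected_inhibition[i, j],
                    "excess": result.excess[i, j],
                    "is_combination": bool(da > 0 and db > 0),
                }
            )
    return pd.DataFrame(rows)


def write_summaries(
    summaries: list[CombinationSummary], path: str | Path
) -> None:
    pd.DataFrame([s.summary_row() for s in summaries]).to_csv(path, index=False)


def read_summaries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
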