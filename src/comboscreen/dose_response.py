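"""Four-parameter logistic (Hill) dose-response fitting.

The model on the activity (%) scale is::

    A(d) = Ainf + (A0 - Ainf) / (1 + (d / ec50)^h)

with A0 the zero-dose asymptote, Ainf the infinite-dose asymptote
(bounded below at -100%: a well cannot lose more than all of its cells),
ec50 the relative midpoint concentration and h > 0 the Hill slope.
Fractional inhibition is f(d) = -A(d)/100.

Fitting uses bounded nonlinear least squares with a single automated
outlier-rejection pass (standardized residual > 3, at most 20% of points
removed) followed by a refit.  Failure to converge is reported through
the ``converged`` flag, never as an exception.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

MIN_EFFECT_DEFAULT = -100.0

#: outlier pass: |standardized residual| threshold and max fraction removable
OUTLIER_Z = 3.0
OUTLIER_MAX_FRACTION = 0.20


def hill_activity(
    dose: np.ndarray | float, a0: float, ainf: float, ec50: float, hill: float
) -> np.ndarray | float:
    """Evaluate the 4PL on the activity scale; dose 0 returns ``a0``."""
    d = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(d > 0, (d / ec50) ** hill, 0.0)
    out = ainf + (a0 - ainf) / (1.0 + ratio)
    return out if out.ndim else float(out)


@dataclass
class Curve4PL:
    """A fitted four-parameter Hill curve for one compound on one cell line."""

    a0: float
    ainf: float
    ec50: float
    hill: float
    rss: float = np.nan
    n_points_used: int = 0
    outlier_indices: list[int] = field(default_factory=list)
    converged: bool = True
    flat: bool = False
    compound_id: str = ""
    cell_line_id: str = ""

    def activity(self, dose):
        return hill_activity(dose, self.a0, self.ainf, self.ec50, self.hill)

    def inhibition(self, dose):
        """Predicted fractional inhibition -A(d)/100 (not clamped)."""
        return -np.asarray(self.activity(dose)) / 100.0

    @property
    def inhibition_bounds(self) -> tuple[float, float]:
        """Attainable inhibition range (at dose 0, at infinite dose)."""
        return (-self.a0 / 100.0, -self.ainf / 100.0)

    def absolute_ic50(self) -> float:
        """Dose at activity -50% (absolute IC50); the reported ``ec50``
        field is the relative midpoint of the fit."""
        return invert_curve(self, 0.5)

    def to_dict(self) -> dict:
        return {
            "compound_id": self.compound_id,
            "cell_line_id": self.cell_line_id,
            "a0": self.a0,
            "ainf": self.ainf,
            "ec50": self.ec50,
            "hill": self.hill,
            "rss": self.rss,
            "n_points_used": self.n_points_used,
            "outlier_indices": list(self.outlier_indices),
            "converged": self.converged,
            "flat": self.flat,
        }


class FitInputError(ValueError):
    """Raised when a fit is requested on structurally insufficient data."""


def _residuals(params, doses, activities, log_scale=True):
    a0, ainf, log_ec50, log_hill = params
    pred = hill_activity(doses, a0, ainf, 10.0**log_ec50, 10.0**log_hill)
    return pred - activities


def fit_4pl(
    doses: np.ndarray,
    activities: np.ndarray,
    constraint_min_effect: float = MIN_EFFECT_DEFAULT,
    compound_id: str = "",
    cell_line_id: str = "",
) -> Curve4PL:
    """Fit the 4PL with the lower bound ``Ainf >= constraint_min_effect``.

    Replicate wells are fitted individually (not pre-averaged).  A single
    outlier pass removes points with absolute standardized residual > 3
    (capped at 20% of the points) and refits.  Optimizer failures return
    ``converged=False`` rather than raising.
    """
    doses = np.asarray(doses, dtype=float)
    activities = np.asarray(activities, dtype=float)
    if doses.shape != activities.shape or doses.ndim != 1:
        raise FitInputError("doses and activities must be matching 1-D arrays")
    if not np.all(np.isfinite(activities)) or not np.all(np.isfinite(doses)):
        raise FitInputError("non-finite dose or activity values")
    if np.any(doses < 0):
        raise FitInputError("negative doses")
    if len(doses) < 5:
        raise FitInputError(f"need at least 5 points for a 4-parameter fit, got {len(doses)}")
    n_distinct_nonzero = len(np.unique(doses[doses > 0]))
    if n_distinct_nonzero < 5:
        raise FitInputError(
            f"need >= 5 distinct nonzero doses, got {n_distinct_nonzero}"
        )

    def _make(a0, ainf, ec50, hill, **kw):
        return Curve4PL(
            a0=a0, ainf=ainf, ec50=ec50, hill=hill,
            compound_id=compound_id, cell_line_id=cell_line_id, **kw,
        )

    if np.ptp(activities) == 0:
        return _make(
            activities[0], activities[0], float(np.median(doses[doses > 0])), 1.0,
            rss=0.0, n_points_used=len(doses), converged=False, flat=True,
        )

    sol = _fit_once(doses, activities, constraint_min_effect)
    if sol is None:
        return _make(np.nan, np.nan, np.nan, np.nan, converged=False)

    # outlier pass: single round, residuals standardized by a robust
    # (median-absolute-deviation) scale so the outlier cannot mask itself
    resid = _residuals(sol.x, doses, activities)
    sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    if sigma == 0:
        dof = max(len(doses) - 4, 1)
        sigma = np.sqrt(np.sum(resid**2) / dof)
    outliers: list[int] = []
    if sigma > 0:
        z = np.abs(resid) / sigma
        # a residual below measurement resolution is never an outlier,
        # whatever its z-score (guards essentially perfect fits)
        candidates = np.where((z > OUTLIER_Z) & (np.abs(resid) > 1e-6))[0]
        max_remove = int(np.floor(OUTLIER_MAX_FRACTION * len(doses)))
        if len(candidates) > max_remove:
            order = np.argsort(z[candidates])[::-1]
            candidates = candidates[order[:max_remove]]
        outliers = sorted(int(i) for i in candidates)
    if outliers:
        keep = np.setdiff1d(np.arange(len(doses)), outliers)
        sol2 = _fit_once(doses[keep], activities[keep], constraint_min_effect)
        if sol2 is not None:
            sol = sol2
        n_used = len(keep)
    else:
        n_used = len(doses)

    a0, ainf, log_ec50, log_hill = sol.x
    return _make(
        float(a0), float(ainf), float(10.0**log_ec50), float(10.0**log_hill),
        rss=float(2 * sol.cost), n_points_used=n_used,
        outlier_indices=outliers, converged=True,
    )


def _fit_once(doses, activities, min_effect):
    """One bounded least-squares solve with multi-start over the Hill slope."""
    nz = doses[doses > 0]
    a0_start = float(np.mean(activities[doses == doses.min()]))
    ainf_start = float(max(np.mean(activities[doses == doses.max()]), min_effect))
    log_ec50_start = float(np.log10(np.sqrt(nz.min() * nz.max())))
    span = np.log10(nz.max()) - np.log10(nz.min())
    # slope kept inside the physiological range [0.01, 10]: steeper fits
    # are step functions that chase single bad wells
    lower = [-np.inf, min_effect, np.log10(nz.min()) - span, np.log10(1e-2)]
    upper = [np.inf, np.inf, np.log10(nz.max()) + span, np.log10(1e1)]

    best = None
    for hill_start in (1.0, 0.5, 2.0):
        x0 = np.array([
            a0_start,
            max(ainf_start, min_effect + 1e-9),
            log_ec50_start,
            np.log10(hill_start),
        ])
        try:
            with np.errstate(all="ignore"):
                sol = least_squares(
                    _residuals, x0, bounds=(lower, upper),
                    args=(doses, activities), method="trf",
                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                )
        except Exception:  # optimizer failure is a reportable state, not an error
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
            if sol.cost < 1e-12:  # already an essentially perfect fit
                break
    return best


def invert_curve(curve: Curve4PL, target_inhibition: float) -> float:
    """Closed-form dose at which predicted inhibition equals the target.

    The target must lie strictly between the curve's attainable bounds
    (-A0/100 at zero dose, -Ainf/100 at infinite dose).
    """
    f0, finf = curve.inhibition_bounds
    lo, hi = min(f0, finf), max(f0, finf)
    if not (lo < target_inhibition < hi):
        raise ValueError(
            f"target inhibition {target_inhibition} outside attainable open "
            f"range ({lo:.6g}, {hi:.6g})"
        )
    a_target = -100.0 * target_inhibition
    # solve Ainf + (A0 - Ainf)/(1 + x) = A_target for x = (d/ec50)^h
    x = (curve.a0 - a_target) / (a_target - curve.ainf)
    return float(curve.ec50 * x ** (1.0 / curve.hill))


@dataclass
class DoseSelection:
    doses: np.ndarray
    target_inhibitions: np.ndarray
    truncated: bool  # curve too shallow: attainable sub-range used


def select_combination_doses(
    curve: Curve4PL,
    k: int = 6,
    max_inhibition: float = 0.85,
    dilution_series: np.ndarray | None = None,
) -> DoseSelection:
    """Pick ``k`` doses whose predicted inhibitions step evenly up to
    ``max_inhibition`` (the screening convention: single-agent effects
    spanning 0-85%), optionally snapped to an available dilution series.
    """
    if not curve.converged:
        raise ValueError("cannot select doses from a non-converged curve")
    f0, finf = curve.inhibition_bounds
    lo, hi = min(f0, finf), max(f0, finf)
    truncated = False
    top = max_inhibition
    if hi <= max_inhibition:
        # attainable sub-range fallback for shallow curves
        top = lo + 0.95 * (hi - lo)
        truncated = True
        logger.warning(
            "curve %s reaches only %.3f inhibition; selecting doses up to %.3f",
            curve.compound_id, hi, top,
        )
    targets = top * np.arange(1, k + 1) / k
    doses = np.array([invert_curve(curve, t) for t in targets])
    if dilution_series is not None:
        series = np.sort(np.asarray(dilution_series, dtype=float))
        snapped = np.array(
            [series[np.argmin(np.abs(np.log(series) - np.log(d)))] for d in doses]
        )
        if not np.all(np.diff(snapped) > 0):
            raise ValueError(
                "snapping to the dilution series breaks strict monotonicity; "
                "provide a finer series"
            )
        doses = snapped
    return DoseSelection(doses=doses, target_inhibitions=targets, truncated=truncated)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def curves_to_csv(curves: list[Curve4PL], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame([c.to_dict() for c in curves]).to_csv(path, index=False)


def curves_to_json(curves: list[Curve4PL], path: str | Path) -> None:
    Path(path).write_text(json.dumps([c.to_dict() for c in curves], indent=2))
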