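"""Panel-level normalization of synergy scores and synergy hit calling.

Within each cell line, the distribution of compound-level overall Bliss
scores sets the normalization denominators: the median absolute
deviation (MAD) and its normal-consistent rescaling SDapprox =
1.4826 x MAD.  A compound x cell-line combination is flagged on four
criteria:

* c1 — score > 2 x MAD (permissive)
* c2 — score > 2 x SDapprox (stringent; implies c1 whenever MAD > 0)
* c3 — excess-over-Bliss volume average > 2
* c4 — median combination index <= 0.5

The default hit rule is the conjunction of all four (the most stringent
reading); an any-k rule is available, and every flag is reported so any
other combination is recoverable from the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: consistency constant: MAD of a normal sample estimates sigma / 1.4826
NORMAL_CONSISTENCY = 1.4826

THRESHOLD_NORM = 2.0  # cutoff for score / MAD and score / SDapprox
THRESHOLD_VOLUME = 2.0  # cutoff for the excess-over-Bliss volume average
THRESHOLD_CI = 0.5  # median CI at or below this counts as synergistic


def mad(values) -> float:
    """Unscaled median absolute deviation median(|x - median(x)|)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("MAD requires at least 2 values")
    return float(np.median(np.abs(x - np.median(x))))


def sd_approx(mad_value: float) -> float:
    """Normal approximation of the standard deviation from the MAD."""
    if mad_value < 0:
        raise ValueError("MAD must be nonnegative")
    return NORMAL_CONSISTENCY * mad_value


@dataclass
class PanelScores:
    """Overall Bliss scores for a compound panel across cell lines.

    ``table`` holds one row per (compound, cell line) with columns
    ``compound, cell_line, bliss_score, volume_average, median_ci``.
    """

    table: pd.DataFrame

    REQUIRED = ("compound", "cell_line", "bliss_score", "volume_average", "median_ci")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        counts = self.table.groupby("cell_line")["compound"].nunique()
        thin = counts[counts < 2]
        if not thin.empty:
            raise ValueError(
                "each cell line needs >= 2 compounds for the MAD: "
                f"{list(thin.index)}"
            )

    @classmethod
    def from_summaries(cls, summaries) -> "PanelScores":
        """Build from :class:`~comboscreen.synergy.CombinationSummary`
        objects, treating compound A as the panel compound."""
        rows = [
            {
                "compound": s.compound_a_id,
                "cell_line": s.cell_line_id,
                "bliss_score": s.bliss_score,
                "volume_average": s.volume_average,
                "median_ci": s.median_ci,
            }
            for s in summaries
        ]
        return cls(pd.DataFrame(rows))

    def score_matrix(self) -> pd.DataFrame:
        """Compound x cell-line wide table of overall Bliss scores."""
        return self.table.pivot(
            index="compound", columns="cell_line", values="bliss_score"
        )


@dataclass
class HitReport:
    """Per-combination criterion flags with audit columns.

    ``table`` columns: compound, cell_line, bliss_score, volume_average,
    median_ci, mad, sd_approx, norm_mad, norm_sd, c1..c4, degenerate_mad,
    is_hit.
    """

    table: pd.DataFrame
    rule: str

    def hits(self) -> pd.DataFrame:
        return self.table[self.table["is_hit"]]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_markdown(self) -> str:
        """Summary ranked by the MAD-normalized score."""
        cols = ["compound", "cell_line", "bliss_score", "norm_mad", "norm_sd",
                "volume_average", "median_ci", "is_hit"]
        ranked = self.table.sort_values("norm_mad", ascending=False)[cols]
        return ranked.to_markdown(index=False, floatfmt=".3g")


def call_hits(
    panel: PanelScores,
    rule: str = "all_four",
    k: int | None = None,
    normalization_axis: str = "cell_line",
    threshold_norm: float = THRESHOLD_NORM,
    threshold_volume: float = THRESHOLD_VOLUME,
    threshold_ci: float = THRESHOLD_CI,
) -> HitReport:
    """Apply the four-criterion synergy hit classifier to a score panel.

    Normalization denominators are computed per ``normalization_axis``
    (default: the MAD of compound scores within each cell line).  A zero
    MAD makes the normalized scores undefined: c1/c2 evaluate False and
    the row is flagged ``degenerate_mad``.
    """
    if rule not in ("all_four", "any_k"):
        raise ValueError(f"unknown rule {rule!r}")
    if rule == "any_k" and not (k and 1 <= k <= 4):
        raise ValueError("rule 'any_k' needs k in 1..4")
    if normalization_axis not in ("cell_line", "compound"):
        raise ValueError("normalization_axis must be 'cell_line' or 'compound'")

    df = panel.table.copy()
    mads = df.groupby(normalization_axis)["bliss_score"].transform(
        lambda s: mad(s.to_numpy())
    )
    df["mad"] = mads
    df["sd_approx"] = sd_approx(1.0) * mads
    degenerate = df["mad"] == 0
    if degenerate.any():
        logger.warning(
            "MAD = 0 for %d %s group(s); normalized criteria undefined there",
            df.loc[degenerate, normalization_axis].nunique(), normalization_axis,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        df["norm_mad"] = np.where(degenerate, np.nan, df["bliss_score"] / df["mad"])
        df["norm_sd"] = np.where(degenerate, np.nan, df["bliss_score"] / df["sd_approx"])
    df["degenerate_mad"] = degenerate
    df["c1"] = (df["norm_mad"] > threshold_norm).fillna(False) & ~degenerate
    df["c2"] = (df["norm_sd"] > threshold_norm).fillna(False) & ~degenerate
    df["c3"] = df["volume_average"] > threshold_volume
    df["c4"] = df["median_ci"].notna() & (df["median_ci"] <= threshold_ci)
    flags = df[["c1", "c2", "c3", "c4"]]
    if rule == "all_four":
        df["is_hit"] = flags.all(axis=1)
    else:
        df["is_hit"] = flags.sum(axis=1) >= k
    return HitReport(table=df, rule=rule)
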