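"""Rank-based single-sample scoring of a bidirectional EMT gene signature.

Each sample is scored independently from the ranks of its expression
values (input convention: log2[FPKM + 0.01], though any monotone scale
gives identical scores).  For a signature with a mesenchymal (up) set of
size k_M and an epithelial (down) set of size k_E among n measured genes:

* all n genes are ranked ascending (ties get average ranks);
* the up-set score normalizes the mean rank of the mesenchymal genes to
  [-0.5, 0.5] between its theoretical extremes, min_mean = (k+1)/2 and
  max_mean = n - (k-1)/2;
* the down-set score applies the same normalization to reversed ranks
  (n + 1 - rank) of the epithelial genes;
* the sample score is their sum, in [-1, 1], higher = more mesenchymal.

A sample is classified mesenchymal when its score is greater than or
equal to the classification threshold (default -0.05, a pan-cancer
median score; the boundary itself counts as mesenchymal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: default classification threshold (pan-cancer median signature score)
DEFAULT_THRESHOLD = -0.05

#: minimum fraction of each direction's genes that must be measured
MIN_PRESENT_FRACTION = 0.5

EPITHELIAL = "epithelial"
MESENCHYMAL = "mesenchymal"

_DIRECTION_ALIASES = {
    "e": EPITHELIAL, "epithelial": EPITHELIAL,
    "m": MESENCHYMAL, "mesenchymal": MESENCHYMAL,
}


@dataclass
class EMTSignature:
    """Gene sets marking the epithelial and mesenchymal states."""

    epithelial: list[str]
    mesenchymal: list[str]

    def __post_init__(self) -> None:
        if not self.epithelial or not self.mesenchymal:
            raise ValueError("both signature directions must be non-empty")
        overlap = set(self.epithelial) & set(self.mesenchymal)
        if overlap:
            raise ValueError(f"genes in both directions: {sorted(overlap)}")

    def __len__(self) -> int:
        return len(self.epithelial) + len(self.mesenchymal)

    @classmethod
    def read(cls, path: str | Path) -> "EMTSignature":
        """Read a two-column CSV ``gene, direction`` (direction E|M or
        epithelial|mesenchymal)."""
        df = pd.read_csv(path)
        missing = {"gene", "direction"} - set(df.columns)
        if missing:
            raise ValueError(f"signature file missing columns: {sorted(missing)}")
        eps, mes = [], []
        for row in df.itertuples(index=False):
            direction = _DIRECTION_ALIASES.get(str(row.direction).strip().lower())
            if direction is None:
                raise ValueError(f"unknown direction {row.direction!r} for {row.gene}")
            (eps if direction == EPITHELIAL else mes).append(str(row.gene))
        return cls(epithelial=eps, mesenchymal=mes)

    def write(self, path: str | Path) -> None:
        rows = [{"gene": g, "direction": "E"} for g in self.epithelial]
        rows += [{"gene": g, "direction": "M"} for g in self.mesenchymal]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class EMTResult:
    sample_id: str
    score: float
    phenotype: str  # epithelial | mesenchymal
    threshold: float
    coverage: float  # fraction of signature genes present in the matrix


def _normalized_set_score(ranks: np.ndarray, member_mask: np.ndarray) -> float:
    """Mean rank of the member set, normalized to [-0.5, 0.5] between its
    theoretical minimum (k+1)/2 and maximum n - (k-1)/2."""
    n = len(ranks)
    k = int(member_mask.sum())
    mean_rank = float(ranks[member_mask].mean())
    min_mean = (k + 1) / 2.0
    max_mean = n - (k - 1) / 2.0
    return (mean_rank - min_mean) / (max_mean - min_mean) - 0.5


def score_sample(
    expression: pd.Series,
    signature: EMTSignature,
    min_present_fraction: float = MIN_PRESENT_FRACTION,
) -> tuple[float, float]:
    """Score one sample; returns (score, signature coverage fraction).

    Raises if fewer than ``min_present_fraction`` of either direction's
    genes are measured, naming the missing genes.
    """
    genes = expression.index
    present_e = [g for g in signature.epithelial if g in genes]
    present_m = [g for g in signature.mesenchymal if g in genes]
    for direction, present, full in (
        (EPITHELIAL, present_e, signature.epithelial),
        (MESENCHYMAL, present_m, signature.mesenchymal),
    ):
        if len(present) < min_present_fraction * len(full):
            missing = sorted(set(full) - set(present))
            raise ValueError(
                f"only {len(present)}/{len(full)} {direction} signature genes "
                f"measured; missing: {missing}"
            )
    values = expression.to_numpy(dtype=float)
    ranks = rankdata(values, method="average")
    pos = {g: i for i, g in enumerate(genes)}
    mask_m = np.zeros(len(genes), dtype=bool)
    mask_m[[pos[g] for g in present_m]] = True
    mask_e = np.zeros(len(genes), dtype=bool)
    mask_e[[pos[g] for g in present_e]] = True

    s_up = _normalized_set_score(ranks, mask_m)
    s_down = _normalized_set_score(len(ranks) + 1 - ranks, mask_e)
    coverage = (len(present_e) + len(present_m)) / len(signature)
    return s_up + s_down, coverage


def classify(score: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Mesenchymal iff score >= threshold (boundary inclusive), else
    epithelial."""
    return MESENCHYMAL if score >= threshold else EPITHELIAL


def score_matrix_emt(
    matrix: pd.DataFrame,
    signature: EMTSignature,
    threshold: float = DEFAULT_THRESHOLD,
    min_present_fraction: float = MIN_PRESENT_FRACTION,
) -> tuple[list[EMTResult], list[str]]:
    """Score every sample (column) of a gene x sample expression matrix.

    Returns the per-sample results plus the sample ordering from lowest
    (most epithelial) to highest (most mesenchymal) score, the
    convention used for heatmap-style displays.
    """
    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in expression matrix: {dups}")
    if len(matrix.index) < len(signature) + 1:
        raise ValueError(
            f"matrix has {len(matrix.index)} genes; need more than the "
            f"signature size {len(signature)}"
        )
    results = []
    for sample in matrix.columns:
        score, coverage = score_sample(
            matrix[sample], signature, min_present_fraction=min_present_fraction
        )
        results.append(
            EMTResult(
                sample_id=str(sample),
                score=score,
                phenotype=classify(score, threshold),
                threshold=threshold,
                coverage=coverage,
            )
        )
    ordering = [r.sample_id for r in sorted(results, key=lambda r: r.score)]
    return results, ordering


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x sample TSV: first column gene ids, header row sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def write_results(results: list[EMTResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample": r.sample_id,
                "score": r.score,
                "class": r.phenotype,
                "threshold": r.threshold,
                "coverage": r.coverage,
            }
            for r in results
        ]
    ).to_csv(path, index=False)
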