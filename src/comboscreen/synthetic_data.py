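"""Ground-truth-known simulators for every pipeline stage.

Three generators, all seeded and reproducible:

* :func:`simulate_screen` — dose-combination viability matrices for one
  drug pair.  Single agents follow four-parameter Hill curves; each
  combination well is the Bliss composite of the two single-agent
  inhibitions plus an injected deviation (the known synergy or
  antagonism), mapped back to the activity (%) scale with additive
  Gaussian plate noise.  The truth record keeps the noiseless surfaces
  so downstream estimates can be checked against what was injected.
* :func:`simulate_expression` — gene x sample matrices on a
  log2(FPKM + 0.01)-like scale with an epithelial/mesenchymal block
  structure for a bidirectional signature.
* :func:`simulate_tumor_growth` — per-animal exponential tumor growth
  expressed as caliper (L, W) pairs consistent with V = L x W^2 / 2.

Defaults mirror the screening design the pipeline targets: 6x6 dose
grids (10x10 for confirmation) at 3-fold dilution with single-agent
effects spanning 0-85% inhibition, and two biological replicates per
combination matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .emt_signature import EMTSignature
from .plate_io import CombinationMatrix

# ---------------------------------------------------------------------------
# screen simulation
# ---------------------------------------------------------------------------


@dataclass
class DrugParams:
    """True Hill-curve parameters of a simulated compound (activity %)."""

    id: str
    a0: float = 0.0  # activity at zero dose
    ainf: float = -100.0  # asymptotic activity, >= -100
    ec50: float = 100.0  # concentration units (e.g. nM)
    hill: float = 1.0

    def validate(self) -> None:
        if self.ainf < -100.0:
            raise ValueError(f"{self.id}: Ainf must be >= -100, got {self.ainf}")
        if self.ec50 <= 0:
            raise ValueError(f"{self.id}: ec50 must be positive")
        if self.hill <= 0:
            raise ValueError(f"{self.id}: hill slope must be positive")

    def activity(self, dose):
        d = np.asarray(dose, dtype=float)
        ratio = np.where(d > 0, (d / self.ec50) ** self.hill, 0.0)
        out = self.ainf + (self.a0 - self.ainf) / (1.0 + ratio)
        return out if out.ndim else float(out)

    def inhibition(self, dose):
        return np.clip(-np.asarray(self.activity(dose)) / 100.0, 0.0, 1.0)

    def dose_at_inhibition(self, f: float) -> float:
        """Closed-form inverse of the true curve on the inhibition scale."""
        f0, finf = -self.a0 / 100.0, -self.ainf / 100.0
        lo, hi = min(f0, finf), max(f0, finf)
        if not (lo < f < hi):
            raise ValueError(f"{self.id}: inhibition {f} unattainable ({lo}, {hi})")
        a_t = -100.0 * f
        x = (self.a0 - a_t) / (a_t - self.ainf)
        return float(self.ec50 * x ** (1.0 / self.hill))


@dataclass
class DoseLayout:
    """Dilution-series dose grid: ``size`` nonzero doses per axis, the top
    dose at ``max_inhibition`` single-agent effect, descending by
    ``dilution``-fold steps."""

    size: int = 6
    dilution: float = 3.0
    max_inhibition: float = 0.85

    def validate(self) -> None:
        if self.size < 2:
            raise ValueError("dose layout needs >= 2 doses")
        if self.dilution <= 1:
            raise ValueError("dilution factor must exceed 1")
        if not (0 < self.max_inhibition < 1):
            raise ValueError("max_inhibition must be in (0, 1)")

    def doses_for(self, drug: DrugParams) -> np.ndarray:
        """Nonzero ascending doses for one drug; shallow curves fall back
        to 95% of their attainable inhibition."""
        f0, finf = -drug.a0 / 100.0, -drug.ainf / 100.0
        attainable = max(f0, finf)
        top_f = self.max_inhibition
        if attainable <= top_f:
            top_f = min(f0, finf) + 0.95 * (attainable - min(f0, finf))
        top = drug.dose_at_inhibition(top_f)
        return top / self.dilution ** np.arange(self.size - 1, -1, -1)


@dataclass
class DeviationSpec:
    """Injected excess-over-Bliss inhibition at combination wells.

    ``kind`` is one of ``zero``, ``constant`` (amplitude everywhere both
    doses > 0) or ``gaussian_bump`` (amplitude at the log-dose center,
    decaying with ``width`` in log10-dose units).  Single-agent wells
    always receive zero deviation.
    """

    kind: str = "zero"
    amplitude: float = 0.0
    center: tuple[float, float] | None = None  # (dose_a, dose_b); bump only
    width: float = 0.5  # log10-dose sd of the bump

    def validate(self) -> None:
        if self.kind not in ("zero", "constant", "gaussian_bump"):
            raise ValueError(f"unknown deviation kind {self.kind!r}")
        if not (-1.0 <= self.amplitude <= 1.0):
            raise ValueError("deviation amplitude must lie in [-1, 1]")
        if self.kind == "gaussian_bump" and self.width <= 0:
            raise ValueError("gaussian bump width must be positive")

    def __call__(self, dose_a: float, dose_b: float) -> float:
        if dose_a == 0 or dose_b == 0 or self.kind == "zero":
            return 0.0
        if self.kind == "constant":
            return self.amplitude
        ca, cb = self.center if self.center is not None else (dose_a, dose_b)
        z = ((np.log10(dose_a) - np.log10(ca)) ** 2
             + (np.log10(dose_b) - np.log10(cb)) ** 2) / (2 * self.width**2)
        return float(self.amplitude * np.exp(-z))


@dataclass
class ScreenSimConfig:
    """Study conditions for one simulated drug-pair combination matrix."""

    drugs: tuple[DrugParams, DrugParams]
    dose_layout: DoseLayout = field(default_factory=DoseLayout)
    deviation: DeviationSpec = field(default_factory=DeviationSpec)
    noise_sd: float = 3.0  # additive Gaussian noise, activity %
    n_replicates: int = 2  # two biological replicates per matrix
    cell_line_id: str = "SIM-1"
    seed: int = 0

    def validate(self) -> None:
        if len(self.drugs) != 2:
            raise ValueError("a combination matrix needs exactly 2 drugs")
        for d in self.drugs:
            d.validate()
        self.dose_layout.validate()
        self.deviation.validate()
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class ScreenTruth:
    """Noiseless ground truth behind one simulated combination matrix."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    fa: np.ndarray  # true single-agent inhibition along axis a
    fb: np.ndarray
    expected: np.ndarray  # Bliss composite grid (no deviation)
    requested_excess: np.ndarray  # deviation as requested
    injected_excess: np.ndarray  # deviation actually applied after clamping
    clamped: np.ndarray  # wells where clamping altered the deviation
    true_inhibition: np.ndarray  # expected + injected_excess

    @property
    def mean_injected_excess(self) -> float:
        """Mean realized excess over combination wells (fraction)."""
        combo = (self.doses_a[:, None] > 0) & (self.doses_b[None, :] > 0)
        return float(np.mean(self.injected_excess[combo]))

    def to_json(self, path: str | Path) -> None:
        payload = {
            k: np.asarray(getattr(self, k)).tolist()
            for k in (
                "doses_a", "doses_b", "fa", "fb", "expected",
                "requested_excess", "injected_excess", "clamped",
                "true_inhibition",
            )
        }
        payload["mean_injected_excess"] = self.mean_injected_excess
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class ScreenSimResult:
    matrices: list[CombinationMatrix]
    truth: ScreenTruth
    config: ScreenSimConfig


def simulate_screen(config: ScreenSimConfig) -> ScreenSimResult:
    """Simulate ``n_replicates`` combination matrices for one drug pair.

    The (size+1) x (size+1) grid includes the zero-dose row/column and
    the DMSO corner (activity 0 before noise).  Combination wells are
    the Bliss composite of the true single-agent inhibitions plus the
    injected deviation, clamped to [0, 1] (clamped wells flagged in the
    truth record), mapped to activity = -100 x inhibition, plus i.i.d.
    Gaussian noise.  Identical seed and config give identical output.
    """
    config.validate()
    drug_a, drug_b = config.drugs
    doses_a = np.concatenate([[0.0], config.dose_layout.doses_for(drug_a)])
    doses_b = np.concatenate([[0.0], config.dose_layout.doses_for(drug_b)])
    fa = drug_a.inhibition(doses_a)
    fb = drug_b.inhibition(doses_b)
    fa[0] = 0.0  # DMSO row/column anchor the no-effect reference
    fb[0] = 0.0
    expected = fa[:, None] + fb[None, :] - fa[:, None] * fb[None, :]
    requested = np.array(
        [[config.deviation(da, db) for db in doses_b] for da in doses_a]
    )
    composite = np.clip(expected + requested, 0.0, 1.0)
    injected = composite - expected
    clamped = ~np.isclose(injected, requested)

    # single-agent wells follow the drug's own activity curve (which may
    # include a nonzero A0); combination wells come from the composite
    activity_true = -100.0 * composite
    activity_true[:, 0] = np.asarray(drug_a.activity(doses_a))
    activity_true[0, :] = np.asarray(drug_b.activity(doses_b))
    activity_true[0, 0] = 0.0

    truth = ScreenTruth(
        doses_a=doses_a, doses_b=doses_b, fa=fa, fb=fb, expected=expected,
        requested_excess=requested, injected_excess=injected,
        clamped=clamped, true_inhibition=composite,
    )

    rng = np.random.default_rng(config.seed)
    matrices = []
    for rep in range(1, config.n_replicates + 1):
        noise = (
            rng.normal(0.0, config.noise_sd, size=activity_true.shape)
            if config.noise_sd > 0
            else np.zeros_like(activity_true)
        )
        matrices.append(
            CombinationMatrix(
                compound_a_id=drug_a.id,
                compound_b_id=drug_b.id,
                cell_line_id=config.cell_line_id,
                replicate_id=str(rep),
                doses_a=doses_a.copy(),
                doses_b=doses_b.copy(),
                activity=activity_true + noise,
            )
        )
    return ScreenSimResult(matrices=matrices, truth=truth, config=config)


def simulate_panel(
    anchor: DrugParams,
    partners: list[DrugParams],
    deviations: dict[str, DeviationSpec],
    dose_layout: DoseLayout | None = None,
    noise_sd: float = 3.0,
    n_replicates: int = 2,
    cell_line_id: str = "SIM-1",
    seed: int = 0,
) -> dict[str, ScreenSimResult]:
    """Screen a panel of partner compounds against one anchor drug.

    Each partner gets its own combination matrix set (deviation looked
    up by partner id; missing ids default to the null deviation), with
    per-pair seeds derived from ``seed``.
    """
    layout = dose_layout if dose_layout is not None else DoseLayout()
    children = np.random.SeedSequence(seed).spawn(len(partners))
    results = {}
    for partner, child in zip(partners, children):
        cfg = ScreenSimConfig(
            drugs=(partner, anchor),
            dose_layout=layout,
            deviation=deviations.get(partner.id, DeviationSpec()),
            noise_sd=noise_sd,
            n_replicates=n_replicates,
            cell_line_id=cell_line_id,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        results[partner.id] = simulate_screen(cfg)
    return results


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSimConfig:
    """Block-structured expression matrix emulating an E/M phenotype split.

    Defaults follow a 77-gene bidirectional signature (25 epithelial +
    52 mesenchymal stand-in genes) among 1,000 measured genes, with 20
    samples per phenotype.
    """

    n_genes_total: int = 1000
    n_signature_e: int = 25
    n_signature_m: int = 52
    n_samples_per_phenotype: int = 20
    effect_size: float = 2.0  # log2-scale shift of signature genes
    noise_sd: float = 0.5
    baseline_mean: float = 2.0  # log2(FPKM + 0.01)-like location
    baseline_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_genes_total, self.n_signature_e, self.n_signature_m,
            self.n_samples_per_phenotype,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if self.n_signature_e + self.n_signature_m > self.n_genes_total:
            raise ValueError("signature larger than the gene universe")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class ExpressionSimResult:
    matrix: pd.DataFrame  # genes x samples
    signature: EMTSignature
    labels: dict[str, str]  # sample id -> truth phenotype


def simulate_expression(config: ExpressionSimConfig) -> ExpressionSimResult:
    """Mesenchymal-truth samples carry signature-M genes shifted up and
    signature-E genes shifted down by ``effect_size`` (epithelial-truth
    samples the reverse), on top of gene-specific baselines."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes_total)]
    sig_e = genes[: config.n_signature_e]
    sig_m = genes[config.n_signature_e : config.n_signature_e + config.n_signature_m]
    n_per = config.n_samples_per_phenotype
    samples = [f"S{i + 1:03d}" for i in range(2 * n_per)]
    labels = {
        s: ("epithelial" if i < n_per else "mesenchymal")
        for i, s in enumerate(samples)
    }

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes_total)
    values = np.tile(baseline[:, None], (1, len(samples)))
    is_e_gene = np.isin(genes, sig_e)
    is_m_gene = np.isin(genes, sig_m)
    for j, s in enumerate(samples):
        sign = 1.0 if labels[s] == "mesenchymal" else -1.0
        values[is_m_gene, j] += sign * config.effect_size
        values[is_e_gene, j] -= sign * config.effect_size
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, values.shape)

    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    signature = EMTSignature(epithelial=sig_e, mesenchymal=sig_m)
    return ExpressionSimResult(matrix=matrix, signature=signature, labels=labels)


# ---------------------------------------------------------------------------
# tumor growth simulation
# ---------------------------------------------------------------------------

#: default caliper aspect ratio L/W; 5:3 reproduces e.g. V=180 -> (10, 6)
DEFAULT_ASPECT_RATIO = 5.0 / 3.0


def simulate_tumor_growth(
    groups: dict[str, int],
    growth_rates: dict[str, float],
    start_volume: float = 180.0,
    days: list[float] | None = None,
    noise_sd: float = 0.1,
    aspect_ratio: float = DEFAULT_ASPECT_RATIO,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential tumor growth V(t) = V0 exp(r t) per animal, reported
    as caliper (L, W) pairs with fixed aspect ratio so that
    L x W^2 / 2 = V.  ``groups`` maps group id -> number of animals;
    ``growth_rates`` maps group id -> per-day exponential rate (0 =
    stasis; negative = regression).  ``noise_sd`` is a lognormal
    fractional error on volume.
    """
    if start_volume <= 0:
        raise ValueError("start_volume must be positive")
    missing = set(groups) - set(growth_rates)
    if missing:
        raise ValueError(f"growth rate missing for groups: {sorted(missing)}")
    if days is None:
        days = [0.0, 3.0, 7.0, 10.0, 14.0, 17.0, 21.0]
    rng = np.random.default_rng(seed)
    rows = []
    for group, n_animals in groups.items():
        rate = growth_rates[group]
        for a in range(1, n_animals + 1):
            animal = f"{group}-{a:02d}"
            for day in days:
                v = start_volume * np.exp(rate * day)
                if noise_sd > 0:
                    v *= np.exp(rng.normal(0.0, noise_sd))
                # invert V = L W^2 / 2 with L = aspect_ratio * W
                w = (2.0 * v / aspect_ratio) ** (1.0 / 3.0)
                rows.append(
                    {
                        "animal": animal,
                        "group": group,
                        "day": day,
                        "length_mm": aspect_ratio * w,
                        "width_mm": w,
                    }
                )
    return pd.DataFrame(rows)
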