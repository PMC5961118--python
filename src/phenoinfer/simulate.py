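"""Synthetic expression/phenotype datasets with planted marker structure.

The generator emulates the statistical structure that makes marker-based
phenotype prediction work on expressed-region coverage: a right-skewed
(lognormal) background of region means on the log2 scale, a disjoint set
of marker regions per phenotype level shifted by an effect delta in that
level only, additive Gaussian noise, flooring at zero (log2 coverage is
non-negative) and excess exact zeros at rate pi. Phenotype labels are
emitted in deliberately messy raw form — mixed-case synonyms, placeholder
strings, empty cells — to exercise canonicalization the way repository
metadata does.

What it does not emulate: correlated regions, batch and lab effects,
library-size artefacts, or any within-level heterogeneity beyond noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .phenotypes import CategoricalColumn, ContinuousColumn, PhenotypeTable
from .regions import Region


@dataclass
class SimulationSpec:
    """Study conditions for the categorical generator.

    Defaults are the package's reference conditions: a two-level phenotype
    with equal proportions, 20 markers per level with a 3-sigma mean shift
    (delta = 3.0 in log2 units against sigma = 1.0), 400 samples over 500
    regions, and 5% excess zeros.
    """

    n_samples: int = 400
    n_regions: int = 500
    levels: tuple = ("female", "male")
    proportions: tuple = (0.5, 0.5)
    markers_per_level: int = 20
    effect: float = 3.0            # delta, log2 units
    noise: float = 1.0             # sigma
    zero_inflation: float = 0.05   # pi
    baseline_log_mean: float = 1.0     # lognormal parameters of region means
    baseline_log_sigma: float = 0.5
    messy_fraction: float = 0.1    # raw labels replaced by "Unknown"/blank
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.proportions):
            raise ValueError("levels and proportions must align")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if self.markers_per_level * len(self.levels) > self.n_regions:
            raise ValueError("markers_per_level x levels exceeds n_regions")
        if self.effect < 0 or self.noise < 0:
            raise ValueError("effect and noise must be >= 0")
        if not (0 <= self.zero_inflation < 1):
            raise ValueError("zero_inflation must be in [0, 1)")


#: Raw spellings emitted per canonical level; drawn uniformly.
_RAW_SPELLINGS = {
    "female": ["female", "F", "Female", "f"],
    "male": ["male", "M", "Male", "m"],
}


def _default_schema(spec: SimulationSpec) -> CategoricalColumn:
    synonyms = {}
    for lev in spec.levels:
        for raw in _RAW_SPELLINGS.get(lev, [lev, lev.upper(), lev.capitalize()]):
            synonyms[raw] = lev
    return CategoricalColumn(name="phenotype", synonyms=synonyms)


def _regions(n: int) -> list[Region]:
    return [Region("chrS", 1000 * i, 1000 * i + 500) for i in range(n)]


@dataclass
class CategoricalTruth:
    """Ground truth of a simulated categorical dataset."""

    true_labels: np.ndarray
    marker_regions: dict[str, list[Region]]
    level_means: pd.DataFrame      # regions x levels true mean expression


def simulate_categorical_dataset(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, PhenotypeTable, CategoricalTruth]:
    """Draw one dataset under ``spec``; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    L = len(spec.levels)
    regions = _regions(spec.n_regions)
    samples = [f"sample{i:04d}" for i in range(spec.n_samples)]

    true_idx = rng.choice(L, size=spec.n_samples, p=list(spec.proportions))
    true_labels = np.asarray([spec.levels[i] for i in true_idx], dtype=object)

    baseline = rng.lognormal(
        spec.baseline_log_mean, spec.baseline_log_sigma, size=spec.n_regions
    )
    means = np.tile(baseline[:, None], (1, L))
    marker_regions: dict[str, list[Region]] = {}
    marker_ids = rng.permutation(spec.n_regions)[: spec.markers_per_level * L]
    for j, lev in enumerate(spec.levels):
        mine = marker_ids[j * spec.markers_per_level : (j + 1) * spec.markers_per_level]
        means[mine, j] += spec.effect
        marker_regions[lev] = [regions[i] for i in sorted(mine)]

    values = means[:, true_idx] + rng.normal(
        0.0, spec.noise, size=(spec.n_regions, spec.n_samples)
    )
    values = np.maximum(values, 0.0)
    if spec.zero_inflation > 0:
        dropout = rng.random(values.shape) < spec.zero_inflation
        values[dropout] = 0.0

    raw = []
    for lab in true_labels:
        u = rng.random()
        if u < spec.messy_fraction / 2:
            raw.append("Unknown")
        elif u < spec.messy_fraction:
            raw.append("")
        else:
            spellings = _RAW_SPELLINGS.get(lab, [lab])
            raw.append(spellings[rng.integers(len(spellings))])
    schema = _default_schema(spec)
    pheno = PhenotypeTable(
        samples, {"phenotype": schema}, pd.DataFrame({"phenotype": raw})
    )
    m = ExpressionMatrix(regions, samples, values, transformed=True)
    truth = CategoricalTruth(
        true_labels=true_labels,
        marker_regions=marker_regions,
        level_means=pd.DataFrame(
            means, index=[r.id for r in regions], columns=list(spec.levels)
        ),
    )
    return m, pheno, truth


@dataclass
class ContinuousSpec:
    """Study conditions for the continuous generator (age-like trait)."""

    n_samples: int = 500
    n_regions: int = 200
    signal_regions: int = 10
    shape: str = "linear"          # linear | smooth-nonlinear | none
    slope: float = 0.1             # expression change per unit of the trait
    noise: float = 0.5             # sigma around f(y)
    y_low: float = 20.0
    y_high: float = 70.0
    zero_inflation: float = 0.05
    baseline_log_mean: float = 1.0
    baseline_log_sigma: float = 0.5
    missing_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in {"linear", "smooth-nonlinear", "none"}:
            raise ValueError(f"unknown signal shape {self.shape!r}")
        if self.signal_regions > self.n_regions:
            raise ValueError("signal_regions exceeds n_regions")
        if not (0 <= self.zero_inflation < 1):
            raise ValueError("zero_inflation must be in [0, 1)")


@dataclass
class ContinuousTruth:
    y_true: np.ndarray
    signal_regions: list[Region]


def simulate_continuous_dataset(
    spec: ContinuousSpec,
) -> tuple[ExpressionMatrix, PhenotypeTable, ContinuousTruth]:
    """Expression tracking a continuous trait at a planted subset of regions."""
    rng = np.random.default_rng(spec.seed)
    regions = _regions(spec.n_regions)
    samples = [f"sample{i:04d}" for i in range(spec.n_samples)]
    y = rng.uniform(spec.y_low, spec.y_high, size=spec.n_samples)

    baseline = rng.lognormal(
        spec.baseline_log_mean, spec.baseline_log_sigma, size=spec.n_regions
    )
    values = np.tile(baseline[:, None], (1, spec.n_samples)).astype(float)
    signal_ids = np.sort(rng.permutation(spec.n_regions)[: spec.signal_regions])
    span = spec.y_high - spec.y_low
    if spec.shape != "none":
        for i in signal_ids:
            if spec.shape == "linear":
                f = spec.slope * (y - spec.y_low)
            else:
                f = spec.slope * span / 2.0 * (
                    1.0 + np.sin(2.0 * np.pi * (y - spec.y_low) / span)
                )
            values[i] += f
    values += rng.normal(0.0, spec.noise, size=values.shape)
    values = np.maximum(values, 0.0)
    if spec.zero_inflation > 0:
        dropout = rng.random(values.shape) < spec.zero_inflation
        values[dropout] = 0.0

    raw = [
        "" if rng.random() < spec.missing_fraction else f"{v:.2f}" for v in y
    ]
    pheno = PhenotypeTable(
        samples,
        {"trait": ContinuousColumn(name="trait")},
        pd.DataFrame({"trait": raw}),
    )
    m = ExpressionMatrix(regions, samples, values, transformed=True)
    truth = ContinuousTruth(
        y_true=y, signal_regions=[regions[i] for i in signal_ids]
    )
    return m, pheno, truth


def simulate_mislabeled_dataset(
    spec: SimulationSpec, flip_fraction: float
) -> tuple[ExpressionMatrix, PhenotypeTable, CategoricalTruth, np.ndarray]:
    """Categorical dataset where a fraction of reported labels are flipped.

    Expression still reflects the *true* labels; only the reported raw
    labels lie. Returns the flipped-sample mask alongside the usual
    outputs, so measured-vs-true accuracy arithmetic can be asserted.
    Fractions >= 0.5 are refused — reported labels would no longer anchor
    the truth.
    """
    if not (0 <= flip_fraction < 0.5):
        raise ValueError("flip_fraction must be in [0, 0.5)")
    m, pheno, truth = simulate_categorical_dataset(spec)
    rng = np.random.default_rng(spec.seed + 982451653 % (2**31))
    flip = rng.random(spec.n_samples) < flip_fraction
    levels = list(spec.levels)
    raw = list(pheno.raw["phenotype"])
    for i in np.flatnonzero(flip):
        current = truth.true_labels[i]
        others = [lev for lev in levels if lev != current]
        wrong = others[rng.integers(len(others))]
        spellings = _RAW_SPELLINGS.get(wrong, [wrong])
        raw[i] = spellings[rng.integers(len(spellings))]
    schema = _default_schema(spec)
    pheno_flipped = PhenotypeTable(
        list(pheno.samples), {"phenotype": schema}, pd.DataFrame({"phenotype": raw})
    )
    return m, pheno_flipped, truth, flip
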