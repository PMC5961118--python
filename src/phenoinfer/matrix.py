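"""The regions x samples expression container shared by every stage.

Values are coverage-derived expression estimates: either raw (non-negative
mean coverage) or log2(1 + coverage). The container tracks which of the two
it holds so the transform cannot be applied twice by accident.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import Region


@dataclass
class ExpressionMatrix:
    """A |regions| x |samples| matrix of expression values.

    Parameters
    ----------
    regions : sequence of Region
        Row identity, ordered. Must be unique.
    samples : sequence of str
        Column identity, ordered. Must be unique.
    values : ndarray of shape (n_regions, n_samples)
        Finite, non-negative expression values.
    transformed : bool
        True when values are log2(1 + coverage); False for raw coverage.
    """

    regions: list[Region]
    samples: list[str]
    values: np.ndarray
    transformed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.regions = list(self.regions)
        self.samples = [str(s) for s in self.samples]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.regions), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.regions)} regions x {len(self.samples)} samples"
            )
        if len(set(self.regions)) != len(self.regions):
            dupes = pd.Series([r.id for r in self.regions])
            dupes = dupes[dupes.duplicated()].unique()
            raise ValueError(f"duplicate regions: {', '.join(dupes[:5])}")
        if len(set(self.samples)) != len(self.samples):
            dupes = pd.Series(self.samples)
            dupes = dupes[dupes.duplicated()].unique()
            raise ValueError(f"duplicate sample IDs: {', '.join(dupes[:5])}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def region_ids(self) -> list[str]:
        return [r.id for r in self.regions]

    def region_index(self) -> dict[Region, int]:
        return {r: i for i, r in enumerate(self.regions)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_ids, columns=self.samples)

    def subset_regions(self, regions: Sequence[Region]) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``regions`` in the given order."""
        idx = self.region_index()
        missing = [r.id for r in regions if r not in idx]
        if missing:
            raise KeyError(f"regions absent from matrix: {', '.join(missing[:10])}")
        rows = [idx[r] for r in regions]
        return ExpressionMatrix(
            list(regions), self.samples, self.values[rows], self.transformed, dict(self.meta)
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in samples if s not in pos]
        if missing:
            raise KeyError(f"samples absent from matrix: {', '.join(missing[:10])}")
        cols = [pos[s] for s in samples]
        return ExpressionMatrix(
            self.regions, list(samples), self.values[:, cols], self.transformed, dict(self.meta)
        )


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Apply the elementwise log2(1 + x) transform to raw coverage.

    A pseudocount of 1 keeps the transform defined at zero coverage and
    order-preserving; 0 maps to 0. Refuses to run twice: double application
    would silently change the scale of every downstream statistic.
    """
    if m.transformed:
        raise ValueError("matrix is already log2-transformed")
    if np.any(m.values < 0):
        raise ValueError("log2 transform requires non-negative raw coverage")
    return ExpressionMatrix(
        m.regions, m.samples, np.log2(1.0 + m.values), transformed=True, meta=dict(m.meta)
    )
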