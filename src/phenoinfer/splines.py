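"""Natural cubic spline bases with quantile knots and a zero-inflation rule.

A natural cubic spline is piecewise cubic between its knots, twice
continuously differentiable, and *linear* beyond the boundary knots — the
tail behaviour that keeps extrapolation sane for coverage data.

Knot placement follows the data: ``l`` knots at equally spaced quantiles of
the observed values. Coverage is zero-inflated, so the quantile grid often
collapses onto the minimum; in that case the first knot is pinned at the
minimum (zero for coverage) and the remaining knots are spread over the
quantiles of the strictly larger values.

The basis returned is the *cardinal* basis: the ``l`` natural splines that
interpolate the unit vectors at the knots. They span the full natural-spline
space on those knots (including constants, since they sum to one), so joint
fits across several regions prune the resulting collinearity explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline


@dataclass
class SplineBasis:
    """Cardinal natural cubic spline basis on a fixed knot vector."""

    knots: np.ndarray
    _spline: CubicSpline = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots.ndim != 1 or self.knots.size < 2:
            raise ValueError("need at least 2 distinct knots")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self._spline = CubicSpline(
            self.knots, np.eye(self.knots.size), axis=0, bc_type="natural"
        )

    @property
    def n_basis(self) -> int:
        return int(self.knots.size)

    def evaluate(self, x) -> np.ndarray:
        """Evaluate all basis functions at ``x``; linear beyond the boundary.

        Returns an array of shape ``(len(x), n_basis)``.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.knots[0], self.knots[-1]
        inner = np.clip(x, lo, hi)
        vals = self._spline(inner)
        below = x < lo
        above = x > hi
        if below.any():
            slope = self._spline(lo, 1)
            vals[below] += np.outer(x[below] - lo, slope)
        if above.any():
            slope = self._spline(hi, 1)
            vals[above] += np.outer(x[above] - hi, slope)
        return vals

    def in_range(self, x) -> np.ndarray:
        """True where ``x`` lies within the boundary knots (no extrapolation)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return (x >= self.knots[0]) & (x <= self.knots[-1])


def make_spline_basis(values, l: int = 5) -> SplineBasis:
    """Place ``l`` knots at equally spaced quantiles of ``values``.

    Zero-inflation rule: when two or more quantile knots coincide at the
    minimum, the first knot is pinned there and the remaining ``l - 1``
    knots are placed at equally spaced quantiles of the strictly larger
    values. If the data support fewer distinct knots than requested, the
    basis is reduced with a warning; fully constant input is an error.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < l + 1:
        raise ValueError(
            f"need at least {l + 1} finite values for an l = {l} basis, "
            f"got {values.size}"
        )
    if np.all(values == values[0]):
        raise ValueError("all values identical: no spline basis exists")
    if l < 2:
        raise ValueError("l must be >= 2")

    knots = np.quantile(values, np.linspace(0.0, 1.0, l))
    vmin = knots[0]
    if np.sum(knots == vmin) >= 2:
        positive = values[values > vmin]
        rest = np.quantile(positive, np.linspace(0.0, 1.0, l - 1))
        knots = np.concatenate([[vmin], rest])
    knots = np.unique(knots)
    if knots.size < l:
        warnings.warn(
            f"only {knots.size} distinct knots available; basis reduced from "
            f"l = {l} to {knots.size}",
            UserWarning,
            stacklevel=2,
        )
    return SplineBasis(knots)
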