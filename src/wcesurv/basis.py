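"""Cubic regression-spline bases for lag-weight functions.

The weighted-cumulative-exposure (WCE) model represents the influence of a
dose taken ``t`` days in the past through a weight function

    w(t) = sum_j theta_j B_j(t),    t = 1, ..., T,

where the ``B_j`` are cubic B-splines on the window ``[0, T]`` and ``T`` is
the maximum lag beyond which past doses are assumed to carry no weight.
The spline coefficients ``theta`` are estimated jointly with the other
regression coefficients of a Cox or conditional-logistic model.

Two basis variants are provided:

* unconstrained — the full cubic B-spline basis with ``n_interior_knots + 4``
  columns;
* right-constrained — the last two columns are dropped, which forces the
  fitted weight function to reach zero smoothly (value and slope) at the
  end of the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineWeightBasis", "WeightFunction"]

_ORDER = 4  # cubic splines


class SplineWeightBasis:
    """Cubic B-spline basis tabulated on integer lags ``1..window``.

    Parameters
    ----------
    window : int
        Time window ``T`` in days. Doses taken more than ``window`` days ago
        receive zero weight.
    n_interior_knots : int
        Number of interior knots, placed equally spaced on ``(0, T)`` by
        default.
    constrained : bool
        If True, drop the two trailing basis columns so every retained
        column (and hence any fitted weight function) is zero at ``t = T``
        with zero slope.
    knot_placement : {"equal", "quantile"}
        "equal" spaces interior knots evenly on ``(0, T)``. "quantile"
        requires explicit knots via ``interior_knots``.
    interior_knots : sequence of float, optional
        Explicit interior knot positions, overriding equal spacing.
    """

    def __init__(
        self,
        window: int = 75,
        n_interior_knots: int = 1,
        constrained: bool = False,
        knot_placement: str = "equal",
        interior_knots=None,
    ):
        if window < _ORDER:
            raise ValueError(
                f"window-too-small: window T={window} must be >= {_ORDER}"
            )
        if n_interior_knots < 0:
            raise ValueError("n_interior_knots must be >= 0")
        self.window = int(window)
        self.n_interior_knots = int(n_interior_knots)
        self.constrained = bool(constrained)
        self.knot_placement = knot_placement

        if interior_knots is not None:
            inner = np.asarray(interior_knots, dtype=float)
            if inner.size != n_interior_knots:
                raise ValueError("interior_knots length mismatch")
        elif knot_placement == "equal":
            inner = np.linspace(0.0, float(window), n_interior_knots + 2)[1:-1]
        else:
            raise ValueError(
                "quantile placement requires explicit interior_knots"
            )
        self.interior_knots_ = inner
        # boundary knots at 0 and T with full (order) multiplicity
        self.knots_ = np.concatenate(
            [np.zeros(_ORDER), inner, np.full(_ORDER, float(window))]
        )
        self._n_full = n_interior_knots + _ORDER
        self.n_terms = self._n_full - (2 if constrained else 0)
        if self.n_terms < 1:
            raise ValueError("constraint leaves no basis columns")
        self._matrix = self.design(np.arange(1, self.window + 1))

    # ------------------------------------------------------------------
    def design(self, lags) -> np.ndarray:
        """Evaluate the basis columns at the given lags (days).

        Lags outside ``(0, window]`` evaluate to zero in every column.
        """
        lags = np.atleast_1d(np.asarray(lags, dtype=float))
        out = np.zeros((lags.size, self._n_full))
        inside = (lags >= 0) & (lags <= self.window)
        if inside.any():
            x = np.clip(lags[inside], 0.0, float(self.window))
            dm = BSpline.design_matrix(x, self.knots_, _ORDER - 1,
                                       extrapolate=False)
            out[inside] = dm.toarray()
        if self.constrained:
            out = out[:, : self.n_terms]
        return out

    @property
    def matrix(self) -> np.ndarray:
        """Basis values at integer lags ``1..window``; shape (T, n_terms)."""
        return self._matrix

    def kernel(self) -> np.ndarray:
        """Convolution kernels, shape ``(window + 1, n_terms)``.

        Row ``l`` holds ``B_j(l)``; row 0 is zero because the same-day dose
        is excluded from the cumulative sum (minimum lag one day).
        """
        k = np.zeros((self.window + 1, self.n_terms))
        k[1:] = self._matrix
        return k

    def pattern_loading(self, pattern) -> np.ndarray:
        """Basis loading ``d_j = sum_t B_j(t) x(t)`` of an exposure pattern.

        ``pattern[i]`` is the dose (g/day) at lag ``i + 1`` days before the
        evaluation day. Shorter patterns are zero-padded; longer ones are
        rejected.
        """
        x = np.asarray(pattern, dtype=float)
        if x.ndim != 1:
            raise ValueError("pattern must be one-dimensional")
        if x.size > self.window:
            raise ValueError(
                "pattern-window mismatch: pattern longer than basis window"
            )
        if np.any(x < 0):
            raise ValueError("pattern doses must be non-negative")
        return x @ self._matrix[: x.size]

    def __repr__(self):  # pragma: no cover - cosmetic
        c = "constrained" if self.constrained else "unconstrained"
        return (f"SplineWeightBasis(window={self.window}, "
                f"knots={self.n_interior_knots}, {c})")


@dataclass
class WeightFunction:
    """A concrete lag-weight function ``w(t) = sum_j theta_j B_j(t)``.

    ``theta`` carries units of log hazard ratio per gram-day.
    """

    basis: SplineWeightBasis
    theta: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.size != self.basis.n_terms:
            raise ValueError(
                f"theta length {self.theta.size} != basis terms "
                f"{self.basis.n_terms}"
            )

    def __call__(self, lags) -> np.ndarray:
        """Evaluate ``w`` at the given lags; zero outside ``(0, window]``."""
        return self.basis.design(lags) @ self.theta

    @property
    def values(self) -> np.ndarray:
        """``w(t)`` tabulated at integer lags ``1..window``."""
        return self.basis.matrix @ self.theta

    def pattern_log_hr(self, pattern) -> float:
        """Log hazard ratio of an exposure pattern versus never-use."""
        return float(self.basis.pattern_loading(pattern) @ self.theta)
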