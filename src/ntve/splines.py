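"""Natural cubic spline basis for time-course GLM design matrices.

A natural cubic spline with M knots is piecewise cubic between knots, has
two continuous derivatives, and is constrained to be *linear* beyond the
boundary knots (second derivative zero at and outside the boundaries).  The
space of such functions has dimension M; excluding the intercept leaves
K = M - 1 basis functions, which is the ``df`` used in design matrices.

The basis is the standard truncated-power construction: with knots
xi_1 < ... < xi_M,

    N_1(x)     = x
    N_{k+1}(x) = d_k(x) - d_{M-1}(x),    k = 1 .. M-2
    d_k(x)     = [ (x - xi_k)_+^3 - (x - xi_M)_+^3 ] / (xi_M - xi_k)

Interior knots default to quantiles of the distinct observed times; boundary
knots sit at the extremes.  The basis is deterministic given times and K.
"""

from __future__ import annotations

import numpy as np

__all__ = ["NaturalCubicSplineBasis", "natural_cubic_spline_basis"]


class NaturalCubicSplineBasis:
    """Callable basis: ``basis(t)`` returns an ``(len(t), K)`` design block."""

    def __init__(self, knots):
        knots = np.asarray(knots, dtype=float)
        if knots.ndim != 1 or len(knots) < 2:
            raise ValueError("need at least 2 knots")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.knots = knots
        # scale for numerical conditioning of the cubic terms
        self._scale = knots[-1] - knots[0]

    @property
    def df(self) -> int:
        return len(self.knots) - 1

    @classmethod
    def from_times(cls, times, df: int) -> "NaturalCubicSplineBasis":
        """Place df+1 knots at quantiles of the distinct times.

        Boundary knots at the extremes, interior knots at evenly spaced
        quantiles in between.  Requires at least df+1 distinct time points.
        """
        uniq = np.unique(np.asarray(times, dtype=float))
        if len(uniq) < df + 1:
            raise ValueError(f"need at least {df + 1} distinct time points for df={df}")
        qs = np.linspace(0, 1, df + 1)
        knots = np.quantile(uniq, qs)
        # quantiles of few unique points can coincide; fall back to even spacing
        if np.any(np.diff(knots) <= 0):
            knots = np.linspace(uniq[0], uniq[-1], df + 1)
        return cls(knots)

    def _d(self, x: np.ndarray, k: int) -> np.ndarray:
        xi = self.knots
        num = np.clip(x - xi[k], 0, None) ** 3 - np.clip(x - xi[-1], 0, None) ** 3
        return num / (xi[-1] - xi[k])

    def __call__(self, t) -> np.ndarray:
        x = np.asarray(t, dtype=float) / self._scale
        xi = self.knots / self._scale
        M = len(xi)
        cols = [x]
        if M > 2:
            dm1 = self._d_scaled(x, xi, M - 2)
            for k in range(M - 2):
                cols.append(self._d_scaled(x, xi, k) - dm1)
        return np.column_stack(cols)

    @staticmethod
    def _d_scaled(x: np.ndarray, xi: np.ndarray, k: int) -> np.ndarray:
        num = np.clip(x - xi[k], 0, None) ** 3 - np.clip(x - xi[-1], 0, None) ** 3
        return num / (xi[-1] - xi[k])


def natural_cubic_spline_basis(times, df: int, knots=None) -> np.ndarray:
    """Evaluate a K=df natural cubic spline basis at the given times.

    Convenience wrapper; use :class:`NaturalCubicSplineBasis` directly when
    the same basis must be evaluated at several sets of times (e.g. fitting
    and prediction).
    """
    basis = NaturalCubicSplineBasis(knots) if knots is not None else NaturalCubicSplineBasis.from_times(times, df)
    return basis(times)
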