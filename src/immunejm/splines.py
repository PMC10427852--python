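"""Restricted (natural) cubic spline bases for modelling log cell counts over time.

The longitudinal submodel and the synthetic-cohort generator both express the
latent log-count trajectory through a natural cubic spline of time.  The basis
used here is the classical truncated-power construction (Hastie, Tibshirani &
Friedman): with knots ``k_1 < ... < k_K`` (boundary knots included), the
``K - 1`` basis columns, excluding the intercept, are

    N_1(t)     = t
    N_{j+1}(t) = d_j(t) - d_{K-1}(t),      j = 1, ..., K - 2

with ``d_j(t) = [(t - k_j)_+^3 - (t - k_K)_+^3] / (k_K - k_j)``.

Each basis function is C2 on the interior and exactly linear outside the
boundary knots, so a model built on this basis extrapolates linearly.  The
first column is the untransformed time itself, which makes the coefficient of
the linear term directly interpretable as the boundary slope at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SplineBasisDef",
    "NaturalCubicSpline",
    "ncs_basis",
    "ncs_deriv",
    "default_knots",
]


@dataclass(frozen=True)
class SplineBasisDef:
    """Knot definition for a restricted cubic spline of time (months).

    ``n_basis`` equals ``len(interior_knots) + 1``: one linear column plus one
    curvature column per interior knot.
    """

    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]

    def __post_init__(self) -> None:
        interior = tuple(float(k) for k in self.interior_knots)
        lo, hi = (float(k) for k in self.boundary_knots)
        object.__setattr__(self, "interior_knots", interior)
        object.__setattr__(self, "boundary_knots", (lo, hi))
        knots = self.all_knots
        if len(knots) < 2 or np.any(np.diff(knots) <= 0):
            raise ValueError(
                f"knots must be strictly increasing with boundary knots "
                f"bracketing interior knots; got {knots}"
            )

    @property
    def all_knots(self) -> np.ndarray:
        lo, hi = self.boundary_knots
        return np.asarray([lo, *self.interior_knots, hi], dtype=float)

    @property
    def n_basis(self) -> int:
        return len(self.interior_knots) + 1


def _validate_times(times) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    return t


def ncs_basis(times, basis: SplineBasisDef) -> np.ndarray:
    """Evaluate the natural cubic spline basis (no intercept column).

    Returns an array of shape ``(len(times), basis.n_basis)``.  Column 0 is
    the raw time; columns ``1..`` are the curvature terms, one per interior
    knot, each identically zero below the lower boundary knot and linear
    above the upper one.
    """
    t = _validate_times(times)
    knots = basis.all_knots
    K = len(knots)
    out = np.empty((t.size, basis.n_basis))
    out[:, 0] = t
    if K > 2:
        kK = knots[-1]
        dK1 = _d(t, knots[K - 2], kK)
        for j in range(1, K - 1):
            out[:, j] = _d(t, knots[j - 1], kK) - dK1
    return out


def ncs_deriv(times, basis: SplineBasisDef) -> np.ndarray:
    """Analytic first derivative of :func:`ncs_basis`, column by column."""
    t = _validate_times(times)
    knots = basis.all_knots
    K = len(knots)
    out = np.empty((t.size, basis.n_basis))
    out[:, 0] = 1.0
    if K > 2:
        kK = knots[-1]
        dK1 = _d_prime(t, knots[K - 2], kK)
        for j in range(1, K - 1):
            out[:, j] = _d_prime(t, knots[j - 1], kK) - dK1
    return out


def _d(t: np.ndarray, kj: float, kK: float) -> np.ndarray:
    return (np.clip(t - kj, 0.0, None) ** 3 - np.clip(t - kK, 0.0, None) ** 3) / (kK - kj)


def _d_prime(t: np.ndarray, kj: float, kK: float) -> np.ndarray:
    return 3.0 * (np.clip(t - kj, 0.0, None) ** 2 - np.clip(t - kK, 0.0, None) ** 2) / (kK - kj)


def default_knots(times, n_interior: int = 2) -> SplineBasisDef:
    """Quantile-based knot placement: interior knots at evenly spaced inner
    quantiles (33.3%/66.7% for the default two), boundary knots at the 5%/95%
    quantiles of the observed measurement times."""
    t = _validate_times(times)
    probs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(t, probs)
    lo, hi = np.quantile(t, [0.05, 0.95])
    return SplineBasisDef(tuple(interior), (float(lo), float(hi)))


class NaturalCubicSpline(TransformerMixin, BaseEstimator):
    """Natural cubic spline transformer over a vector of times.

    Parameters
    ----------
    interior_knots, boundary_knots:
        Explicit knots (months).  When either is None, :meth:`fit` places
        knots at quantiles of the training times (``n_interior`` interior
        knots at inner quantiles, boundary at the 5%/95% quantiles).
    n_interior:
        Number of interior knots used for quantile placement; ignored when
        explicit knots are given.
    """

    def __init__(self, interior_knots=None, boundary_knots=None, n_interior: int = 2):
        self.interior_knots = interior_knots
        self.boundary_knots = boundary_knots
        self.n_interior = n_interior

    def fit(self, X, y=None):
        t = _validate_times(X)
        if self.interior_knots is not None and self.boundary_knots is not None:
            self.basis_def_ = SplineBasisDef(
                tuple(self.interior_knots), tuple(self.boundary_knots)
            )
        else:
            self.basis_def_ = default_knots(t, self.n_interior)
        self.n_features_out_ = self.basis_def_.n_basis
        return self

    def transform(self, X) -> np.ndarray:
        return ncs_basis(X, self.basis_def_)

    def derivative(self, X) -> np.ndarray:
        """First time-derivative of the basis at the given times."""
        return ncs_deriv(X, self.basis_def_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(
            ["time"] + [f"ncs{j}" for j in range(1, self.basis_def_.n_basis)]
        )
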