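"""Legendre polynomial basis over days in milk (DIM).

Test-day models regress lactation trajectories on Legendre polynomials of
standardized DIM.  DIM t in [dim_min, dim_max] maps to
w = 2 (t - dim_min) / (dim_max - dim_min) - 1 in [-1, 1]; the m-th covariate is
phi_m(t) = sqrt((2m+1)/2) * P_m(w) in the normalized form (the default;
normalization makes the basis orthonormal under the uniform measure on
[-1, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre as npleg


@dataclass(frozen=True)
class LegendreBasis:
    order: int = 5
    dim_min: int = 5
    dim_max: int = 305
    normalized: bool = True

    def __post_init__(self):
        if self.order < 0:
            raise ValueError("basis order must be non-negative")
        if self.dim_max <= self.dim_min:
            raise ValueError("dim_max must exceed dim_min")

    @property
    def n_coef(self) -> int:
        return self.order + 1

    def standardize(self, dim):
        """Map DIM to w in [-1, 1]; errors outside [dim_min, dim_max]."""
        dim = np.asarray(dim, dtype=float)
        if np.any(dim < self.dim_min) or np.any(dim > self.dim_max):
            raise ValueError(
                f"DIM outside [{self.dim_min}, {self.dim_max}]"
            )
        return 2.0 * (dim - self.dim_min) / (self.dim_max - self.dim_min) - 1.0

    def row(self, dim):
        """Basis covariates phi(dim); shape (order+1,) or (n, order+1)."""
        w = self.standardize(dim)
        scalar = w.ndim == 0
        w = np.atleast_1d(w)
        V = npleg.legvander(w, self.order)
        if self.normalized:
            V = V * np.sqrt((2 * np.arange(self.n_coef) + 1) / 2.0)
        return V[0] if scalar else V


def standardize_dim(dim, basis: LegendreBasis):
    return basis.standardize(dim)


def legendre_row(dim, basis: LegendreBasis):
    return basis.row(dim)
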