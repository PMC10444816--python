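"""Matérn spatial correlation over great-circle distances.

The latent spatial field uses the Matérn family with smoothness ν fixed at 1
(the stochastic-PDE default) and the range parameterised the SPDE way,
κ = sqrt(8ν)/r, so that correlation has dropped to ≈ 0.1 (0.14 for ν = 1) at
distance r — the distance at which spatial correlation is said to diminish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as gamma_fn
from scipy.special import kv
from sklearn.metrics.pairwise import haversine_distances

EARTH_RADIUS_KM = 6371.0

#: Diagonal jitter added to correlation matrices before factorisation.
#: Keeps matrices positive-definite when sites nearly coincide (observations
#: in the same grid cell); orders of magnitude below any meaningful signal.
CORRELATION_JITTER = 1e-8


@dataclass
class MaternParams:
    """Matérn hyperparameters: correlation range r (km), field sd σ, smoothness ν."""

    range_km: float
    sigma: float
    smoothness: float = 1.0

    def __post_init__(self) -> None:
        if self.range_km <= 0:
            raise ValueError(f"Matérn range must be positive, got {self.range_km}")
        if self.sigma <= 0:
            raise ValueError(f"Matérn sigma must be positive, got {self.sigma}")
        if self.smoothness <= 0:
            raise ValueError("Matérn smoothness must be positive")


def matern_correlation(distance_km, params: MaternParams) -> np.ndarray | float:
    """Matérn correlation at the given great-circle distance(s) in km.

    ρ(d) = 2^(1−ν)/Γ(ν) · (κd)^ν · K_ν(κd) with κ = sqrt(8ν)/r; ρ(0) = 1.
    """
    d = np.asarray(distance_km, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    nu = params.smoothness
    kappa = np.sqrt(8.0 * nu) / params.range_km
    x = kappa * d
    with np.errstate(invalid="ignore"):
        rho = (2.0 ** (1.0 - nu) / gamma_fn(nu)) * (x ** nu) * kv(nu, x)
    rho = np.where(x == 0.0, 1.0, rho)
    rho = np.clip(np.nan_to_num(rho, nan=0.0), 0.0, 1.0)
    return rho if rho.ndim else float(rho)


def great_circle_km(lat, lon) -> np.ndarray:
    """Pairwise great-circle distances (km) between decimal-degree points."""
    pts = np.radians(np.column_stack([np.asarray(lat, float), np.asarray(lon, float)]))
    return haversine_distances(pts) * EARTH_RADIUS_KM


def matern_covariance(lat, lon, params: MaternParams,
                      jitter: float = CORRELATION_JITTER) -> np.ndarray:
    """σ²·R + jitter·I at the given sites; symmetric positive-definite."""
    dist = great_circle_km(lat, lon)
    corr = matern_correlation(dist, params)
    cov = params.sigma ** 2 * corr
    cov[np.diag_indices_from(cov)] += jitter * max(params.sigma ** 2, 1.0)
    return cov
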