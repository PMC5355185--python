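"""Central-place foraging on rasters: visitation rates and collected resources.

Foragers nest in cells and distribute their visits over flowering cells within
reach, preferring nearby and more rewarding flowers. The rate at which cell i
receives visits from the foragers of cell j is

    V(j -> i) = X_j * F_i * e^(-d_ij / beta)
                / sum_q F_q * e^(-d_qj / beta) * rho_F ** d_ij

where X_j is the number of foragers nesting in j, F the floral-value raster,
d_ij the Euclidean distance between cell centers, beta the mean foraging
distance of the exponential kernel and rho_F a per-meter survival rate. The
normalization makes each forager allocate its (surviving) visits over the
flowers it can reach, so with rho_F = 1 visits are conserved: sum_i V_i =
sum_j X_j. For speed the kernel is truncated to zero beyond a high quantile of
the exponential distance distribution, consistently in numerator and
normalization, and all sums are evaluated as FFT convolutions.

The resources collected per nest in cell i during a period are the
foragers-per-nest times the kernel-weighted mean floral value around i:

    R_i = (X_i / N_i) * sum_j F_j e^(-d_ij/beta) / sum_j e^(-d_ij/beta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .params import ModelParams

__all__ = [
    "kernel_weight",
    "truncation_radius",
    "kernel_stencil",
    "visitation_rates",
    "resources_per_nest",
    "ForagerField",
    "VisitationRaster",
]


def truncation_radius(beta: float, q: float) -> float:
    """Distance (m) at quantile ``q`` of the exponential kernel: -beta*ln(1-q)."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"truncation quantile must lie in (0, 1), got {q!r}")
    if beta <= 0:
        raise ValueError("beta must be positive")
    return -beta * math.log1p(-q)


def kernel_weight(
    d: float | np.ndarray, beta: float, quantile: float = 0.99
) -> np.ndarray:
    """Truncated exponential kernel weight e^(-d/beta), zero beyond the cutoff."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    r = truncation_radius(beta, quantile)
    return np.where(d <= r, np.exp(-d / beta), 0.0)


def kernel_stencil(
    beta: float, cell_size: float, quantile: float = 0.99, rho: float = 1.0
) -> np.ndarray:
    """Centered 2-D stencil of kernel weights e^(-d/beta) * rho**d.

    Cell (R, R) of the (2R+1)-square stencil is the source cell (d = 0);
    distances are between cell centers. Weights beyond the truncation radius
    are zero.
    """
    r = truncation_radius(beta, quantile)
    ncells = int(math.floor(r / cell_size))
    offsets = np.arange(-ncells, ncells + 1, dtype=float) * cell_size
    d = np.hypot(offsets[:, None], offsets[None, :])
    kern = np.where(d <= r, np.exp(-d / beta), 0.0)
    if rho != 1.0:
        kern *= rho**d
    return kern


def _convolve(grid: np.ndarray, kern: np.ndarray) -> np.ndarray:
    """Sum_j grid_j * kern(d_ij) for every cell i (kernel is symmetric)."""
    out = fftconvolve(grid, kern, mode="same")
    # FFT round-off can leave tiny negatives on zero regions
    np.maximum(out, 0.0, out=out)
    return out


@dataclass
class ForagerField:
    """Foraging-bee counts per cell for one period (queens or p_w * workers)."""

    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if np.any(self.X < 0):
            raise ValueError("forager counts must be non-negative")


@dataclass
class VisitationRaster:
    """Total visits received per cell, plus visits per unit flowering area."""

    V: np.ndarray
    per_flower: np.ndarray = field(default=None)  # type: ignore[assignment]

    def total(self) -> float:
        return float(self.V.sum())


def visitation_rates(
    X: np.ndarray,
    F: np.ndarray,
    params: ModelParams,
    cell_size: float = 25.0,
    cover: np.ndarray | None = None,
) -> VisitationRaster:
    """Visits received per cell from all foragers (truncated-kernel Eq. above).

    A source cell whose whole normalization sum is zero (no reachable flowers)
    contributes no visits. If ``cover`` (flowering-area proportion) is given,
    the per-flower rate V / (cover * cell area in ha) is filled in where
    cover > 0.
    """
    X = np.asarray(X, dtype=float)
    F = np.asarray(F, dtype=float)
    if X.shape != F.shape:
        raise ValueError("forager and floral grids must be congruent")
    if np.any(X < 0) or np.any(F < 0):
        raise ValueError("forager counts and floral values must be non-negative")
    kern = kernel_stencil(params.beta, cell_size, params.kernel_quantile)
    Z = _convolve(F, kern)  # normalization per source cell
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(Z > 0, X / Z, 0.0)
    if params.rho_F != 1.0:
        kern = kernel_stencil(
            params.beta, cell_size, params.kernel_quantile, rho=params.rho_F
        )
    V = F * _convolve(S, kern)
    per_flower = None
    if cover is not None:
        area_ha = cover * (cell_size**2 / 1e4)
        per_flower = np.where(area_ha > 0, V / np.where(area_ha > 0, area_ha, 1.0), 0.0)
    return VisitationRaster(V=V, per_flower=per_flower)


def resources_per_nest(
    X: np.ndarray,
    N: np.ndarray,
    F: np.ndarray,
    params: ModelParams,
    cell_size: float = 25.0,
) -> np.ndarray:
    """Resources collected per nest: (X_i/N_i) * kernel-weighted mean F around i.

    Cells with no nests (N = 0) collect nothing; N = 0 where X > 0 is an
    error (foragers must nest somewhere).
    """
    X = np.asarray(X, dtype=float)
    N = np.asarray(N, dtype=float)
    F = np.asarray(F, dtype=float)
    if not (X.shape == N.shape == F.shape):
        raise ValueError("grids must be congruent")
    if np.any(X < 0) or np.any(F < 0):
        raise ValueError("inputs must be non-negative")
    if np.any((N <= 0) & (X > 0)):
        raise ValueError("foragers present in cells without nests (N = 0, X > 0)")
    kern = kernel_stencil(params.beta, cell_size, params.kernel_quantile)
    num = _convolve(F, kern)
    den = _convolve(np.ones_like(F), kern)
    per_forager = num / den  # den >= kern[center] = 1 everywhere
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(N > 0, X / np.where(N > 0, N, 1.0), 0.0)
    return ratio * per_forager
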