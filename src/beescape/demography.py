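"""Colony growth within a season and queen survival/dispersal between seasons.

Within a season, resources map to offspring through a saturating response: the
CDF of a lognormal distribution parameterized by its *median* a (resources at
which half the maximum output is produced) and *variance* b (steepness).
Workers raised per queen are W = Q * w_max * G(R1, a_w, b_w); new queens per
colony are Q_E = Q * q_max * G(R2, a_q, b_q), with period-2 foragers being the
fraction p_w of the workers.

Between seasons, new queens overwinter in their natal cell and then fly to
nesting sites following an exponential kernel with mean distance beta_nest,
weighted by how attractive destinations are for nesting. Expected arrivals are
truncated at the cell's nesting capacity (density-dependent mortality among
nest-searching queens) and realized as independent Poisson draws, the model's
only source of stochasticity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import lognorm

from .foraging import kernel_stencil, resources_per_nest, _convolve
from .params import ModelParams

__all__ = [
    "ColonyState",
    "lognormal_sigma2",
    "growth_cdf",
    "worker_growth",
    "queen_production",
    "expected_settlement",
    "overwinter_disperse",
]

logger = logging.getLogger(__name__)


@dataclass
class ColonyState:
    """Population rasters for one season.

    Q: founding queens (= nests, one queen each) in period 1; W: workers in
    period 2; Q_E: new queens at the end of the season.
    """

    Q: np.ndarray
    W: np.ndarray = field(default=None)  # type: ignore[assignment]
    Q_E: np.ndarray = field(default=None)  # type: ignore[assignment]


def lognormal_sigma2(a: float, b: float) -> float:
    """Log-scale variance sigma^2 of the lognormal with median ``a``, variance ``b``.

    With mu = ln(a), the variance is (e^(s) - 1) * e^(2*mu + s) for s = sigma^2;
    the unique root is bracketed and solved to ~1e-12 relative accuracy.
    """
    if a <= 0 or b <= 0:
        raise ValueError("median a and variance b must be positive")
    mu2 = 2.0 * math.log(a)

    def f(s: float) -> float:
        return math.expm1(s) * math.exp(mu2 + s) - b

    lo, hi = 1e-12, 50.0
    if f(lo) > 0:  # variance already above b at the smallest bracket
        return lo
    return brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)


def growth_cdf(R: float | np.ndarray, a: float, b: float) -> np.ndarray:
    """Saturating growth response: lognormal CDF with median ``a``, variance ``b``.

    G(0) = 0, G(a) = 0.5 exactly, G strictly increasing toward 1.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("resources must be non-negative")
    sigma = math.sqrt(lognormal_sigma2(a, b))
    return lognorm.cdf(R, s=sigma, scale=a)


def worker_growth(Q: np.ndarray, R1: np.ndarray, params: ModelParams) -> np.ndarray:
    """Workers raised per cell: W = Q * w_max * G(R1, a_w, b_w)."""
    Q = np.asarray(Q, dtype=float)
    R1 = np.asarray(R1, dtype=float)
    if Q.shape != R1.shape:
        raise ValueError("grids must be congruent")
    if np.any(Q < 0):
        raise ValueError("queen counts must be non-negative")
    return Q * params.w_max * growth_cdf(R1, params.a_w, params.b_w)


def queen_production(
    Q: np.ndarray,
    W: np.ndarray,
    F2: np.ndarray,
    params: ModelParams,
    cell_size: float = 25.0,
) -> tuple[np.ndarray, np.ndarray]:
    """New queens per cell at season end.

    Period-2 foragers are X2 = p_w * W; resources per colony R2 follow the
    collected-resources rule with N = Q nests per cell; output saturates at
    q_max per colony. Returns ``(Q_E, R2)``.
    """
    Q = np.asarray(Q, dtype=float)
    W = np.asarray(W, dtype=float)
    X2 = params.p_w * W
    R2 = resources_per_nest(X2, Q, F2, params, cell_size)
    Q_E = Q * params.q_max * growth_cdf(R2, params.a_q, params.b_q)
    return Q_E, R2


def expected_settlement(
    Q_E: np.ndarray,
    dest_weight: np.ndarray,
    params: ModelParams,
    cell_size: float = 25.0,
) -> np.ndarray:
    """Expected queen arrivals per cell before density-dependent truncation.

    A_i = w_i * sum_j Q_E,j * e^(-d_ij/beta_nest) * rho_N**d_ij
                / sum_q w_q * e^(-d_qj/beta_nest)

    with destination weight w. Queens from source cells whose whole reachable
    weight is zero are lost (logged at DEBUG), mirroring queens that never find
    a nest site.
    """
    Q_E = np.asarray(Q_E, dtype=float)
    w = np.asarray(dest_weight, dtype=float)
    if Q_E.shape != w.shape:
        raise ValueError("grids must be congruent")
    if np.any(Q_E < 0) or np.any(w < 0):
        raise ValueError("inputs must be non-negative")
    kern = kernel_stencil(params.beta_nest, cell_size, params.kernel_quantile)
    Z = _convolve(w, kern)
    lost = float(Q_E[(Z <= 0) & (Q_E > 0)].sum())
    if lost > 0:
        logger.debug("%.3f queens found no reachable nesting habitat", lost)
    S = np.where(Z > 0, Q_E / np.where(Z > 0, Z, 1.0), 0.0)
    if params.rho_N != 1.0:
        kern = kernel_stencil(
            params.beta_nest, cell_size, params.kernel_quantile, rho=params.rho_N
        )
    return w * _convolve(S, kern)


def overwinter_disperse(
    Q_E: np.ndarray,
    nest_capacity: np.ndarray,
    params: ModelParams,
    rng: np.random.Generator,
    cell_size: float = 25.0,
    dest_weight: np.ndarray | None = None,
) -> np.ndarray:
    """Next spring's founding queens: disperse, truncate at capacity, Poisson.

    ``dest_weight`` defaults to the nesting-capacity raster (queens settle
    preferentially where nesting resources are); pass the current queen raster
    for the literal self-weighted variant. Expected arrivals are first capped
    at ``nest_capacity`` cellwise, then each cell's colony count is drawn from
    an independent Poisson with that intensity.
    """
    nest_capacity = np.asarray(nest_capacity, dtype=float)
    if np.any(nest_capacity < 0):
        raise ValueError("nest capacity must be non-negative")
    w = nest_capacity if dest_weight is None else np.asarray(dest_weight, dtype=float)
    A = expected_settlement(Q_E, w, params, cell_size)
    A = np.minimum(A, nest_capacity)
    return rng.poisson(A).astype(float)
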