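"""Scalar model parameters for the bumble bee pollinator model.

Defaults describe common early-active bumble bees (e.g. *Bombus terrestris*
group): queens forage alone in the early floral period, a fraction ``p_w`` of
the workers they raise forages in the late period, and colony output saturates
at ``w_max`` workers and ``q_max`` new queens per founding queen.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ModelParams:
    """All scalar parameters of the foraging / demography model.

    Attributes
    ----------
    n_max : float
        Nest density (nests/ha) in a cell of maximum nesting quality.
    beta : float
        Mean foraging dispersal distance (m) of the exponential kernel.
    beta_nest : float
        Mean dispersal distance (m) of new queens flying to nesting sites;
        roughly twice the foraging distance.
    a_w, b_w : float
        Median and variance of the lognormal worker growth function: resources
        a queen must gather to raise half of ``w_max`` workers, and the
        steepness of that response. ``b_w`` defaults to ``2 * a_w``.
    a_q, b_q : float
        Same for new-queen production; ``a_q`` is a calibration constant
        keeping realistic landscapes neither empty nor saturated.
    w_max : float
        Maximum workers produced per queen.
    q_max : float
        Maximum new queens produced per colony.
    p_w : float
        Proportion of workers that forage in the late period.
    rho_F, rho_N : float
        Per-meter survival while foraging / while flying to nesting sites,
        compounded over distance (``rho ** d``). 1.0 disables en-route
        mortality.
    kernel_quantile : float
        Quantile of the exponential distance kernel beyond which the kernel is
        truncated to zero (computational cutoff).
    """

    n_max: float = 19.6
    beta: float = 530.0
    beta_nest: float = 1000.0
    a_w: float = 100.0
    b_w: float = field(default=-1.0)
    a_q: float = 15000.0
    b_q: float = field(default=-1.0)
    w_max: float = 600.0
    q_max: float = 160.0
    p_w: float = 0.5
    rho_F: float = 1.0
    rho_N: float = 1.0
    kernel_quantile: float = 0.99

    def __post_init__(self) -> None:
        # variance defaults to twice the median
        if self.b_w <= 0:
            object.__setattr__(self, "b_w", 2.0 * self.a_w)
        if self.b_q <= 0:
            object.__setattr__(self, "b_q", 2.0 * self.a_q)
        if self.a_w <= 0 or self.a_q <= 0:
            raise ValueError("growth medians a_w, a_q must be positive")
        if self.beta <= 0 or self.beta_nest <= 0:
            raise ValueError("dispersal distances must be positive")
        if not 0.0 <= self.p_w <= 1.0:
            raise ValueError("p_w must lie in [0, 1]")
        for name in ("rho_F", "rho_N"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0.0 < self.kernel_quantile < 1.0:
            raise ValueError("kernel_quantile must lie in (0, 1)")
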