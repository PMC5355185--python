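"""Multi-year simulation driver and response-variable aggregation.

A run replays a rotation of landscape-years for ``n_cycles`` cycles (default
5 x 7 = 35 years), preceded by a burn-in of baseline-scenario cycles that
levels off the population after initialization. Each year executes one season:

    queens forage (period 1) -> workers raised -> a fraction of workers
    forages (period 2) -> new queens produced -> overwinter dispersal,
    density-dependent settlement, Poisson realization -> next year's queens.

Response variables are aggregated inside a circular buffer around the raster
center: colonies per hectare, mean workers and new queens per colony,
visitation per unit flower area for each period (also restricted to non-strip
flowers), and mean visitation per hectare of oilseed rape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import overwinter_disperse, queen_production, worker_growth
from .foraging import resources_per_nest, visitation_rates
from .landscapes import buffer_mask, landscape_covariates
from .management import Scenario, apply_scenario, place_flower_strips
from .params import ModelParams
from .resources import LandscapeYear, ResourceLookup, ResourceRasters

__all__ = [
    "SimulationConfig",
    "SeasonResult",
    "initialize_population",
    "run_season",
    "run_simulation",
    "scenario_compare",
    "log_response_ratio",
    "RESPONSE_COLUMNS",
]

logger = logging.getLogger(__name__)

RESPONSE_COLUMNS = [
    "year",
    "map_index",
    "colonies_per_ha",
    "mean_workers_per_colony",
    "mean_queens_per_colony",
    "visit_per_flower_p1",
    "visit_per_flower_p2",
    "visit_per_flower_p2_nonstrip",
    "osr_visitation_per_ha",
    "osr_area_ha",
    "edge_area_ha",
]


@dataclass
class SimulationConfig:
    """Everything one multi-year run needs."""

    rotation: list[LandscapeYear]
    lut: ResourceLookup
    params: ModelParams = field(default_factory=ModelParams)
    scenario: Scenario = field(default_factory=Scenario)
    n_cycles: int = 5
    burn_in_cycles: int = 1
    seed: int = 0
    buffer_radius: float = 3000.0
    init_fill: float = 0.5

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 0.0 < self.init_fill <= 1.0:
            raise ValueError("init_fill must lie in (0, 1]")
        land = self.rotation[0]
        half_extent = min(land.landuse.shape) * land.cell_size / 2.0
        if self.buffer_radius > half_extent:
            raise ValueError(
                f"buffer radius {self.buffer_radius} m exceeds half the raster "
                f"extent ({half_extent} m)"
            )


@dataclass
class SeasonResult:
    """All rasters produced by one season."""

    Q: np.ndarray
    W: np.ndarray
    Q_E: np.ndarray
    R1: np.ndarray
    R2: np.ndarray
    V1: np.ndarray
    V2: np.ndarray
    per_flower1: np.ndarray
    per_flower2: np.ndarray
    Q_next: np.ndarray


def initialize_population(
    capacity: np.ndarray, init_fill: float, rng: np.random.Generator
) -> np.ndarray:
    """Initial founding queens: Poisson(init_fill * capacity) per cell."""
    if not 0.0 < init_fill <= 1.0:
        raise ValueError("init_fill must lie in (0, 1]")
    return rng.poisson(init_fill * np.asarray(capacity, dtype=float)).astype(float)


def run_season(
    Q: np.ndarray,
    res: ResourceRasters,
    params: ModelParams,
    rng: np.random.Generator,
    cell_size: float = 25.0,
) -> SeasonResult:
    """Execute one full season from founding queens to next year's queens."""
    Q = np.asarray(Q, dtype=float)
    vis1 = visitation_rates(Q, res.F[1], params, cell_size, cover=res.cover[1])
    R1 = resources_per_nest(Q, Q, res.F[1], params, cell_size)
    W = worker_growth(Q, R1, params)
    X2 = params.p_w * W
    vis2 = visitation_rates(X2, res.F[2], params, cell_size, cover=res.cover[2])
    Q_E, R2 = queen_production(Q, W, res.F[2], params, cell_size)
    Q_next = overwinter_disperse(Q_E, res.nest_capacity, params, rng, cell_size)
    return SeasonResult(
        Q=Q,
        W=W,
        Q_E=Q_E,
        R1=R1,
        R2=R2,
        V1=vis1.V,
        V2=vis2.V,
        per_flower1=vis1.per_flower,
        per_flower2=vis2.per_flower,
        Q_next=Q_next,
    )


def _responses(
    season: SeasonResult,
    res: ResourceRasters,
    land: LandscapeYear,
    lut: ResourceLookup,
    mask: np.ndarray,
    buffer_radius: float,
) -> dict[str, float]:
    cell_ha = land.cell_area_ha
    buffer_ha = float(mask.sum()) * cell_ha
    tot_q = float(season.Q[mask].sum())

    def per_colony(x: np.ndarray) -> float:
        return float(x[mask].sum()) / tot_q if tot_q > 0 else 0.0

    def per_flower(V: np.ndarray, cover: np.ndarray, keep: np.ndarray) -> float:
        area = float((cover * cell_ha)[keep].sum())
        return float(V[keep].sum()) / area if area > 0 else 0.0

    osr = (land.landuse == lut.code_of("oilseed_rape")) & ~res.strip_mask
    osr_in = osr & mask
    osr_area = float(osr_in.sum()) * cell_ha
    osr_visits = float(season.V1[osr_in].sum()) / osr_area if osr_area > 0 else 0.0
    osr_area_ha, edge_area_ha = landscape_covariates(land, lut, buffer_radius)
    return {
        "colonies_per_ha": tot_q / buffer_ha,
        "mean_workers_per_colony": per_colony(season.W),
        "mean_queens_per_colony": per_colony(season.Q_E),
        "visit_per_flower_p1": per_flower(season.V1, res.cover[1], mask),
        "visit_per_flower_p2": per_flower(season.V2, res.cover[2], mask),
        "visit_per_flower_p2_nonstrip": per_flower(
            season.V2, res.cover[2], mask & ~res.strip_mask
        ),
        "osr_visitation_per_ha": osr_visits,
        "osr_area_ha": osr_area_ha,
        "edge_area_ha": edge_area_ha,
    }


def run_simulation(
    config: SimulationConfig, save_rasters: "str | None" = None
) -> pd.DataFrame:
    """Run burn-in plus the treated multi-year simulation.

    Burn-in always uses the baseline scenario and the population carries over
    into the treated years, so with a shared seed all scenarios of the same
    landscape start their first treated year with identical colonies.
    Returns one row per treated year (``n_cycles * len(rotation)`` rows).
    ``save_rasters`` names a directory for per-year TIFF stacks
    (Q, W, Q_E, V1, V2 bands).
    """
    rng = np.random.default_rng(config.seed)
    land0 = config.rotation[0]
    cell_size = land0.cell_size
    mask = buffer_mask(land0.landuse.shape, config.buffer_radius, cell_size)

    baseline = Scenario()
    # cache resources + strip placements per rotation index and scenario
    base_res = [
        apply_scenario(land, config.lut, baseline, config.params)
        for land in config.rotation
    ]
    if config.scenario == baseline:
        treat_res = base_res
    else:
        strip_masks = [
            place_flower_strips(land, config.lut, config.scenario, config.params)
            for land in config.rotation
        ]
        treat_res = [
            apply_scenario(
                land, config.lut, config.scenario, config.params, strip_mask=sm
            )
            for land, sm in zip(config.rotation, strip_masks)
        ]

    Q = initialize_population(base_res[0].nest_capacity, config.init_fill, rng)
    for cycle in range(config.burn_in_cycles):
        for i, land in enumerate(config.rotation):
            season = run_season(Q, base_res[i], config.params, rng, cell_size)
            Q = season.Q_next
    logger.info("burn-in finished: %.0f colonies", Q.sum())

    rows = []
    year = 0
    for cycle in range(config.n_cycles):
        for i, land in enumerate(config.rotation):
            year += 1
            season = run_season(Q, treat_res[i], config.params, rng, cell_size)
            row = {"year": year, "map_index": i}
            row.update(
                _responses(
                    season, treat_res[i], land, config.lut, mask, config.buffer_radius
                )
            )
            rows.append(row)
            if save_rasters is not None:
                from pathlib import Path

                from . import gridio

                outdir = Path(save_rasters)
                outdir.mkdir(parents=True, exist_ok=True)
                gridio.write_tiff(
                    outdir / f"state_y{year:03d}.tif",
                    season.Q, season.W, season.Q_E, season.V1, season.V2,
                )
            logger.info(
                "year %d: %.0f colonies, %.0f workers, %.0f new queens",
                year,
                season.Q.sum(),
                season.W.sum(),
                season.Q_E.sum(),
            )
            if season.Q.sum() == 0:
                logger.warning("population extinct in year %d", year)
            Q = season.Q_next
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def scenario_compare(
    rotation: list[LandscapeYear],
    lut: ResourceLookup,
    params: ModelParams | None = None,
    scenarios: list[Scenario] | None = None,
    **config_kw,
) -> pd.DataFrame:
    """Run the management factorial on one landscape; tidy long-format output.

    All scenarios share the seed (hence the burn-in trajectory), mirroring a
    controlled experiment on the same landscape.
    """
    params = params or ModelParams()
    if scenarios is None:
        scenarios = [
            Scenario(margins_widened=m, flower_strips=s)
            for m in (False, True)
            for s in (False, True)
        ]
    frames = []
    for sc in scenarios:
        cfg = SimulationConfig(
            rotation=rotation, lut=lut, params=params, scenario=sc, **config_kw
        )
        df = run_simulation(cfg)
        long = df.melt(
            id_vars=["year", "map_index"], var_name="response", value_name="value"
        )
        long.insert(0, "scenario", sc.name)
        frames.append(long)
    return pd.concat(frames, ignore_index=True)


def log_response_ratio(
    treatment: np.ndarray | pd.Series, baseline: np.ndarray | pd.Series
) -> np.ndarray:
    """Elementwise log10(treatment / baseline); NaN (with warning) where baseline <= 0."""
    treatment = np.asarray(treatment, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    bad = baseline <= 0
    if bad.any():
        logger.warning(
            "log response ratio undefined for %d entries with baseline <= 0",
            int(bad.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log10(treatment / np.where(bad, np.nan, baseline))
    return out
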