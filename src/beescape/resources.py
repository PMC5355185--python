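"""Land-use rasters -> floral and nesting resource rasters.

A landscape-year is described by two congruent 25 m rasters: categorical
land-use/crop codes and meters of field-block edge per cell. A lookup table
maps each land-use code to floral coverage (proportion of area in flower) and
attractiveness (resource units per unit coverage) for each of two floral
periods, plus a nesting-quality score NQ in [0, 1].

Per-cell resources mix the patch land use with the uncultivated grassy margin
habitat that sits on field-block edges, weighting by the fraction of the cell
area the margin occupies: f_edge = min(1, edge_length * margin_width /
cell_area). Margins carry maximum nesting quality and very low floral value,
so widening margins trades a little floral area for nesting habitat.

The floral value of a cell for period k is coverage_k * attractiveness_k; the
nesting capacity is NQ * n_max * cell_area(ha), the expected number of
colonies the cell can hold.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ModelParams

__all__ = [
    "LandscapeYear",
    "ResourceLookup",
    "ResourceRasters",
    "build_floral_raster",
    "build_coverage_raster",
    "build_nesting_raster",
    "build_resources",
    "default_lookup",
    "BASELINE_MARGIN_WIDTH",
]

BASELINE_MARGIN_WIDTH = 2.4  # meters of grassy margin around field blocks

LOOKUP_COLUMNS = [
    "code",
    "name",
    "coverage_p1",
    "coverage_p2",
    "attract_p1",
    "attract_p2",
    "nesting_quality",
    "is_agricultural",
]

# Shipped lookup fixture (Scanian-style mixed farmland). Floral coverages are
# area proportions; attractiveness is in resource units per unit coverage,
# scaled so that early-season resources per queen sit near the worker growth
# median a_w and late-season resources per colony straddle the queen growth
# median a_q: populations are flower-limited late in the season, neither
# extinct nor saturated (see docs/methods.md for the calibration rationale).
# Nesting sites live chiefly in uncultivated field margins (tussocky linear
# habitat, maximum quality); open grassland patches score much lower. Margins
# match cereal floral values ("very low"), so widening margins leaves cereal
# borders unchanged and dilutes mass-flowering crop borders. Flower strips
# uniquely carry maximum late-season attractiveness, negligible nesting.
_DEFAULT_LOOKUP_CSV = """\
code,name,coverage_p1,coverage_p2,attract_p1,attract_p2,nesting_quality,is_agricultural
0,non_habitat,0.0,0.0,0.0,0.0,0.0,0
1,cereal,0.06,0.0,1500.0,0.0,0.10,1
2,oilseed_rape,0.60,0.0,1000.0,0.0,0.10,1
3,ley,0.06,0.10,1500.0,900.0,0.15,1
4,seminatural,0.10,0.10,2000.0,900.0,0.15,0
90,margin,0.06,0.0,1500.0,0.0,1.00,0
91,flower_strip,0.0,0.80,0.0,2000.0,0.05,0
"""


@dataclass
class LandscapeYear:
    """Physical template of one landscape in one year.

    ``landuse`` holds categorical codes, ``edge_length`` meters of field-block
    edge per cell (0 .. 4 * cell_size: up to two crossing borders).
    """

    landuse: np.ndarray
    edge_length: np.ndarray
    cell_size: float = 25.0
    year_index: int = 0

    def __post_init__(self) -> None:
        self.landuse = np.asarray(self.landuse)
        self.edge_length = np.asarray(self.edge_length, dtype=float)
        if self.landuse.shape != self.edge_length.shape:
            raise ValueError("landuse and edge_length grids must be congruent")
        if np.any(self.edge_length < 0):
            raise ValueError("edge_length must be non-negative")
        if np.any(self.edge_length > 4 * self.cell_size + 1e-9):
            raise ValueError("edge_length exceeds geometric maximum 4 * cell_size")

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size**2

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / 1e4


class ResourceLookup:
    """Per-land-use resource scores, indexed by integer code.

    Backed by a DataFrame with columns ``code, name, coverage_p1, coverage_p2,
    attract_p1, attract_p2, nesting_quality, is_agricultural``. Two names are
    special: ``margin`` (grassy field-block margin habitat mixed into edge
    cells) and ``flower_strip`` (the sown strip land use used by management).
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in LOOKUP_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"lookup table missing columns {missing}")
        table = table[LOOKUP_COLUMNS].copy()
        table["code"] = table["code"].astype(int)
        if table["code"].duplicated().any():
            raise ValueError("duplicate land-use codes in lookup table")
        for col in ("coverage_p1", "coverage_p2"):
            if ((table[col] < 0) | (table[col] > 1)).any():
                raise ValueError(f"{col} must lie in [0, 1]")
        if ((table["nesting_quality"] < 0) | (table["nesting_quality"] > 1)).any():
            raise ValueError("nesting_quality must lie in [0, 1]")
        if (table[["attract_p1", "attract_p2"]] < 0).to_numpy().any():
            raise ValueError("attractiveness must be non-negative")
        self.table = table.set_index("code", drop=False)
        self._by_name = {n: int(c) for c, n in zip(table["code"], table["name"])}

    # -- construction ------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path | io.StringIO) -> "ResourceLookup":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    # -- code helpers ------------------------------------------------------
    def code_of(self, name: str) -> int:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no land use named {name!r} in lookup table") from None

    @property
    def margin_code(self) -> int:
        return self.code_of("margin")

    @property
    def strip_code(self) -> int:
        return self.code_of("flower_strip")

    def is_agricultural(self, codes: np.ndarray) -> np.ndarray:
        return self._column(codes, "is_agricultural").astype(bool)

    # -- vectorized column lookup -----------------------------------------
    def _column(self, codes: np.ndarray, column: str) -> np.ndarray:
        codes = np.asarray(codes, dtype=int)
        known = self.table.index.to_numpy()
        unknown = np.setdiff1d(np.unique(codes), known)
        if unknown.size:
            raise KeyError(f"unknown land-use code(s) {unknown.tolist()} in raster")
        dense_size = int(known.max()) + 1
        dense = np.zeros(dense_size, dtype=float)
        dense[known] = self.table[column].to_numpy(dtype=float)
        return dense[codes]

    def coverage(self, codes: np.ndarray, period: int) -> np.ndarray:
        return self._column(codes, f"coverage_p{_check_period(period)}")

    def attractiveness(self, codes: np.ndarray, period: int) -> np.ndarray:
        return self._column(codes, f"attract_p{_check_period(period)}")

    def floral_value(self, codes: np.ndarray, period: int) -> np.ndarray:
        period = _check_period(period)
        return self.coverage(codes, period) * self.attractiveness(codes, period)

    def nesting_quality(self, codes: np.ndarray) -> np.ndarray:
        return self._column(codes, "nesting_quality")

    def scalar(self, code: int, column: str) -> float:
        return float(self._column(np.asarray([code]), column)[0])


@dataclass
class ResourceRasters:
    """Derived per-cell resources for one landscape-year (and scenario).

    ``F[k]`` is floral value (coverage x attractiveness), ``cover[k]`` the
    flowering area proportion (used for per-flower visitation), and
    ``nest_capacity`` the expected maximum number of colonies per cell,
    constant across periods within a year.
    """

    F: dict[int, np.ndarray]
    cover: dict[int, np.ndarray]
    nest_capacity: np.ndarray
    strip_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.strip_mask is None:
            self.strip_mask = np.zeros_like(self.nest_capacity, dtype=bool)


def _check_period(period: int) -> int:
    if period not in (1, 2):
        raise ValueError(f"period must be 1 or 2, got {period!r}")
    return period


def edge_fraction(land: LandscapeYear, margin_width: float) -> np.ndarray:
    """Fraction of each cell's area occupied by grassy margin, capped at 1."""
    if margin_width < 0:
        raise ValueError("margin_width must be non-negative")
    return np.minimum(1.0, land.edge_length * margin_width / land.cell_area_m2)


def _mixed(
    land: LandscapeYear,
    margin_width: float,
    patch_vals: np.ndarray,
    margin_val: float,
) -> np.ndarray:
    f_edge = edge_fraction(land, margin_width)
    return (1.0 - f_edge) * patch_vals + f_edge * margin_val


def build_floral_raster(
    land: LandscapeYear,
    lut: ResourceLookup,
    period: int,
    margin_width: float = BASELINE_MARGIN_WIDTH,
) -> np.ndarray:
    """Floral value per cell for one period: area-weighted patch/margin mix."""
    period = _check_period(period)
    patch = lut.floral_value(land.landuse, period)
    margin = lut.scalar(lut.margin_code, f"coverage_p{period}") * lut.scalar(
        lut.margin_code, f"attract_p{period}"
    )
    return _mixed(land, margin_width, patch, margin)


def build_coverage_raster(
    land: LandscapeYear,
    lut: ResourceLookup,
    period: int,
    margin_width: float = BASELINE_MARGIN_WIDTH,
) -> np.ndarray:
    """Flowering-area proportion per cell (same mixing as the floral raster)."""
    period = _check_period(period)
    patch = lut.coverage(land.landuse, period)
    margin = lut.scalar(lut.margin_code, f"coverage_p{period}")
    return _mixed(land, margin_width, patch, margin)


def build_nesting_raster(
    land: LandscapeYear,
    lut: ResourceLookup,
    params: ModelParams,
    margin_width: float = BASELINE_MARGIN_WIDTH,
) -> np.ndarray:
    """Maximum expected colonies per cell: mixed NQ * n_max * cell_area(ha)."""
    patch = lut.nesting_quality(land.landuse)
    margin = lut.scalar(lut.margin_code, "nesting_quality")
    nq = _mixed(land, margin_width, patch, margin)
    return nq * params.n_max * land.cell_area_ha


def build_resources(
    land: LandscapeYear,
    lut: ResourceLookup,
    params: ModelParams,
    margin_width: float = BASELINE_MARGIN_WIDTH,
    strip_cells: np.ndarray | None = None,
) -> ResourceRasters:
    """Assemble all resource rasters for one landscape-year.

    ``strip_cells`` is an optional boolean mask of cells converted to the
    flower-strip land use before the patch/margin mixing is applied.
    """
    if strip_cells is not None and strip_cells.any():
        landuse = land.landuse.copy()
        landuse[strip_cells] = lut.strip_code
        land = LandscapeYear(landuse, land.edge_length, land.cell_size, land.year_index)
        strip_mask = np.asarray(strip_cells, dtype=bool)
    else:
        strip_mask = np.zeros(land.landuse.shape, dtype=bool)
    return ResourceRasters(
        F={k: build_floral_raster(land, lut, k, margin_width) for k in (1, 2)},
        cover={k: build_coverage_raster(land, lut, k, margin_width) for k in (1, 2)},
        nest_capacity=build_nesting_raster(land, lut, params, margin_width),
        strip_mask=strip_mask,
    )


def default_lookup() -> ResourceLookup:
    """The shipped land-use resource table (see module docstring)."""
    return ResourceLookup.from_csv(io.StringIO(_DEFAULT_LOOKUP_CSV))
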