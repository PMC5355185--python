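"""Synthetic agricultural landscapes: field blocks, crop rotations, edges.

Emulates the structure of intensively farmed southern-Swedish landscapes: the
square extent is tessellated into rectangular field blocks (mean area set by
``mean_field_size``); each block is seminatural grassland, non-habitat or
arable; arable blocks carry a cyclic crop rotation in which oilseed rape (OSR)
appears in randomly chosen years so that the expected yearly OSR share of
arable land matches ``osr_target`` while the crop moves between blocks from
year to year. The edge raster stores meters of field-block border per
agricultural cell: every cell side facing a different block (or non-arable
land) contributes one cell side of edge, which is where grassy margins sit.

Seminatural grassland is not scattered uniformly: a smooth random field
modulates the per-block probability (``seminatural_clustering``), creating
mixed farmland regions rich in permanent habitat next to open arable plains,
as in southern-Swedish agricultural landscapes. This regional structure is
what makes parts of a landscape flower-limited and hence responsive to
management.

Varying ``mean_field_size`` sweeps structural heterogeneity (total edge), and
``osr_target`` sweeps mass-flowering crop cover; the two controls are
independent, producing uncorrelated gradients across an ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .resources import BASELINE_MARGIN_WIDTH, LandscapeYear, ResourceLookup

__all__ = ["LandscapeSpec", "generate_landscape", "landscape_covariates", "buffer_mask"]

# land-use codes matching resources.default_lookup()
NON_HABITAT, CEREAL, OSR, LEY, SEMINATURAL = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class LandscapeSpec:
    """Knobs of the landscape generator.

    extent: side length (m) of the square raster; must contain the analysis
    buffer. mean_field_size: mean field-block area (ha); smaller blocks mean
    more edges (higher structural heterogeneity). osr_target: expected yearly
    proportion of arable land in oilseed rape. seminatural_frac /
    non_habitat_frac: probability a block is permanent grassland / unusable.
    """

    extent: float = 10000.0
    mean_field_size: float = 12.0
    osr_target: float = 0.10
    seminatural_frac: float = 0.10
    non_habitat_frac: float = 0.03
    ley_frac: float = 0.25  # share of non-OSR arable years in ley
    seminatural_clustering: float = 6.0  # 0 = uniform scatter
    ley_phase_years: int = 2  # consecutive ley years per participating block
    ley_year_alpha: float = 0.5  # Dirichlet conc. of ley phase starts; small = boom/bust
    rotation_length: int = 7
    cell_size: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.osr_target <= 0.5:
            raise ValueError("osr_target must lie in [0, 0.5]")
        n = self.extent / self.cell_size
        if abs(n - round(n)) > 1e-9:
            raise ValueError("extent must be a multiple of cell_size")
        if self.mean_field_size <= 0:
            raise ValueError("mean_field_size must be positive")

    @property
    def n_cells(self) -> int:
        return int(round(self.extent / self.cell_size))


def _block_grid(spec: LandscapeSpec, rng: np.random.Generator) -> np.ndarray:
    """Rectangular 'brick' tessellation: block id per cell."""
    n = spec.n_cells
    side = np.sqrt(spec.mean_field_size * 1e4) / spec.cell_size  # cells
    side = max(side, 1.0)

    def cuts(length: int) -> np.ndarray:
        # cumulative random segment lengths around the target side
        out = [0]
        while out[-1] < length:
            step = max(1, int(round(rng.uniform(0.6, 1.4) * side)))
            out.append(min(length, out[-1] + step))
        return np.asarray(out)

    blocks = np.zeros((n, n), dtype=int)
    next_id = 0
    row_cuts = cuts(n)
    for r0, r1 in zip(row_cuts[:-1], row_cuts[1:]):
        col_cuts = cuts(n)
        for c0, c1 in zip(col_cuts[:-1], col_cuts[1:]):
            blocks[r0:r1, c0:c1] = next_id
            next_id += 1
    return blocks


def _edge_raster(
    blocks: np.ndarray, agricultural: np.ndarray, cell_size: float
) -> np.ndarray:
    """Meters of field-block edge per agricultural cell.

    A cell side counts if the cell is agricultural and faces non-agricultural
    land or the outside of the raster. A border between two agricultural
    blocks is a single shared margin strip, so it is booked once, to the
    upper/left cell only.
    """
    edge_sides = np.zeros(blocks.shape, dtype=float)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        nb_block = np.roll(blocks, shift, axis=axis)
        nb_ag = np.roll(agricultural, shift, axis=axis)
        if shift == -1:  # neighbor below/right: shared ag-ag border booked here
            differs = ~nb_ag | (nb_ag & (nb_block != blocks))
        else:  # neighbor above/left: only non-agricultural boundaries
            differs = ~nb_ag
        # rolled-over border cells face the outside: always an edge
        if axis == 0:
            sl = (0 if shift == 1 else -1, slice(None))
        else:
            sl = (slice(None), 0 if shift == 1 else -1)
        differs[sl] = True
        edge_sides += differs
    edge_sides[~agricultural] = 0.0
    return edge_sides * cell_size


def _seminatural_probability(
    spec: LandscapeSpec, blocks: np.ndarray, n_blocks: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-block seminatural probability, spatially clustered.

    A coarse Gaussian field bilinearly interpolated to block centroids is
    rank-scaled to [0, 1] and raised to ``seminatural_clustering``; the mean
    probability stays at ``seminatural_frac``. Clustering 0 gives a uniform
    scatter; larger values concentrate permanent habitat in fewer regions,
    leaving open arable plains elsewhere.
    """
    if spec.seminatural_clustering <= 0:
        return np.full(n_blocks, spec.seminatural_frac)
    coarse = rng.standard_normal((5, 5))
    n = blocks.shape[0]
    # block centroids in units of the coarse grid
    cy = np.zeros(n_blocks)
    cx = np.zeros(n_blocks)
    counts = np.bincount(blocks.ravel(), minlength=n_blocks).astype(float)
    np.add.at(cy, blocks.ravel(), np.repeat(np.arange(n), n))
    np.add.at(cx, blocks.ravel(), np.tile(np.arange(n), n))
    cy, cx = cy / counts, cx / counts
    gy = cy / max(n - 1, 1) * 4.0
    gx = cx / max(n - 1, 1) * 4.0
    y0 = np.clip(gy.astype(int), 0, 3)
    x0 = np.clip(gx.astype(int), 0, 3)
    fy, fx = gy - y0, gx - x0
    g = (
        coarse[y0, x0] * (1 - fy) * (1 - fx)
        + coarse[y0 + 1, x0] * fy * (1 - fx)
        + coarse[y0, x0 + 1] * (1 - fy) * fx
        + coarse[y0 + 1, x0 + 1] * fy * fx
    )
    z = np.argsort(np.argsort(g)) / max(n_blocks - 1, 1)  # rank in [0, 1]
    w = z**spec.seminatural_clustering
    if w.mean() <= 0:
        return np.full(n_blocks, spec.seminatural_frac)
    p = np.clip(spec.seminatural_frac * w / w.mean(), 0.0, 0.95)
    # every landscape keeps one compact seminatural complex (the blocks at the
    # top of the field): a permanent refugium, as in real mixed farmland
    p[z > 0.985] = np.maximum(p[z > 0.985], 0.85)
    return p


def generate_landscape(spec: LandscapeSpec) -> list[LandscapeYear]:
    """Generate one rotation (``rotation_length`` years) of landscape rasters.

    Deterministic in ``spec.seed``. Block geometry and the arable /
    seminatural / non-habitat partition are fixed across years; crops rotate.
    """
    rng = np.random.default_rng(spec.seed)
    blocks = _block_grid(spec, rng)
    n_blocks = blocks.max() + 1

    p_semin = _seminatural_probability(spec, blocks, n_blocks, rng)
    u = rng.random(n_blocks)
    block_class = np.where(
        u < p_semin,
        SEMINATURAL,
        np.where(u < p_semin + spec.non_habitat_frac, NON_HABITAT, -1),
    )  # -1 = arable
    arable_blocks = np.nonzero(block_class == -1)[0]

    # Per-block crop calendar over the rotation. Ley occupies a phase of
    # consecutive years whose start year is drawn from a landscape-level
    # Dirichlet weight vector: uneven weights synchronize rotations across
    # blocks, so total flowering-ley cover fluctuates strongly between years
    # (mass-flowering boom/bust), while the long-run ley share stays at
    # ley_frac. OSR years are drawn among the remaining (cereal) years.
    L = spec.rotation_length
    lam = min(L * spec.osr_target, L)  # expected OSR years per block
    n_osr = int(np.floor(lam)) + (rng.random(arable_blocks.size) < (lam % 1.0))
    phase = min(spec.ley_phase_years, L)
    p_ley_block = min(1.0, spec.ley_frac * L / phase)
    ley_start_w = rng.dirichlet(np.full(L, spec.ley_year_alpha))
    in_ley = rng.random(arable_blocks.size) < p_ley_block
    calendar = np.empty((n_blocks, L), dtype=int)
    calendar[:] = NON_HABITAT
    for b, m, has_ley in zip(arable_blocks, n_osr, in_ley):
        crops = np.full(L, CEREAL)
        if has_ley:
            start = rng.choice(L, p=ley_start_w)
            crops[(start + np.arange(phase)) % L] = LEY
        non_ley = np.nonzero(crops != LEY)[0]
        m = min(int(m), non_ley.size)
        if m > 0:
            crops[rng.choice(non_ley, size=m, replace=False)] = OSR
        calendar[b] = crops
    for b in np.nonzero(block_class >= 0)[0]:
        calendar[b] = block_class[b]

    agricultural = (block_class == -1)[blocks]
    edges = _edge_raster(blocks, agricultural, spec.cell_size)

    years = []
    for y in range(L):
        landuse = calendar[:, y][blocks]
        years.append(
            LandscapeYear(
                landuse=landuse,
                edge_length=edges,
                cell_size=spec.cell_size,
                year_index=y,
            )
        )
    return years


def buffer_mask(
    shape: tuple[int, int], buffer_radius: float, cell_size: float = 25.0
) -> np.ndarray:
    """Cells whose centers lie within ``buffer_radius`` of the raster center."""
    rows = (np.arange(shape[0]) + 0.5) * cell_size
    cols = (np.arange(shape[1]) + 0.5) * cell_size
    cy, cx = shape[0] * cell_size / 2.0, shape[1] * cell_size / 2.0
    d2 = (rows[:, None] - cy) ** 2 + (cols[None, :] - cx) ** 2
    return d2 <= buffer_radius**2


def landscape_covariates(
    land: LandscapeYear,
    lut: ResourceLookup,
    buffer_radius: float,
    margin_width: float = BASELINE_MARGIN_WIDTH,
) -> tuple[float, float]:
    """(OSR area, edge area) in hectares within the central circular buffer.

    OSR area counts oilseed-rape cells; edge area is total edge length times
    the margin width (the paper's structural-heterogeneity covariate HET).
    """
    mask = buffer_mask(land.landuse.shape, buffer_radius, land.cell_size)
    osr_code = lut.code_of("oilseed_rape")
    osr_area = float((land.landuse[mask] == osr_code).sum()) * land.cell_area_ha
    edge_area = float(land.edge_length[mask].sum()) * margin_width / 1e4
    return osr_area, edge_area
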