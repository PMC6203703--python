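"""Richness, rarity-weighted richness, and core areas on an analysis grid.

Observed patterns are computed on a coarse (1° by default) cell grid:
species richness is the number of species occupying a cell, rarity-weighted
richness (RWR) weights each species by the inverse of the number of cells it
occupies (so each species contributes total mass 1 across the map). Core
areas are connected blocks of high-value cells: the top 20% of occupied
cells for richness, cells scoring at least 0.7 for RWR, with at least two
cells connected under rook (edge) adjacency.

Predicted richness comes from stacking (summing) per-species binary
suitability maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster_core import AlignmentError, GridSpec, OccurrenceSet, RasterLayer

__all__ = [
    "CellPresence",
    "CoreArea",
    "occurrences_to_cell_presence",
    "species_richness",
    "rarity_weighted_richness",
    "core_areas",
    "stack_binary_maps",
]


@dataclass
class CellPresence:
    """Which grid cells each species occupies."""

    grid: GridSpec
    presence: dict[str, set[tuple[int, int]]] = field(default_factory=dict)


@dataclass
class CoreArea:
    """A connected block of qualifying cells, ranked by summed value."""

    cells: frozenset
    total_value: float
    rank: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def occurrences_to_cell_presence(occ: OccurrenceSet, grid: GridSpec) -> CellPresence:
    """A species occupies a cell iff at least one record falls in it
    (floor-based containing-cell assignment; duplicates collapse).
    Records outside the grid are ignored."""
    pres: dict[str, set[tuple[int, int]]] = {}
    for sp, lon, lat in occ.records[["species", "lon", "lat"]].itertuples(index=False):
        row, col = grid.cell_of(float(lon), float(lat))
        if grid.contains_cell(row, col):
            pres.setdefault(sp, set()).add((row, col))
    return CellPresence(grid=grid, presence=pres)


def species_richness(presence: CellPresence) -> RasterLayer:
    """Cell value = number of species occupying the cell."""
    grid = presence.grid
    values = np.zeros((grid.n_rows, grid.n_cols))
    for cells in presence.presence.values():
        for row, col in cells:
            values[row, col] += 1
    return RasterLayer(grid, values, name="species_richness")


def rarity_weighted_richness(presence: CellPresence) -> RasterLayer:
    """Cell score = Σ over species present of 1/(number of cells the
    species occupies); total mass over the map equals the species count."""
    grid = presence.grid
    values = np.zeros((grid.n_rows, grid.n_cols))
    for cells in presence.presence.values():
        if not cells:
            raise ValueError("every species must occupy at least one cell")
        w = 1.0 / len(cells)
        for row, col in cells:
            values[row, col] += w
    return RasterLayer(grid, values, name="rwr")


_ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
_QUEEN = np.ones((3, 3), dtype=int)


def core_areas(
    layer: RasterLayer,
    mode: str = "richness",
    top_fraction: float = 0.2,
    rwr_cut: float = 0.7,
    min_cells: int = 2,
    adjacency: str = "rook",
) -> list[CoreArea]:
    """Connected blocks of high-value cells, ranked by summed value.

    richness mode: qualifying cells are occupied cells (value > 0) at or
    above the (1 − top_fraction) percentile of occupied-cell values. rwr
    mode: cells scoring at least ``rwr_cut``. Components smaller than
    ``min_cells`` are dropped; ties in summed value break toward the
    westernmost, then southernmost member cell.
    """
    values = layer.values
    valid = layer.valid_mask
    if mode == "richness":
        occupied = valid & (values > 0)
        if not occupied.any():
            return []
        cut = np.percentile(values[occupied], 100 * (1 - top_fraction))
        qualify = occupied & (values >= cut)
    elif mode == "rwr":
        qualify = valid & (values >= rwr_cut)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    structure = _ROOK if adjacency == "rook" else _QUEEN
    labels, n = ndimage.label(qualify, structure=structure)
    areas = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        if rows.size < min_cells:
            continue
        cells = frozenset(zip(rows.tolist(), cols.tolist()))
        total = float(values[rows, cols].sum())
        # tie-break key: westernmost (min col), then southernmost (max row)
        west = int(cols.min())
        south = int(rows.max())
        areas.append((total, west, -south, CoreArea(cells=cells, total_value=total)))
    areas.sort(key=lambda t: (-t[0], t[1], t[2]))
    out = []
    for rank, (_, _, _, area) in enumerate(areas, start=1):
        area.rank = rank
        out.append(area)
    return out


def stack_binary_maps(binary_maps: list[RasterLayer]) -> RasterLayer:
    """Cellwise sum of per-species presence/absence maps.

    A cell is nodata only where *every* input is nodata; a species' nodata
    at an otherwise-valid cell counts as absence.
    """
    if not binary_maps:
        raise ValueError("nothing to stack")
    spec = binary_maps[0].spec
    for m in binary_maps[1:]:
        if m.spec != spec:
            raise AlignmentError("binary maps are misaligned")
    arr = np.stack([m.values for m in binary_maps])
    nodata = spec.nodata_value
    is_nd = arr == nodata
    total = np.where(is_nd, 0.0, arr).sum(axis=0)
    total[is_nd.all(axis=0)] = nodata
    return RasterLayer(spec, total, name="stacked_richness")
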