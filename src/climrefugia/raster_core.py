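"""Grid data model and I/O.

Every map in the pipeline — bioclimatic layers, suitability surfaces, binary
presence/absence maps, richness stacks — is a :class:`RasterLayer`: a dense
2-D array on a regular lon/lat grid described by a :class:`GridSpec`.
Rasters are exchanged as ESRI ASCII grids (the classic WorldClim distribution
format); occurrences as a plain ``species,lon,lat`` CSV.

Conventions (chosen for bit-exact ASCII-grid compliance):

* row 0 of ``values`` is the **northernmost** row;
* the grid is georeferenced by its **lower-left corner** (``x_origin``,
  ``y_origin``);
* a point belongs to the cell whose half-open interval
  ``[edge, edge + cell_size)`` contains it (closed on the south/west edge).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "RasterLayer",
    "ClimateStack",
    "OccurrenceSet",
    "RasterParseError",
    "AlignmentError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_occurrences_csv",
    "write_occurrences_csv",
    "extract_at_points",
    "cell_area_km2",
    "is_binary",
]


class RasterParseError(ValueError):
    """Malformed ESRI ASCII grid header or body."""


class AlignmentError(ValueError):
    """Operation on rasters whose grids are not identical."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid.

    ``x_origin``/``y_origin`` are the lower-left corner of the lower-left
    cell, in degrees; ``nodata_value`` is the sentinel written to file and
    carried in ``RasterLayer.values`` for missing cells.
    """

    n_rows: int
    n_cols: int
    x_origin: float
    y_origin: float
    cell_size: float
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    def aligned_with(self, other: "GridSpec") -> bool:
        return self == other

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; row 0 is north."""
        col = math.floor((lon - self.x_origin) / self.cell_size)
        row_from_south = math.floor((lat - self.y_origin) / self.cell_size)
        row = self.n_rows - 1 - row_from_south
        return row, col

    def contains_cell(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the cell center."""
        lon = self.x_origin + (col + 0.5) * self.cell_size
        lat = self.y_origin + (self.n_rows - row - 0.5) * self.cell_size
        return lon, lat

    def cell_center_latitudes(self) -> np.ndarray:
        """Latitude of the center of every row, north to south."""
        rows = np.arange(self.n_rows)
        return self.y_origin + (self.n_rows - rows - 0.5) * self.cell_size


@dataclass
class RasterLayer:
    """One gridded variable. ``values`` has shape (n_rows, n_cols); nodata
    cells carry exactly ``spec.nodata_value``."""

    spec: GridSpec
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.spec.n_rows}, {self.spec.n_cols})"
            )

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.values == self.spec.nodata_value

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterLayer":
        return RasterLayer(self.spec, values, self.name if name is None else name)

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_equal(self.values, self.spec.nodata_value)


def is_binary(layer: RasterLayer) -> bool:
    """True iff all non-nodata values are 0 or 1."""
    v = layer.values[layer.valid_mask]
    return bool(np.isin(v, (0.0, 1.0)).all())


@dataclass
class ClimateStack:
    """Named bioclimatic layers (bio1..bio19 style) for one scenario.

    All layers share one grid; variable names are unique and keep insertion
    order.
    """

    scenario_id: str
    layers: dict[str, RasterLayer] = field(default_factory=dict)

    def __post_init__(self) -> None:
        specs = {name: lyr.spec for name, lyr in self.layers.items()}
        it = iter(specs.values())
        first = next(it, None)
        for s in it:
            if s != first:
                raise AlignmentError(
                    f"layers of scenario {self.scenario_id!r} are not aligned"
                )

    @property
    def spec(self) -> GridSpec:
        if not self.layers:
            raise ValueError(f"scenario {self.scenario_id!r} has no layers")
        return next(iter(self.layers.values())).spec

    @property
    def variable_names(self) -> list[str]:
        return list(self.layers)

    def values_matrix(self, variables: list[str] | None = None) -> np.ndarray:
        """(n_cells, n_vars) matrix over the full grid, row-major."""
        names = variables if variables is not None else self.variable_names
        return np.column_stack([self.layers[v].values.ravel() for v in names])

    def valid_mask(self) -> np.ndarray:
        """Flat mask of cells valid in every layer."""
        m = np.ones(self.spec.n_rows * self.spec.n_cols, dtype=bool)
        for lyr in self.layers.values():
            m &= lyr.valid_mask.ravel()
        return m


@dataclass
class OccurrenceSet:
    """Species occurrence records: (species_id, lon, lat) rows."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        cols = {"species", "lon", "lat"}
        if not cols.issubset(self.records.columns):
            raise ValueError(f"occurrence table needs columns {sorted(cols)}")
        lon = self.records["lon"].to_numpy(dtype=float)
        lat = self.records["lat"].to_numpy(dtype=float)
        if np.any((lon < -180) | (lon > 180)) or np.any((lat < -90) | (lat > 90)):
            raise ValueError("coordinates outside lon [-180,180] / lat [-90,90]")

    @property
    def species_ids(self) -> list[str]:
        return list(dict.fromkeys(self.records["species"]))

    def counts(self) -> pd.Series:
        return self.records["species"].value_counts()

    def for_species(self, species_id: str) -> np.ndarray:
        """(n, 2) array of (lon, lat) for one species."""
        sub = self.records[self.records["species"] == species_id]
        return sub[["lon", "lat"]].to_numpy(dtype=float)


_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path, name: str = "") -> RasterLayer:
    """Read an ESRI ASCII grid (.asc).

    Header lines ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value are
    followed by row-major values, northernmost row first.
    """
    header: dict[str, float] = {}
    body_start = 0
    with open(path) as fh:
        lines = fh.read().split("\n")
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower().replace("_", "") in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodatavalue",
        ):
            header[parts[0].lower().replace("_", "")] = float(parts[1])
            body_start = i + 1
        else:
            break
    for key in _HEADER_KEYS:
        if key not in header:
            raise RasterParseError(f"{path}: missing header key {key!r}")
    nodata = header.get("nodatavalue", -9999.0)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    try:
        flat = np.array(" ".join(lines[body_start:]).split(), dtype=float)
    except ValueError as exc:
        raise RasterParseError(f"{path}: non-numeric body value ({exc})") from exc
    if flat.size != n_rows * n_cols:
        raise RasterParseError(
            f"{path}: body has {flat.size} values, expected {n_rows * n_cols}"
        )
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata_value=nodata,
    )
    return RasterLayer(spec, flat.reshape(n_rows, n_cols), name=name)


def write_ascii_grid(layer: RasterLayer, path) -> None:
    """Write an ESRI ASCII grid; round-trips bit-identically through
    :func:`read_ascii_grid` for finite values."""
    s = layer.spec
    with open(path, "w") as fh:
        fh.write(f"ncols {s.n_cols}\n")
        fh.write(f"nrows {s.n_rows}\n")
        fh.write(f"xllcorner {float(s.x_origin)!r}\n")
        fh.write(f"yllcorner {float(s.y_origin)!r}\n")
        fh.write(f"cellsize {float(s.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(s.nodata_value)!r}\n")
        for row in layer.values:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_occurrences_csv(path) -> OccurrenceSet:
    return OccurrenceSet(pd.read_csv(path).rename(columns=str.lower))


def write_occurrences_csv(occ: OccurrenceSet, path) -> None:
    occ.records[["species", "lon", "lat"]].to_csv(path, index=False)


def extract_at_points(stack: ClimateStack, points) -> pd.DataFrame:
    """Containing-cell lookup of every stack variable at each (lon, lat).

    Returns one row per point, in the input order, with a boolean ``valid``
    column: points outside the grid extent or on a nodata cell are flagged
    invalid (their variable columns are NaN), never raised.
    """
    if not stack.layers:
        raise ValueError("cannot extract from an empty stack")
    pts = np.asarray(list(points), dtype=float).reshape(-1, 2)
    spec = stack.spec
    col = np.floor((pts[:, 0] - spec.x_origin) / spec.cell_size).astype(int)
    row_s = np.floor((pts[:, 1] - spec.y_origin) / spec.cell_size).astype(int)
    row = spec.n_rows - 1 - row_s
    inside = (col >= 0) & (col < spec.n_cols) & (row >= 0) & (row < spec.n_rows)
    out = {}
    valid = inside.copy()
    rr = np.clip(row, 0, spec.n_rows - 1)
    cc = np.clip(col, 0, spec.n_cols - 1)
    for name, lyr in stack.layers.items():
        vals = lyr.values[rr, cc]
        bad = ~inside | (vals == lyr.spec.nodata_value)
        vals = np.where(bad, np.nan, vals)
        valid &= ~bad
        out[name] = vals
    frame = pd.DataFrame(out)
    frame["valid"] = valid
    frame["row"] = np.where(inside, row, -1)
    frame["col"] = np.where(inside, col, -1)
    return frame


def cell_area_km2(lat: float, d_lat: float, d_lon: float) -> float:
    """Spherical-rectangle area of a d_lat × d_lon cell centered at ``lat``.

    area = (111.32 · d_lat) · (111.32 · d_lon · cos lat), lat in degrees.
    """
    return (111.32 * d_lat) * (111.32 * d_lon * math.cos(math.radians(lat)))
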