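"""Genetic landscape surfaces: IDW interpolation of diversity and divergence.

Population-level haplotype diversity (one value per sampling site) and
pairwise Phi_ST (one value per population pair, placed at the pair's
lon/lat midpoint) are interpolated onto a regular geographic grid by
inverse-distance weighting and clipped to the study boundary; per-species
surfaces are averaged cell-wise into the multi-species landscape.

The grid is cell-center registered with row 0 northernmost, the layout of
an ESRI ASCII grid, the text raster format used for input and output.
Default resolution is 2.5 arc-minutes (~5 km at the equator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import Delaunay
from shapely.geometry.base import BaseGeometry

from .geo import EARTH_RADIUS_KM, haversine_km, points_in_polygon
from .popgen import PairwiseFstMatrix, SpeciesDataset

__all__ = [
    "GridSpec",
    "Surface",
    "make_grid",
    "idw_interpolate",
    "species_diversity_surface",
    "species_divergence_surface",
    "combine_surfaces",
    "cell_areas",
    "read_ascii_grid",
    "write_ascii_grid",
    "DEFAULT_RESOLUTION_DEG",
]

#: 2.5 arc-minutes in decimal degrees
DEFAULT_RESOLUTION_DEG = 2.5 / 60.0

#: point-to-cell distances below this (km) count as coincident
_COINCIDENT_KM = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid, cell-center registered, row 0 northernmost."""

    west: float
    north: float
    resolution: float
    n_rows: int
    n_cols: int
    boundary_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.resolution <= 0:
            raise ValueError("grid must have positive shape and resolution")
        mask = np.asarray(self.boundary_mask, dtype=bool)
        if mask.shape != (self.n_rows, self.n_cols):
            raise ValueError("boundary_mask shape does not match grid shape")
        object.__setattr__(self, "boundary_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.n_cols) + 0.5) * self.resolution

    def lat_centers(self) -> np.ndarray:
        return self.north - (np.arange(self.n_rows) + 0.5) * self.resolution

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) 2-d arrays of every cell center."""
        lon, lat = np.meshgrid(self.lon_centers(), self.lat_centers())
        return lon, lat

    def index_of(self, lons, lats) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point (clipped to the grid)."""
        cols = np.clip(((np.asarray(lons, float) - self.west) / self.resolution).astype(int), 0, self.n_cols - 1)
        rows = np.clip(((self.north - np.asarray(lats, float)) / self.resolution).astype(int), 0, self.n_rows - 1)
        return rows, cols

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.west, other.west, abs_tol=1e-9)
            and math.isclose(self.north, other.north, abs_tol=1e-9)
            and math.isclose(self.resolution, other.resolution, rel_tol=1e-12)
        )


@dataclass
class Surface:
    """Georeferenced raster of interpolated values; NaN outside the mask."""

    grid: GridSpec
    values: np.ndarray
    layer_name: str = "surface"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise ValueError("surface shape does not match grid")
        v = v.copy()
        v[~self.grid.boundary_mask] = np.nan
        self.values = v

    def masked_values(self) -> np.ndarray:
        """1-d array of values at masked-in cells."""
        return self.values[self.grid.boundary_mask]

    def sample(self, lons, lats) -> np.ndarray:
        """Nearest-cell sample at arbitrary lon/lat points."""
        rows, cols = self.grid.index_of(lons, lats)
        return self.values[rows, cols]


def make_grid(boundary: BaseGeometry, resolution: float = DEFAULT_RESOLUTION_DEG) -> GridSpec:
    """Grid covering the boundary's bounding box in whole cells.

    The western and northern edges sit on the bbox corner; widths are
    rounded up to a whole number of cells.  A cell is masked in when its
    center falls inside (or on the border of) the boundary polygon.
    """
    if boundary is None or boundary.is_empty or not boundary.is_valid:
        raise ValueError("boundary polygon is empty or invalid")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    minx, miny, maxx, maxy = boundary.bounds
    # tiny epsilon so exact-multiple extents do not gain a spurious cell row
    n_cols = max(1, math.ceil((maxx - minx) / resolution - 1e-9))
    n_rows = max(1, math.ceil((maxy - miny) / resolution - 1e-9))
    grid = GridSpec(
        west=minx,
        north=maxy,
        resolution=resolution,
        n_rows=n_rows,
        n_cols=n_cols,
        boundary_mask=np.ones((n_rows, n_cols), dtype=bool),
    )
    lon, lat = grid.cell_centers()
    mask = points_in_polygon(lon.ravel(), lat.ravel(), boundary).reshape(grid.shape)
    return replace(grid, boundary_mask=mask)


def _dedupe_points(lons, lats, values) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average values at exactly coincident lon/lat points."""
    pts = np.column_stack([np.asarray(lons, float), np.asarray(lats, float)])
    values = np.asarray(values, dtype=float)
    uniq, inverse = np.unique(pts, axis=0, return_inverse=True)
    out = np.zeros(len(uniq))
    counts = np.bincount(inverse, minlength=len(uniq))
    np.add.at(out, inverse, values)
    return uniq[:, 0], uniq[:, 1], out / counts


def idw_interpolate(
    points,
    values,
    grid: GridSpec,
    power: float = 2.0,
    chunk_rows: int = 64,
) -> Surface:
    """Inverse-distance-weighted interpolation onto the grid.

    Each masked-in cell takes ``sum(w_i z_i) / sum(w_i)`` with
    ``w_i = d_i**-power`` and ``d_i`` the great-circle distance (km) from
    the cell center to data point i.  All points contribute (no search
    radius); a cell coincident with data points takes their average value.
    Output is therefore bounded by the range of the inputs.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    z = np.asarray(values, dtype=float)
    if len(pts) == 0:
        raise ValueError("IDW needs at least one data point")
    if len(pts) != len(z):
        raise ValueError("points and values length mismatch")
    if not np.isfinite(z).all():
        raise ValueError("non-finite interpolation value")
    if power <= 0:
        raise ValueError("power must be positive")

    plon, plat, pz = _dedupe_points(pts[:, 0], pts[:, 1], z)
    lon_c = grid.lon_centers()
    lat_c = grid.lat_centers()
    out = np.full(grid.shape, np.nan)

    for r0 in range(0, grid.n_rows, chunk_rows):
        r1 = min(r0 + chunk_rows, grid.n_rows)
        block_mask = grid.boundary_mask[r0:r1]
        if not block_mask.any():
            continue
        lon_g, lat_g = np.meshgrid(lon_c, lat_c[r0:r1])
        cl = lon_g[block_mask]
        ct = lat_g[block_mask]
        d = haversine_km(cl[:, None], ct[:, None], plon[None, :], plat[None, :])
        hit = d < _COINCIDENT_KM
        with np.errstate(divide="ignore", over="ignore"):
            w = d ** (-power)
        w[hit] = 0.0
        w = np.where(np.isfinite(w), w, 0.0)
        num = w @ pz
        den = w.sum(axis=1)
        vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        any_hit = hit.any(axis=1)
        if any_hit.any():
            hit_mean = (hit @ pz) / np.maximum(hit.sum(axis=1), 1)
            vals = np.where(any_hit, hit_mean, vals)
        block = np.full(block_mask.shape, np.nan)
        block[block_mask] = vals
        out[r0:r1] = block

    return Surface(grid=grid, values=out)


def species_diversity_surface(
    dataset: SpeciesDataset, diversity, grid: GridSpec, power: float = 2.0
) -> Surface:
    """IDW surface of per-population haplotype diversity for one species.

    Co-located populations are averaged into a single data point before
    interpolation.
    """
    rows = diversity[diversity["species"] == dataset.species]
    if rows.empty:
        raise ValueError(f"no diversity rows for species {dataset.species!r}")
    surf = idw_interpolate(
        rows[["lon", "lat"]].to_numpy(), rows["H_D"].to_numpy(), grid, power=power
    )
    surf.layer_name = f"{dataset.species}:H_D"
    return surf


def species_divergence_surface(
    dataset: SpeciesDataset,
    fst: PairwiseFstMatrix,
    grid: GridSpec,
    pair_mode: str = "all_pairs",
    truncate_negative: bool = True,
    power: float = 2.0,
) -> Surface:
    """IDW surface of pairwise Phi_ST placed at population-pair midpoints.

    Each population pair contributes one synthetic point at the arithmetic
    lon/lat midpoint carrying the pair's Phi_ST (the midpoint construction
    of genetic-landscape GIS workflows; antimeridian-crossing regions are
    not supported).  ``pair_mode`` selects all pairs or only Delaunay
    neighbors.
    """
    pops = {p.pop_id: p for p in dataset.populations}
    if len(fst.pop_ids) < 2:
        raise ValueError("need >= 2 populations for a divergence surface")
    coords = np.array([[pops[pid].longitude, pops[pid].latitude] for pid in fst.pop_ids])

    if pair_mode == "all_pairs":
        pairs = [(i, j) for i in range(len(fst.pop_ids)) for j in range(i + 1, len(fst.pop_ids))]
    elif pair_mode == "delaunay":
        if len(fst.pop_ids) < 4:
            pairs = [(i, j) for i in range(len(fst.pop_ids)) for j in range(i + 1, len(fst.pop_ids))]
        else:
            tri = Delaunay(coords)
            edges = set()
            for simplex in tri.simplices:
                for a in range(3):
                    for b in range(a + 1, 3):
                        edges.add(tuple(sorted((simplex[a], simplex[b]))))
            pairs = sorted(edges)
    else:
        raise ValueError(f"unknown pair_mode {pair_mode!r}")

    mids = np.array([(coords[i] + coords[j]) / 2.0 for i, j in pairs])
    vals = np.array([fst.values[i, j] for i, j in pairs])
    if truncate_negative:
        vals = np.maximum(vals, 0.0)
    surf = idw_interpolate(mids, vals, grid, power=power)
    surf.layer_name = f"{dataset.species}:PhiST"
    return surf


def combine_surfaces(surfaces: list[Surface], layer_name: str = "combined") -> Surface:
    """Cell-wise mean across species surfaces sharing one grid.

    With every input clipped to the study boundary the masked-in cells all
    overlap, so the mean is over the full species set; a cell is missing
    only where it is missing in every input.
    """
    if not surfaces:
        raise ValueError("no surfaces to combine")
    grid = surfaces[0].grid
    for s in surfaces[1:]:
        if not grid.same_geometry(s.grid):
            raise ValueError("surfaces do not share one grid geometry")
    stack = np.stack([s.values for s in surfaces])
    with np.errstate(invalid="ignore"):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            mean = np.nanmean(stack, axis=0)
    return Surface(grid=grid, values=mean, layer_name=layer_name)


def cell_areas(grid: GridSpec) -> np.ndarray:
    """Spherical cell areas in km^2 (latitude-dependent, equal along rows)."""
    res_km = grid.resolution * math.pi / 180.0 * EARTH_RADIUS_KM
    lat = grid.lat_centers()
    return np.repeat((res_km**2 * np.cos(np.radians(lat)))[:, None], grid.n_cols, axis=1)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (text raster; cell-center registration round-trips
# exactly with GridSpec)

_NODATA = -9999.0


def write_ascii_grid(path, surface: Surface) -> None:
    g = surface.grid
    vals = np.where(np.isfinite(surface.values), surface.values, _NODATA)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.west!r}\n"
        f"yllcorner {g.north - g.n_rows * g.resolution!r}\n"
        f"cellsize {g.resolution!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path, boundary_mask: np.ndarray | None = None, layer_name: str | None = None) -> Surface:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(n_rows, n_cols)
    nodata = header.get("nodata_value", _NODATA)
    values = np.where(data == nodata, np.nan, data)
    mask = boundary_mask if boundary_mask is not None else np.isfinite(values)
    grid = GridSpec(
        west=header["xllcorner"],
        north=header["yllcorner"] + n_rows * header["cellsize"],
        resolution=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
        boundary_mask=mask,
    )
    name = layer_name if layer_name is not None else str(path)
    return Surface(grid=grid, values=values, layer_name=name)
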