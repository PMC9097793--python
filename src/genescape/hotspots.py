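"""Genetic-diversity hotspot delineation and protected-area overlap.

Hotspots are connected groups of grid cells whose diversity exceeds the
landscape mean by more than ``z_threshold`` standard deviations (mean and
SD over all masked-in cells).  Components are labeled A, B, ... in
descending order of spherical area; protection status of a hotspot cell is
decided by whether its center lies inside any protected-area polygon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .geo import points_in_polygon
from .landscape import GridSpec, Surface, cell_areas

__all__ = ["Hotspot", "detect_hotspots", "threshold_value", "protected_overlap", "hotspot_polygon"]


class DegenerateSurfaceError(ValueError):
    """Raised when the surface has zero spatial variance."""


@dataclass
class Hotspot:
    """One connected above-threshold component."""

    label: str
    cells: list[tuple[int, int]]
    area_km2: float
    centroid: tuple[float, float]  # lon, lat (area-weighted over cells)


def _component_label(i: int) -> str:
    """A, B, ... Z, AA, AB, ... (spreadsheet-style)."""
    label = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


def _surface_mean_sd(surface: Surface) -> tuple[float, float]:
    vals = surface.masked_values()
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        raise DegenerateSurfaceError("need >= 2 finite cells")
    return float(vals.mean()), float(vals.std())  # population SD


def threshold_value(surface: Surface, z_threshold: float = 1.5) -> float:
    """Hotspot cut on the diversity scale: mean + z_threshold * SD."""
    mean, sd = _surface_mean_sd(surface)
    if sd == 0.0:
        raise DegenerateSurfaceError("constant surface: threshold undefined")
    return mean + z_threshold * sd

def detect_hotspots(
    surface: Surface, z_threshold: float = 1.5, connectivity: int = 8
) -> list[Hotspot]:
    """Connected components of cells with z-score above ``z_threshold``.

    A constant surface (zero SD) yields no hotspots rather than an error.
    ``connectivity`` 8 merges diagonal neighbours; 4 requires edge contact.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mean, sd = _surface_mean_sd(surface)
    if sd == 0.0:
        return []
    flagged = np.zeros(surface.grid.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        flagged[surface.grid.boundary_mask] = (
            surface.values[surface.grid.boundary_mask] - mean
        ) / sd > z_threshold
    structure = np.ones((3, 3), bool) if connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    labeled, n_comp = ndimage.label(flagged, structure=structure)
    if n_comp == 0:
        return []

    areas = cell_areas(surface.grid)
    lon_c = surface.grid.lon_centers()
    lat_c = surface.grid.lat_centers()
    comps = []
    for comp_id in range(1, n_comp + 1):
        rows, cols = np.nonzero(labeled == comp_id)
        a = areas[rows, cols]
        total = float(a.sum())
        centroid = (
            float(np.average(lon_c[cols], weights=a)),
            float(np.average(lat_c[rows], weights=a)),
        )
        comps.append((total, list(zip(rows.tolist(), cols.tolist())), centroid))
    comps.sort(key=lambda t: -t[0])
    return [
        Hotspot(label=_component_label(i), cells=cells, area_km2=total, centroid=centroid)
        for i, (total, cells, centroid) in enumerate(comps)
    ]


def hotspot_polygon(hotspot: Hotspot, grid: GridSpec) -> BaseGeometry:
    """Dissolved union of the hotspot's cell rectangles."""
    res = grid.resolution
    cells = [
        box(
            grid.west + c * res,
            grid.north - (r + 1) * res,
            grid.west + (c + 1) * res,
            grid.north - r * res,
        )
        for r, c in hotspot.cells
    ]
    return unary_union(cells)


def protected_overlap(
    hotspots: list[Hotspot], protected_areas: BaseGeometry | None, grid: GridSpec
) -> tuple[float, pd.DataFrame]:
    """Area fraction of hotspot land outside protected areas.

    Returns the area-weighted outside fraction plus a per-hotspot table
    (label, area_km2, protected_fraction).  A hotspot cell is protected iff
    its center lies inside any protected polygon.
    """
    if not hotspots:
        raise ValueError("no hotspots: protected fraction undefined")
    areas = cell_areas(grid)
    lon_c = grid.lon_centers()
    lat_c = grid.lat_centers()
    empty_pa = protected_areas is None or protected_areas.is_empty

    records = []
    tot_area = 0.0
    tot_protected = 0.0
    for h in hotspots:
        rows = np.array([r for r, _ in h.cells])
        cols = np.array([c for _, c in h.cells])
        a = areas[rows, cols]
        if empty_pa:
            inside = np.zeros(len(a), dtype=bool)
        else:
            inside = points_in_polygon(lon_c[cols], lat_c[rows], protected_areas)
        protected_area = float(a[inside].sum())
        records.append(
            {
                "label": h.label,
                "area_km2": float(a.sum()),
                "protected_fraction": protected_area / float(a.sum()),
            }
        )
        tot_area += float(a.sum())
        tot_protected += protected_area
    outside_fraction = 1.0 - tot_protected / tot_area
    return outside_fraction, pd.DataFrame(records)
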