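"""Great-circle geometry and GeoJSON polygon I/O (WGS84 lon/lat throughout)."""

from __future__ import annotations

import json

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "pairwise_haversine_km",
    "points_in_polygon",
    "read_geojson_polygons",
    "write_geojson_polygons",
]


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km; broadcasts over numpy inputs."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_haversine_km(lons, lats) -> np.ndarray:
    """Symmetric all-pairs great-circle distance matrix (km)."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons.ndim != 1 or lons.shape != lats.shape:
        raise ValueError("lons and lats must be equal-length 1-d arrays")
    if not (np.isfinite(lons).all() and np.isfinite(lats).all()):
        raise ValueError("non-finite coordinate")
    if (np.abs(lons) > 180).any() or (np.abs(lats) > 90).any():
        raise ValueError("coordinate out of WGS84 range")
    d = haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)


def points_in_polygon(lons, lats, polygon: BaseGeometry) -> np.ndarray:
    """Boolean mask of points inside (or on the boundary of) a polygon."""
    return shapely.intersects_xy(polygon, np.asarray(lons, float), np.asarray(lats, float))


def read_geojson_polygons(path) -> BaseGeometry:
    """Union of all polygonal geometries in a GeoJSON file (may be empty)."""
    with open(path) as fh:
        gj = json.load(fh)
    geoms = []
    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"] if f.get("geometry")]
    elif gj.get("type") == "Feature":
        geoms = [shape(gj["geometry"])]
    else:
        geoms = [shape(gj)]
    if not geoms:
        return shapely.Polygon()
    return unary_union(geoms)


def write_geojson_polygons(path, geometries, properties=None) -> None:
    """Write geometries as a GeoJSON FeatureCollection."""
    if isinstance(geometries, BaseGeometry):
        geometries = [geometries]
    properties = properties or [{} for _ in geometries]
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geometries, properties)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
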