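"""Shared star-convex polygon helpers (ray casting, uniform sampling).

All coordinates are 0-based pixel (x, y) with y increasing downward.
"""
from __future__ import annotations

import math

import numpy as np
from shapely.geometry import LineString, Point, Polygon
from shapely.prepared import prep

from .errors import GeometryError


def polygon_vertices(poly: Polygon) -> np.ndarray:
    """Exterior vertices as an (n, 2) array of (x, y), closing point dropped."""
    xy = np.asarray(poly.exterior.coords)
    if len(xy) > 1 and np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    return xy


def ray_boundary_distance(poly: Polygon, center: tuple[float, float], theta: float) -> float:
    """Distance from ``center`` to the outline along the ray at angle ``theta``.

    For star-convex outlines the ray meets the boundary once; if numerical
    noise yields several hits the nearest one is used.
    """
    cx, cy = center
    minx, miny, maxx, maxy = poly.bounds
    reach = 2.0 * (abs(maxx - minx) + abs(maxy - miny) + 1.0)
    ray = LineString(
        [(cx, cy), (cx + reach * math.cos(theta), cy + reach * math.sin(theta))]
    )
    hit = poly.exterior.intersection(ray)
    if hit.is_empty:
        raise GeometryError("ray from center does not meet the outline; center outside?")
    pts: list[Point] = []
    for geom in getattr(hit, "geoms", [hit]):
        if isinstance(geom, Point):
            pts.append(geom)
        else:  # collinear overlap: take its endpoints
            pts.extend(Point(c) for c in geom.coords)
    return min(math.hypot(p.x - cx, p.y - cy) for p in pts)


def uniform_points_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` points uniformly over the polygon area (rejection sampling)."""
    minx, miny, maxx, maxy = poly.bounds
    prepared = prep(poly)
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(64, 2 * (n - filled))
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        for x, y in zip(xs, ys):
            if prepared.contains(Point(x, y)):
                out[filled] = (x, y)
                filled += 1
                if filled == n:
                    break
    return out


def star_convex_polygon(
    center: tuple[float, float],
    mean_radius: float,
    rng: np.random.Generator,
    n_vertices: int = 16,
    irregularity: float = 0.25,
) -> Polygon:
    """Random star-convex polygon around ``center``: equally spaced angles with
    radii jittered by ±``irregularity`` of the mean radius."""
    angles = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    radii = mean_radius * (1.0 + irregularity * rng.uniform(-1.0, 1.0, n_vertices))
    xs = center[0] + radii * np.cos(angles)
    ys = center[1] + radii * np.sin(angles)
    return Polygon(np.column_stack([xs, ys]))
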