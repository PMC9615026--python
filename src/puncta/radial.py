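"""Shape-aware radial distribution of organelles in concentric shells.

Shells are scaled copies of the cell outline about the user-chosen center
(factors k/n for k = 1..n), so the analysis respects the cell's shape rather
than assuming circular symmetry. Each object's normalized radius is its
distance from the center divided by the outline-boundary distance along the
same ray; the distribution is the percentage frequency of objects per shell.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .errors import GeometryError
from .io import CellGeometry
from .segment import ObjectSet
from ._geom import polygon_vertices, ray_boundary_distance

logger = logging.getLogger(__name__)


@dataclass
class ShellSet:
    """Concentric shell boundaries: scaled copies of the outline."""

    n_shells: int
    boundaries: list[Polygon]  # innermost first; last equals the outline
    center: tuple[float, float]


@dataclass
class ShellDistribution:
    """Percentage frequency of objects per shell (sums to 100 when any
    object is included)."""

    frequencies: np.ndarray
    n_objects_included: int
    n_objects_excluded: int

    @property
    def n_shells(self) -> int:
        return len(self.frequencies)


def shape_scaled_shells(geometry: CellGeometry, n_shells: int = 10) -> ShellSet:
    """Scale the outline about the center by k/n for k = 1..n.

    Raises if consecutive boundaries are not strictly nested, which happens
    for outlines that are not star-convex about the chosen center; the
    remedy is to re-draw the outline or move the center.
    """
    if n_shells < 1:
        raise GeometryError("n_shells must be >= 1")
    cx, cy = geometry.center
    verts = polygon_vertices(geometry.outline)
    boundaries = []
    for k in range(1, n_shells + 1):
        f = k / n_shells
        scaled = np.column_stack([cx + f * (verts[:, 0] - cx), cy + f * (verts[:, 1] - cy)])
        boundaries.append(Polygon(scaled))
    for inner, outer in zip(boundaries, boundaries[1:]):
        if not outer.contains(inner):
            raise GeometryError(
                "scaled shell boundaries cross: outline is not star-convex about "
                "the center; re-draw the outline or move the center"
            )
    return ShellSet(n_shells=n_shells, boundaries=boundaries, center=(cx, cy))


def normalized_radius(
    point: tuple[float, float], outline: Polygon, center: tuple[float, float]
) -> float:
    """Distance from center over boundary distance along the point's ray."""
    cx, cy = center
    dx, dy = point[0] - cx, point[1] - cy
    d = math.hypot(dx, dy)
    if d == 0.0:
        return 0.0
    b = ray_boundary_distance(outline, center, math.atan2(dy, dx))
    return d / b


def radial_distribution(objects, shells: ShellSet, outline: Polygon | None = None) -> ShellDistribution:
    """Percentage frequency of object centroids per concentric shell.

    ``objects`` is an :class:`ObjectSet` or an (n, 2) array of (x, y)
    centroids. A radius exactly on a shell boundary goes to the inner shell
    (half-open intervals). Centroids outside the outline are excluded with a
    logged warning, not an error — edge noise should not abort a batch run.
    """
    pts = objects.centroids() if isinstance(objects, ObjectSet) else np.asarray(objects, float)
    outline = outline if outline is not None else shells.boundaries[-1]
    n = shells.n_shells
    prepared = prep(outline)
    counts = np.zeros(n, dtype=int)
    excluded = 0
    for x, y in pts:
        if not prepared.covers(Point(x, y)):  # boundary counts as inside
            excluded += 1
            continue
        r = normalized_radius((x, y), outline, shells.center)
        # boundary ties go inward: shell index = ceil(r * n) on (lo, hi]
        idx = math.ceil(round(r * n, 9))
        counts[min(max(idx, 1), n) - 1] += 1
    included = int(counts.sum())
    if excluded:
        logger.warning("%d object(s) outside the outline excluded", excluded)
    if included == 0:
        raise GeometryError("no objects inside outline")
    return ShellDistribution(
        frequencies=100.0 * counts / included,
        n_objects_included=included,
        n_objects_excluded=excluded,
    )


def aggregate_distributions(dists: list[ShellDistribution]) -> dict:
    """Per-shell sample mean and SD (n-1 denominator) across cells.

    With a single cell the SD is reported as NaN (not available) rather
    than 0 — one observation carries no spread information.
    """
    if not dists:
        raise ValueError("empty distribution list")
    n_shells = dists[0].n_shells
    if any(d.n_shells != n_shells for d in dists):
        raise ValueError("distributions have mismatched shell counts")
    mat = np.vstack([d.frequencies for d in dists])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if len(dists) > 1 else np.full(n_shells, np.nan)
    return {"mean": mean, "sd": sd, "n_cells": len(dists)}
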