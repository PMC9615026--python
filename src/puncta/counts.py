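"""Organelle counting inside named ROIs (soma, growth cone) for neurons.

Membership is centroid containment with ROI boundaries counting as inside;
the growth-cone-to-soma ratio summarizes redistribution toward the neurite
tip. Overlapping ROIs are permitted — an object may count in both, with a
logged notice — so user-drawn geometries never silently drop data.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

from shapely.geometry import Point
from shapely.prepared import prep

from .errors import GeometryError
from .io import CellGeometry
from .segment import ObjectSet

logger = logging.getLogger(__name__)


@dataclass
class RoiCountResult:
    cell_id: str
    counts: dict[str, int]
    gc_soma_ratio: float  # NaN when the soma count is zero


def roi_object_counts(
    objects: ObjectSet,
    geometry: CellGeometry,
    roi_names: tuple[str, ...] = ("soma", "growth_cone"),
    cell_id: str = "",
) -> RoiCountResult:
    """Count object centroids in each named ROI and form growth_cone/soma.

    The ratio is ``counts["growth_cone"] / counts["soma"]`` when both ROIs
    are requested and the soma count is positive; otherwise NaN with a
    warning.
    """
    missing = [name for name in roi_names if name not in geometry.rois]
    if missing:
        raise GeometryError(f"ROI(s) {missing} absent from geometry")
    prepared = {name: prep(geometry.rois[name]) for name in roi_names}
    counts = {name: 0 for name in roi_names}
    for x, y in objects.centroids():
        p = Point(x, y)
        hits = [name for name in roi_names if prepared[name].covers(p)]
        for name in hits:
            counts[name] += 1
        if len(hits) > 1:
            logger.info("object at (%.1f, %.1f) lies in overlapping ROIs %s", x, y, hits)
    ratio = float("nan")
    if "soma" in counts and "growth_cone" in counts:
        if counts["soma"] > 0:
            ratio = counts["growth_cone"] / counts["soma"]
        else:
            warnings.warn(
                "soma count is zero; growth-cone/soma ratio not available", stacklevel=2
            )
    return RoiCountResult(cell_id=cell_id, counts=counts, gc_soma_ratio=ratio)
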