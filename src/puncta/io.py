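"""Reading and writing the formats the pipeline touches.

Stacks are TIFF/OME-TIFF, geometries are GeoJSON, result tables are CSV.
Pixel coordinates are 0-based (x, y) with y increasing downward, matching
raster indexing. Intensities of any non-negative numeric type are promoted
to float64 internally; the scoring math is arithmetic on channel means.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Point, Polygon, mapping, shape

from .errors import GeometryError, StackError

#: Recognized channel roles. ``marker`` is the organelle marker used for
#: masking, ``construct`` the membrane-anchored construct the analysis is
#: restricted to, ``cargo`` the recruited protein being scored.
CHANNEL_ROLES = ("marker", "construct", "cargo", "other")

#: Roles that may be declared at most once per stack.
_UNIQUE_ROLES = ("marker", "construct", "cargo")


@dataclass
class ChannelStack:
    """A multi-channel z-stack with channel roles and voxel spacing.

    Parameters
    ----------
    voxels
        4-D array indexed ``(z, y, x, channel)``; non-negative intensities.
    channel_roles
        Map channel index -> role in :data:`CHANNEL_ROLES`.
    z_step_um
        Slice spacing in micrometers (0.3 for COS-7-like stacks, 0.2 for
        neuron-like stacks).
    pixel_size_um
        In-plane pixel size in micrometers.
    """

    voxels: np.ndarray
    channel_roles: dict[int, str]
    z_step_um: float = 0.3
    pixel_size_um: float = 0.2

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=np.float64)
        if v.ndim != 4:
            raise StackError(f"voxels must be 4-D (z, y, x, channel), got ndim={v.ndim}")
        if any(s < 1 for s in v.shape):
            raise StackError(f"all stack extents must be >= 1, got shape {v.shape}")
        if v.min() < 0:
            raise StackError("negative intensities are not allowed")
        if self.z_step_um <= 0 or self.pixel_size_um <= 0:
            raise StackError("voxel spacing must be positive")
        n_channels = v.shape[3]
        seen: dict[str, int] = {}
        for idx, role in self.channel_roles.items():
            if not (0 <= idx < n_channels):
                raise StackError(
                    f"channel index {idx} out of range for {n_channels}-channel stack"
                )
            if role not in CHANNEL_ROLES:
                raise StackError(f"unknown channel role {role!r}")
            if role in _UNIQUE_ROLES and role in seen:
                raise StackError(f"role {role!r} declared for more than one channel")
            seen[role] = idx
        self.voxels = v

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[3]

    def channel_index(self, role: str) -> int:
        for idx, r in self.channel_roles.items():
            if r == role:
                return idx
        raise StackError(f"stack declares no {role!r} channel")

    def channel(self, role: str) -> np.ndarray:
        """The (z, y, x) intensity array for the channel with ``role``."""
        return self.voxels[..., self.channel_index(role)]


@dataclass
class CellGeometry:
    """User-supplied cell outline, center point and named ROI polygons."""

    outline: Polygon
    center: tuple[float, float]
    rois: dict[str, Polygon] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outline = _as_polygon(self.outline, "outline")
        if not self.outline.contains(Point(*self.center)):
            raise GeometryError("center not inside outline")
        self.rois = {name: _as_polygon(p, name) for name, p in self.rois.items()}


def _as_polygon(poly: Polygon, name: str) -> Polygon:
    if not isinstance(poly, Polygon):
        poly = Polygon(poly)
    coords = list(poly.exterior.coords)
    # the closing vertex repeats the first
    if len(coords) - 1 < 3:
        raise GeometryError(f"degenerate polygon {name!r}: fewer than 3 vertices")
    if not (poly.is_valid and poly.is_simple):
        raise GeometryError(f"polygon {name!r} is self-intersecting or invalid")
    return poly


# ---------------------------------------------------------------------------
# TIFF stacks


def read_stack(
    path: str | Path,
    channel_role_map: Mapping[int, str],
    z_step_um: float = 0.3,
    pixel_size_um: float = 0.2,
) -> ChannelStack:
    """Read a single- or multi-page TIFF/OME-TIFF into a :class:`ChannelStack`.

    The axis order is normalized to ``(z, y, x, channel)`` using the file's
    axis labels; sample (``S``) axes count as channels. 8/16-bit integer and
    float data are accepted and promoted to float64.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            if len(tf.series) != 1:
                raise StackError(
                    f"{path}: pages have inconsistent shapes ({len(tf.series)} series)"
                )
            series = tf.series[0]
            arr = series.asarray()
            axes = series.axes
    except StackError:
        raise
    except Exception as exc:  # tifffile raises a mix of OSError/ValueError
        raise StackError(f"could not read TIFF {path}: {exc}") from exc

    arr, _ = _normalize_axes(arr, axes, path)
    return ChannelStack(
        voxels=arr,
        channel_roles=dict(channel_role_map),
        z_step_um=z_step_um,
        pixel_size_um=pixel_size_um,
    )


def _normalize_axes(arr: np.ndarray, axes: str, path: Path) -> tuple[np.ndarray, str]:
    """Reorder ``arr`` with axis labels ``axes`` to (Z, Y, X, C)."""
    axes = axes.upper()
    arr = np.asarray(arr)
    keep: list[str] = []
    for i, ax in enumerate(axes):
        if ax in "ZYX":
            keep.append(ax)
        elif ax in "CS":
            keep.append("C")
        elif arr.shape[i] == 1:
            keep.append("drop")
        else:
            raise StackError(f"{path}: unsupported non-trivial axis {ax!r}")
    # squeeze droppable axes
    for i in reversed([i for i, k in enumerate(keep) if k == "drop"]):
        arr = np.squeeze(arr, axis=i)
        del keep[i]
    if keep.count("C") > 1 or any(keep.count(a) > 1 for a in "ZYX"):
        raise StackError(f"{path}: duplicated axis in {axes!r}")
    for missing in [a for a in "ZYXC" if a not in keep]:
        arr = arr[..., np.newaxis] if missing == "C" else arr[np.newaxis]
        keep = keep + ["C"] if missing == "C" else [missing] + keep
    order = [keep.index(a) for a in "ZYXC"]
    return np.transpose(arr, order), "ZYXC"


def write_stack(stack: ChannelStack, path: str | Path, dtype: str | None = None) -> None:
    """Write a stack as OME-TIFF with ZCYX page layout.

    ``dtype=None`` picks ``uint16`` when every voxel is an integer in range,
    otherwise ``float32``. Integer stacks round-trip bit-exactly.
    """
    v = stack.voxels
    if dtype is None:
        integral = np.all(v == np.round(v)) and v.max() <= np.iinfo(np.uint16).max
        dtype = "uint16" if integral else "float32"
    data = np.transpose(v, (0, 3, 1, 2)).astype(dtype)  # -> (z, c, y, x)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "ZCYX",
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeY": stack.pixel_size_um,
            "PhysicalSizeZ": stack.z_step_um,
        },
        photometric="minisblack",
    )


# ---------------------------------------------------------------------------
# GeoJSON geometry


def read_geometry(path: str | Path) -> CellGeometry:
    """Read a GeoJSON FeatureCollection with an ``outline`` polygon, a
    ``center`` point, and optional named ROI polygons."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise GeometryError(f"{path}: expected a GeoJSON FeatureCollection")
    outline = center = None
    rois: dict[str, Polygon] = {}
    for feat in doc.get("features", []):
        name = feat.get("properties", {}).get("name")
        geom = shape(feat["geometry"])
        if name == "outline":
            outline = geom
        elif name == "center":
            if not isinstance(geom, Point):
                raise GeometryError(f"{path}: 'center' feature must be a point")
            center = (geom.x, geom.y)
        elif name:
            if not isinstance(geom, Polygon):
                raise GeometryError(f"{path}: ROI {name!r} must be a polygon")
            rois[name] = geom
    if outline is None or center is None:
        raise GeometryError(f"{path}: missing required 'outline' or 'center' feature")
    return CellGeometry(outline=outline, center=center, rois=rois)


def write_geometry(geometry: CellGeometry, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"name": "outline"},
            "geometry": mapping(geometry.outline),
        },
        {
            "type": "Feature",
            "properties": {"name": "center"},
            "geometry": mapping(Point(*geometry.center)),
        },
    ]
    for name, poly in geometry.rois.items():
        features.append(
            {"type": "Feature", "properties": {"name": name}, "geometry": mapping(poly)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


# ---------------------------------------------------------------------------
# Result tables


def write_results(records, path: str | Path, columns: list[str] | None = None) -> None:
    """Write tabular records (list of dicts or DataFrame) as CSV with header.

    ``columns`` fixes the header for empty record lists, whose schema cannot
    be inferred from the data.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records), columns=columns)
    df.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
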