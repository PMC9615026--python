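"""Per-slice organelle masking and object labeling.

The marker channel is thresholded independently in every z-slice ("in each
z-slice"); the analysis is later restricted to marker pixels that are also
construct-positive. Object identity, used for counting and radial analysis,
comes from 8-connected components of the 2-D maximum projection of the mask,
so a punctum spanning two or three adjacent slices counts once.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, remove_small_objects

from .errors import SegmentationError
from .io import CellGeometry, ChannelStack
from ._geom import polygon_vertices

try:  # scikit-image >= 0.26 renamed the size cutoff parameter
    from inspect import signature

    _RSO_KW = (
        "max_size" if "max_size" in signature(remove_small_objects).parameters else "min_size"
    )
except Exception:  # pragma: no cover
    _RSO_KW = "min_size"


def _remove_small(mask, min_size_px: int):
    """Remove connected components with fewer than ``min_size_px`` pixels."""
    if _RSO_KW == "max_size":
        return remove_small_objects(mask, max_size=min_size_px - 1, connectivity=2)
    return remove_small_objects(mask, min_size=min_size_px, connectivity=2)


@dataclass
class MaskStack:
    """Per-slice boolean masks plus the record needed to reproduce them."""

    masks: np.ndarray  # bool, (z, y, x)
    source_role: str
    method_record: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise SegmentationError("masks must be 3-D (z, y, x)")

    @property
    def max_projection(self) -> np.ndarray:
        return self.masks.any(axis=0)


@dataclass
class SegmentedObject:
    id: int
    centroid: tuple[float, float]  # (x, y)
    area_px: int
    slice_span: tuple[int, int]  # inclusive (z_min, z_max)


@dataclass
class ObjectSet:
    objects: list[SegmentedObject] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.objects)

    def centroids(self) -> np.ndarray:
        """(n, 2) array of (x, y) centroids."""
        if not self.objects:
            return np.empty((0, 2))
        return np.array([o.centroid for o in self.objects])


def _parse_method(method: str) -> tuple[str, float | None]:
    if method == "otsu":
        return "otsu", None
    for prefix, caster in (("fixed:", float), ("quantile:", float)):
        if method.startswith(prefix):
            try:
                return prefix[:-1], caster(method[len(prefix):])
            except ValueError as exc:
                raise SegmentationError(f"bad threshold in method {method!r}") from exc
    raise SegmentationError(
        f"unknown method {method!r}; expected 'otsu', 'fixed:<t>' or 'quantile:<q>'"
    )


def _threshold_slice(img: np.ndarray, kind: str, param: float | None) -> np.ndarray:
    if kind == "fixed":
        return img >= param
    if kind == "quantile":
        if not (0.0 < param < 1.0):
            raise SegmentationError("quantile must be in (0, 1)")
        return img > np.quantile(img, param)
    # otsu: a constant slice has no foreground
    if img.max() == img.min():
        return np.zeros_like(img, dtype=bool)
    return img > threshold_otsu(img)


def segment_marker(
    stack: ChannelStack,
    method: str = "otsu",
    min_size_px: int = 2,
    role: str = "marker",
) -> tuple[MaskStack, ObjectSet]:
    """Threshold the marker channel per z-slice and label projected objects.

    Parameters
    ----------
    method
        ``"otsu"`` (per-slice Otsu; an all-constant slice yields an empty
        mask), ``"fixed:<t>"`` (intensity >= t) or ``"quantile:<q>"``.
    min_size_px
        Connected components smaller than this are removed slice-wise.
    role
        Channel role to segment; the peroxisomal marker by default, but the
        same routine masks a mitochondrial marker channel.
    """
    if min_size_px < 1:
        raise SegmentationError("min_size_px must be >= 1")
    kind, param = _parse_method(method)
    chan = stack.channel(role)
    masks = np.zeros(chan.shape, dtype=bool)
    for z in range(chan.shape[0]):
        m = _threshold_slice(chan[z], kind, param)
        if min_size_px > 1:
            m = _remove_small(m, min_size_px)
        masks[z] = m
    mask_stack = MaskStack(
        masks=masks,
        source_role=role,
        method_record={"method": method, "min_size_px": min_size_px, "per_slice": True},
    )
    return mask_stack, label_objects(mask_stack)


def label_objects(mask_stack: MaskStack) -> ObjectSet:
    """8-connected components of the 2-D max projection, with z spans."""
    proj = mask_stack.max_projection
    labels = measure.label(proj, connectivity=2)
    objects = []
    per_slice_any = mask_stack.masks
    for prop in measure.regionprops(labels):
        footprint = labels == prop.label
        present = np.array(
            [(per_slice_any[z] & footprint).any() for z in range(per_slice_any.shape[0])]
        )
        zs = np.flatnonzero(present)
        row, col = prop.centroid
        objects.append(
            SegmentedObject(
                id=int(prop.label),
                centroid=(float(col), float(row)),
                area_px=int(prop.area),
                slice_span=(int(zs[0]), int(zs[-1])),
            )
        )
    return ObjectSet(objects=objects)


def default_construct_threshold(stack: ChannelStack, marker_mask: MaskStack) -> float:
    """Per-cell Otsu of the construct channel restricted to the marker mask.

    This is the pixel-level analog of the study's inclusion rule: only
    organelles with visible construct signal enter the analysis.
    """
    construct = stack.channel("construct")
    vals = construct[marker_mask.masks]
    if vals.size == 0 or vals.max() == vals.min():
        return float("inf")  # nothing construct-positive
    return float(threshold_otsu(vals))


def double_positive_mask(
    marker_mask: MaskStack,
    stack: ChannelStack,
    construct_threshold: float | None = None,
) -> MaskStack:
    """Restrict the marker mask to construct-positive pixels, per slice.

    ``construct_threshold=None`` uses :func:`default_construct_threshold`.
    The result is always a subset of the marker mask; raising the threshold
    never grows it.
    """
    if marker_mask.masks.shape != stack.shape_zyx:
        raise SegmentationError("marker mask shape does not match stack")
    construct = stack.channel("construct")
    if construct_threshold is None:
        construct_threshold = default_construct_threshold(stack, marker_mask)
        how = "otsu_in_marker_mask"
    else:
        how = "fixed"
    masks = marker_mask.masks & (construct >= construct_threshold)
    return MaskStack(
        masks=masks,
        source_role="marker+construct",
        method_record={
            "parent": marker_mask.method_record,
            "construct_threshold": float(construct_threshold),
            "threshold_rule": how,
        },
    )


def cell_region(stack: ChannelStack, geometry: CellGeometry | None = None) -> MaskStack:
    """The whole-cell region over which background ("whole-cell intensity
    outside the organelle mask") is evaluated.

    With a geometry the outline polygon is rasterized and replicated across
    z. Without one, a fallback unions per-channel Otsu masks and closes/fills
    them; the method_record says which path was taken.
    """
    z, h, w = stack.shape_zyx
    if geometry is not None:
        verts = polygon_vertices(geometry.outline)
        mask2d = polygon2mask((h, w), verts[:, ::-1])  # (x, y) -> (row, col)
        masks = np.broadcast_to(mask2d, (z, h, w)).copy()
        return MaskStack(
            masks=masks, source_role="geometry", method_record={"method": "outline_raster"}
        )
    union = np.zeros((z, h, w), dtype=bool)
    for c in range(stack.n_channels):
        chan = stack.voxels[..., c]
        if chan.max() == chan.min():
            continue
        union |= chan > threshold_otsu(chan)
    footprint = disk(2)
    for zi in range(z):
        closed = closing(union[zi], footprint)
        union[zi] = _fill_holes(closed)
    return MaskStack(
        masks=union,
        source_role="all-channels",
        method_record={"method": "union_otsu_closed_filled", "closing_radius": 2},
    )


def _fill_holes(mask: np.ndarray) -> np.ndarray:
    from scipy.ndimage import binary_fill_holes

    return binary_fill_holes(mask)
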