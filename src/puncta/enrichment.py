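"""Cargo-enrichment scoring on construct-positive organelles.

The central statistic: for each z-slice with a non-empty analysis mask, the
mean cargo intensity on the mask minus the mean cargo intensity over the
cytosol (cell region excluding the full organelle mask); the per-cell raw
enrichment is the unweighted average of these slice values, and the
normalized enrichment divides by the construct's mean intensity on the same
mask, cancelling cell-to-cell differences in construct expression. Negative
raw values are reported, not clipped — cargo can be depleted on organelles.

A mitochondrial variant expresses cargo on the organelle relative to the
cytosol as a fold ratio.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import EnrichmentError
from .io import ChannelStack
from .segment import MaskStack


@dataclass
class EnrichmentResult:
    """Per-cell enrichment scores.

    ``normalized_enrichment`` equals ``raw_enrichment / construct_intensity``
    exactly; ``background`` is the mean cytosolic cargo level that was
    subtracted; ``n_slices_used`` counts slices with a non-empty analysis
    mask; ``analysis_mask_px`` is the total analysis-mask size over those
    slices.
    """

    cell_id: str
    raw_enrichment: float
    construct_intensity: float
    normalized_enrichment: float
    background: float
    n_slices_used: int
    analysis_mask_px: int


def peroxisomal_enrichment(
    stack: ChannelStack,
    marker_mask: MaskStack,
    analysis_mask: MaskStack,
    cell_region: MaskStack,
    cargo_channel: int | None = None,
    cell_id: str = "",
    slice_weighting: str = "unweighted",
    normalization: str = "ratio_of_means",
) -> EnrichmentResult:
    """Background-subtracted, construct-normalized cargo enrichment.

    Parameters
    ----------
    marker_mask
        Full organelle-marker mask; its complement within ``cell_region``
        defines the cytosolic background.
    analysis_mask
        Construct-positive restriction of the marker mask; must be a subset.
    cargo_channel
        Channel index of the scored cargo; defaults to the ``cargo`` role.
    slice_weighting
        ``"unweighted"`` averages slice values with equal weight (default);
        ``"pixel"`` weights each slice by its analysis-mask pixel count.
    normalization
        ``"ratio_of_means"`` (default) divides the slice-averaged raw
        enrichment by the slice-averaged construct intensity;
        ``"mean_of_ratios"`` averages per-slice raw/construct ratios.
    """
    if slice_weighting not in ("unweighted", "pixel"):
        raise ValueError(f"unknown slice_weighting {slice_weighting!r}")
    if normalization not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError(f"unknown normalization {normalization!r}")
    shape = stack.shape_zyx
    for m, name in (
        (marker_mask, "marker_mask"),
        (analysis_mask, "analysis_mask"),
        (cell_region, "cell_region"),
    ):
        if m.masks.shape != shape:
            raise EnrichmentError(f"{name} shape {m.masks.shape} != stack {shape}")
    if (analysis_mask.masks & ~marker_mask.masks).any():
        raise EnrichmentError("analysis mask is not a subset of the marker mask")

    cargo = (
        stack.channel("cargo") if cargo_channel is None else stack.voxels[..., cargo_channel]
    )
    construct = stack.channel("construct")

    raw_z, out_z, con_z, npx_z = [], [], [], []
    for z in range(shape[0]):
        a = analysis_mask.masks[z]
        if not a.any():
            continue
        cytosol = cell_region.masks[z] & ~marker_mask.masks[z]
        if not cytosol.any():
            raise EnrichmentError("no cytosol for background on a used slice")
        in_mean = cargo[z][a].mean()
        out_mean = cargo[z][cytosol].mean()
        raw_z.append(in_mean - out_mean)
        out_z.append(out_mean)
        con_z.append(construct[z][a].mean())
        npx_z.append(int(a.sum()))

    if not raw_z:
        raise EnrichmentError("no construct-positive organelles: cell excluded")

    if slice_weighting == "pixel":
        w = np.asarray(npx_z, dtype=float)
        avg = lambda v: float(np.average(v, weights=w))  # noqa: E731
    else:
        avg = lambda v: float(np.mean(v))  # noqa: E731

    raw = avg(raw_z)
    background = avg(out_z)
    construct_intensity = avg(con_z)
    if construct_intensity == 0:
        raise EnrichmentError("construct intensity is zero; normalization undefined")
    if normalization == "mean_of_ratios":
        ratios = [r / c for r, c in zip(raw_z, con_z)]
        normalized = avg(ratios)
    else:
        normalized = raw / construct_intensity

    return EnrichmentResult(
        cell_id=cell_id,
        raw_enrichment=raw,
        construct_intensity=construct_intensity,
        normalized_enrichment=normalized,
        background=background,
        n_slices_used=len(raw_z),
        analysis_mask_px=int(sum(npx_z)),
    )


def mitochondrial_enrichment(
    stack: ChannelStack,
    mito_mask: MaskStack,
    cell_region: MaskStack,
    cargo_channel: int | None = None,
    mode: str = "ratio",
) -> float:
    """Cargo on the mitochondrial mask relative to the cytosol.

    Per used slice the statistic is mean-on-mask / mean-on-cytosol (fold
    ratio; ``mode="difference"`` subtracts instead); slices with a zero
    cytosolic mean are dropped with a warning. Returns the mean over used
    slices. A uniform cargo distribution gives 1.0 (ratio mode).
    """
    if mode not in ("ratio", "difference"):
        raise ValueError(f"unknown mode {mode!r}")
    if mito_mask.masks.shape != stack.shape_zyx:
        raise EnrichmentError("mito mask shape does not match stack")
    cargo = (
        stack.channel("cargo") if cargo_channel is None else stack.voxels[..., cargo_channel]
    )
    vals = []
    for z in range(stack.shape_zyx[0]):
        m = mito_mask.masks[z]
        if not m.any():
            continue
        cytosol = cell_region.masks[z] & ~m
        if not cytosol.any():
            raise EnrichmentError("no cytosol on a slice with mitochondrial signal")
        in_mean = cargo[z][m].mean()
        out_mean = cargo[z][cytosol].mean()
        if mode == "difference":
            vals.append(in_mean - out_mean)
        elif out_mean == 0:
            warnings.warn(f"slice {z}: zero cytosolic mean, slice dropped", stacklevel=2)
        else:
            vals.append(in_mean / out_mean)
    if not vals:
        raise EnrichmentError("no usable slices for mitochondrial enrichment")
    return float(np.mean(vals))
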