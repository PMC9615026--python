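import numpy as np
import pytest

from puncta import (
    ChannelStack,
    SimulationParams,
    cell_region,
    double_positive_mask,
    peroxisomal_enrichment,
    segment_marker,
    simulate_cos7_cell,
)
from puncta.segment import MaskStack


@pytest.fixture(scope="session")
def cos7_cell():
    """One deterministic wild-type-like COS-7 cell (stack, geometry, truth)."""
    return simulate_cos7_cell(SimulationParams(seed=42))


@pytest.fixture(scope="session")
def cos7_segmented(cos7_cell):
    stack, geometry, truth = cos7_cell
    marker_mask, objects = segment_marker(stack)
    analysis = double_positive_mask(marker_mask, stack)
    region = cell_region(stack, geometry)
    return stack, geometry, truth, marker_mask, objects, analysis, region


def estimate_normalized_enrichment(params: SimulationParams) -> tuple[float, float]:
    """(estimate, truth) of the normalized enrichment for one simulated cell."""
    stack, geometry, truth = simulate_cos7_cell(params)
    marker_mask, _ = segment_marker(stack)
    analysis = double_positive_mask(marker_mask, stack)
    region = cell_region(stack, geometry)
    res = peroxisomal_enrichment(stack, marker_mask, analysis, region)
    return res.normalized_enrichment, truth.normalized_enrichment


def brute_force_enrichment(stack, marker, analysis, region, cargo_c, construct_c):
    """Independent per-pixel re-implementation of the enrichment score.

    Explicit python loops over pixels and slices; no shared code with the
    package beyond numpy's mean.
    """
    vox = stack.voxels
    nz, h, w = vox.shape[:3]
    raw_z, out_z, con_z = [], [], []
    for z in range(nz):
        a_px = [(y, x) for y in range(h) for x in range(w) if analysis[z, y, x]]
        if not a_px:
            continue
        cyt_px = [
            (y, x)
            for y in range(h)
            for x in range(w)
            if region[z, y, x] and not marker[z, y, x]
        ]
        in_mean = np.mean(np.array([vox[z, y, x, cargo_c] for y, x in a_px]))
        out_mean = np.mean(np.array([vox[z, y, x, cargo_c] for y, x in cyt_px]))
        raw_z.append(in_mean - out_mean)
        out_z.append(out_mean)
        con_z.append(np.mean(np.array([vox[z, y, x, construct_c] for y, x in a_px])))
    raw = np.mean(np.array(raw_z))
    construct = np.mean(np.array(con_z))
    return {
        "raw": float(raw),
        "background": float(np.mean(np.array(out_z))),
        "construct": float(construct),
        "normalized": float(raw / construct),
        "n_slices": len(raw_z),
    }


def random_small_case(rng):
    """A random valid (stack, masks) case on a stack of at most 8x8x2."""
    while True:
        nz = int(rng.integers(1, 3))
        h = int(rng.integers(2, 9))
        w = int(rng.integers(2, 9))
        vox = rng.integers(0, 200, size=(nz, h, w, 3)).astype(float)
        marker = rng.random((nz, h, w)) < 0.3
        analysis = marker & (rng.random((nz, h, w)) < 0.7)
        region = rng.random((nz, h, w)) < 0.9
        used = [z for z in range(nz) if analysis[z].any()]
        if not used:
            continue
        if any(not (region[z] & ~marker[z]).any() for z in used):
            continue
        stack = ChannelStack(
            voxels=vox, channel_roles={0: "marker", 1: "construct", 2: "cargo"}
        )
        if all(vox[z][analysis[z]][:, 1].mean() != 0 for z in used):
            return stack, marker, analysis, region


def as_mask_stacks(marker, analysis, region):
    return (
        MaskStack(marker, "marker"),
        MaskStack(analysis, "marker+construct"),
        MaskStack(region, "geometry"),
    )
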