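"""Synthetic fluorescence z-stacks with known ground truth.

Two cell archetypes are emulated. COS-7-like cells: a star-convex outline,
punctate peroxisomes rendered as 2-D Gaussian spots spanning up to three
adjacent z-slices, tubular mitochondria as thickened random polylines, a
membrane-anchored construct on every peroxisome (with configurable
"spillover" onto mitochondria, as seen at high expression levels), and a
diffuse cytosolic cargo background with cargo recruited onto peroxisomes in
proportion to ``recruitment_fraction`` — the generative analog of the
wild-type/GTP-state versus GDP-state constructs. Neuron-like cells: a soma,
a thin neurite, and a growth cone, with peroxisomes placed in requested
numbers per region.

Closed-form truth
-----------------
Cargo spots share the construct spots' exact spatial profile with amplitude
``recruitment_fraction * construct_level`` on top of a uniform cytosolic
background, so the profile and the background cancel in the enrichment
score and the true normalized enrichment is exactly ``recruitment_fraction``
(dimensionless), independent of the mask, spot shape, or background level.

Radial placement draws each peroxisome's normalized radius as
``r = u ** (1 / (1 + radial_bias))`` along a uniformly random ray:
``radial_bias = 0`` concentrates organelles perinuclearly, ``1`` recovers
the area-uniform law ``P(r <= t) = t**2`` of a star-convex cell, and larger
values disperse them peripherally. The expected shell frequencies are
``(k/n)**(1+b) - ((k-1)/n)**(1+b)`` for shell k of n, so the outermost-shell
truth frequency is strictly increasing in the bias.

Additive Gaussian noise is clipped at zero; every generated voxel is
non-negative.
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union
from skimage.draw import line as draw_line
from skimage.draw import polygon2mask
from skimage.morphology import dilation, disk

from .errors import ConfigError
from .io import CellGeometry, ChannelStack
from ._geom import (
    polygon_vertices,
    ray_boundary_distance,
    star_convex_polygon,
    uniform_points_in_polygon,
)

#: Channel layout written by the simulator.
CHANNEL_ROLES = {0: "marker", 1: "construct", 2: "cargo"}

_DEFAULT_N_SHELLS = 10
_MIN_SPOT_SEPARATION = 9.0  # px; keeps projected puncta resolvable at Otsu's threshold


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults are the standard study conditions.

    ``recruitment_fraction`` is the fraction of peroxisomal cargo capacity
    occupied (0 = GDP-state-like, no recruitment; ~0.8 = wild-type-like);
    ``mito_spillover_fraction`` puts that fraction of the construct level
    onto mitochondrial tubules; ``radial_bias`` controls organelle dispersal
    (see module docstring); ``noise_sd`` is the additive Gaussian noise SD
    in intensity units.
    """

    image_shape: tuple[int, int, int] = (4, 192, 192)  # (z, y, x)
    n_peroxisomes: int = 40
    n_mitochondria: int = 6
    recruitment_fraction: float = 0.8
    construct_level: float = 120.0
    cargo_background: float = 20.0
    mito_spillover_fraction: float = 0.3
    radial_bias: float = 1.0
    noise_sd: float = 3.0
    seed: int = 0
    marker_level: float = 150.0
    spot_sigma_px: float = 2.0
    pixel_size_um: float = 0.2
    z_step_um: float = 0.3

    def __post_init__(self) -> None:
        z, h, w = self.image_shape
        if min(z, h, w) < 4:
            raise ConfigError("image_shape extents must all be >= 4")
        if self.n_peroxisomes < 0 or self.n_mitochondria < 0:
            raise ConfigError("organelle counts must be non-negative")
        if not (0.0 <= self.recruitment_fraction <= 1.0):
            raise ConfigError("recruitment_fraction must be in [0, 1]")
        if not (0.0 <= self.mito_spillover_fraction <= 1.0):
            raise ConfigError("mito_spillover_fraction must be in [0, 1]")
        if self.construct_level <= 0:
            raise ConfigError("construct_level must be positive")
        if self.cargo_background < 0 or self.noise_sd < 0 or self.radial_bias < 0:
            raise ConfigError("cargo_background, noise_sd, radial_bias must be >= 0")

    @classmethod
    def neuron_defaults(cls, **overrides) -> "SimulationParams":
        """Neuron-mode conditions: long thin field of view, 0.2-um slices."""
        base = dict(
            image_shape=(4, 160, 320), n_peroxisomes=30, n_mitochondria=0,
            z_step_um=0.2, radial_bias=1.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SimulationTruth:
    """Exact placements and analytically expected readouts."""

    organelle_centroids: np.ndarray  # (n, 3) of (x, y, z)
    per_organelle_enrichment: np.ndarray  # raw amplitude units
    normalized_enrichment: float  # == recruitment_fraction
    shell_truth: np.ndarray  # percent, for the default 10 shells (COS-7 mode)
    radial_exponent: float  # 1 + radial_bias
    roi_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class PanelCell:
    condition: str
    index: int
    params: SimulationParams
    stack: ChannelStack
    geometry: CellGeometry
    truth: SimulationTruth


def _spot_z_weights(z0: int, nz: int) -> dict[int, float]:
    """A punctum spans up to 3 adjacent slices with a 0.5/1.0/0.5 profile."""
    return {z: w for z, w in ((z0 - 1, 0.5), (z0, 1.0), (z0 + 1, 0.5)) if 0 <= z < nz}


def _render_spot(img: np.ndarray, x0: float, y0: float, amp: float, sigma: float) -> None:
    """Add a 2-D Gaussian of peak ``amp`` at (x0, y0) into a (y, x) image."""
    h, w = img.shape
    r = int(math.ceil(4 * sigma))
    ylo, yhi = max(0, int(y0) - r), min(h, int(y0) + r + 1)
    xlo, xhi = max(0, int(x0) - r), min(w, int(x0) + r + 1)
    if ylo >= yhi or xlo >= xhi:
        return
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
    img[ylo:yhi, xlo:xhi] += amp * np.exp(
        -((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2)
    )


def _place_radial(
    outline: Polygon,
    center: tuple[float, float],
    n: int,
    exponent: float,
    rng: np.random.Generator,
    min_sep: float = _MIN_SPOT_SEPARATION,
) -> np.ndarray:
    """Place n points at normalized radius r = u**(1/exponent) along uniform
    rays, greedily enforcing a minimum pairwise separation."""
    placed: list[tuple[float, float]] = []
    for _ in range(n):
        best = None
        for _try in range(200):
            theta = rng.uniform(0.0, 2.0 * math.pi)
            r = min(rng.uniform() ** (1.0 / exponent), 0.95)
            b = ray_boundary_distance(outline, center, theta)
            x = center[0] + r * b * math.cos(theta)
            y = center[1] + r * b * math.sin(theta)
            best = (x, y)
            if all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in placed):
                break
        placed.append(best)
    return np.array(placed) if placed else np.empty((0, 2))


def _place_in_polygon(
    poly: Polygon,
    n: int,
    rng: np.random.Generator,
    existing: list[tuple[float, float]],
    min_sep: float = _MIN_SPOT_SEPARATION,
    margin: float = 4.0,
) -> list[tuple[float, float]]:
    """Uniform placement inside ``poly`` shrunk by ``margin``, min-separated."""
    inner = poly.buffer(-margin)
    if inner.is_empty or not isinstance(inner, Polygon):
        inner = poly
    out: list[tuple[float, float]] = []
    for _ in range(n):
        best = None
        for _try in range(300):
            (x, y), = uniform_points_in_polygon(inner, 1, rng)
            best = (x, y)
            if all(
                (x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in existing + out
            ):
                break
        out.append(best)
    return out


def _rasterize(poly: Polygon, h: int, w: int) -> np.ndarray:
    verts = polygon_vertices(poly)
    return polygon2mask((h, w), verts[:, ::-1])


def _render_cell(
    params: SimulationParams,
    outline: Polygon,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Render marker/construct/cargo channels for spots at ``positions``.

    Returns (voxels, spot_z) where spot_z holds each spot's central slice.
    """
    nz, h, w = params.image_shape
    vox = np.zeros((nz, h, w, 3))
    spot_z = np.empty(len(positions), dtype=int)
    cargo_amp = params.recruitment_fraction * params.construct_level
    for i, (x, y) in enumerate(positions):
        z0 = int(rng.integers(1, nz - 1))
        spot_z[i] = z0
        for z, zw in _spot_z_weights(z0, nz).items():
            _render_spot(vox[z, :, :, 0], x, y, zw * params.marker_level, params.spot_sigma_px)
            _render_spot(vox[z, :, :, 1], x, y, zw * params.construct_level, params.spot_sigma_px)
            if cargo_amp > 0:
                _render_spot(vox[z, :, :, 2], x, y, zw * cargo_amp, params.spot_sigma_px)

    # tubular mitochondria carry construct spillover only
    if params.n_mitochondria > 0 and params.mito_spillover_fraction > 0:
        spill = params.mito_spillover_fraction * params.construct_level
        for _ in range(params.n_mitochondria):
            tub = _mito_tubule(outline, h, w, rng)
            z0 = int(rng.integers(0, nz - 1))
            vox[z0, :, :, 1][tub] += spill
            vox[z0 + 1, :, :, 1][tub] += spill

    # diffuse cytosolic cargo inside the outline
    if params.cargo_background > 0:
        inside = _rasterize(outline, h, w)
        vox[:, :, :, 2][:, inside] += params.cargo_background

    if params.noise_sd > 0:
        vox += rng.normal(0.0, params.noise_sd, vox.shape)
        np.clip(vox, 0.0, None, out=vox)
    return vox, spot_z


def _mito_tubule(
    outline: Polygon, h: int, w: int, rng: np.random.Generator
) -> np.ndarray:
    """A thickened random polyline starting inside the outline."""
    (x, y), = uniform_points_in_polygon(outline, 1, rng)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    img = np.zeros((h, w), dtype=bool)
    for _ in range(3):
        seg = rng.uniform(10.0, 22.0)
        x2 = x + seg * math.cos(theta)
        y2 = y + seg * math.sin(theta)
        rr, cc = draw_line(
            int(np.clip(y, 0, h - 1)), int(np.clip(x, 0, w - 1)),
            int(np.clip(y2, 0, h - 1)), int(np.clip(x2, 0, w - 1)),
        )
        img[rr, cc] = True
        x, y = x2, y2
        theta += rng.uniform(-0.6, 0.6)
    return dilation(img, disk(1))


def expected_shell_frequencies(radial_bias: float, n_shells: int = _DEFAULT_N_SHELLS) -> np.ndarray:
    """Analytic percent frequency per shell under the radial placement law."""
    e = 1.0 + radial_bias
    edges = np.arange(n_shells + 1) / n_shells
    return 100.0 * np.diff(edges**e)


def simulate_cos7_cell(
    params: SimulationParams,
) -> tuple[ChannelStack, CellGeometry, SimulationTruth]:
    """One COS-7-like cell: stack, geometry and exact ground truth.

    Deterministic in ``params.seed`` — identical parameters give
    bit-identical stacks and truths.
    """
    rng = np.random.default_rng(params.seed)
    nz, h, w = params.image_shape
    center = (w / 2.0, h / 2.0)
    outline = star_convex_polygon(center, 0.42 * min(h, w), rng)
    exponent = 1.0 + params.radial_bias
    positions = _place_radial(outline, center, params.n_peroxisomes, exponent, rng)
    vox, spot_z = _render_cell(params, outline, positions, rng)
    stack = ChannelStack(
        voxels=vox, channel_roles=dict(CHANNEL_ROLES),
        z_step_um=params.z_step_um, pixel_size_um=params.pixel_size_um,
    )
    geometry = CellGeometry(outline=outline, center=center)
    n = params.n_peroxisomes
    centroids = (
        np.column_stack([positions, spot_z]) if n else np.empty((0, 3))
    )
    truth = SimulationTruth(
        organelle_centroids=centroids,
        per_organelle_enrichment=np.full(
            n, params.recruitment_fraction * params.construct_level
        ),
        normalized_enrichment=params.recruitment_fraction,
        shell_truth=expected_shell_frequencies(params.radial_bias),
        radial_exponent=exponent,
    )
    return stack, geometry, truth


def simulate_neuron(
    params: SimulationParams, soma_count: int, growth_cone_count: int
) -> tuple[ChannelStack, CellGeometry, SimulationTruth]:
    """One neuron-like cell with ``soma`` and ``growth_cone`` ROIs.

    Exactly ``soma_count`` peroxisomes are placed in the soma ROI,
    ``growth_cone_count`` in the growth cone, and the remainder along the
    neurite; ``truth.roi_counts`` records the requested placements.
    """
    if soma_count + growth_cone_count > params.n_peroxisomes:
        raise ConfigError("soma_count + growth_cone_count exceeds n_peroxisomes")
    rng = np.random.default_rng(params.seed)
    nz, h, w = params.image_shape

    soma_c = (0.18 * w, h / 2.0)
    soma = Point(*soma_c).buffer(0.30 * h, quad_segs=24)
    neurite = Polygon(
        [
            (soma_c[0], h / 2.0 - 0.05 * h), (0.80 * w, h / 2.0 - 0.05 * h),
            (0.80 * w, h / 2.0 + 0.05 * h), (soma_c[0], h / 2.0 + 0.05 * h),
        ]
    )
    growth_cone = Polygon(
        [
            (0.78 * w, h / 2.0), (0.96 * w, h / 2.0 - 0.22 * h),
            (0.97 * w, h / 2.0), (0.96 * w, h / 2.0 + 0.22 * h),
        ]
    )
    outline = unary_union([soma, neurite, growth_cone])
    if not isinstance(outline, Polygon):  # pragma: no cover - by construction
        outline = outline.convex_hull

    pos: list[tuple[float, float]] = []
    pos += _place_in_polygon(soma, soma_count, rng, pos)
    pos += _place_in_polygon(growth_cone, growth_cone_count, rng, pos, margin=3.0)
    n_rest = params.n_peroxisomes - soma_count - growth_cone_count
    if n_rest:
        shaft = neurite.difference(soma).difference(growth_cone)
        pos += _place_in_polygon(shaft, n_rest, rng, pos, margin=2.0)
    positions = np.array(pos) if pos else np.empty((0, 2))

    vox, spot_z = _render_cell(params, outline, positions, rng)
    stack = ChannelStack(
        voxels=vox, channel_roles=dict(CHANNEL_ROLES),
        z_step_um=params.z_step_um, pixel_size_um=params.pixel_size_um,
    )
    geometry = CellGeometry(
        outline=outline, center=soma_c, rois={"soma": soma, "growth_cone": growth_cone}
    )
    truth = SimulationTruth(
        organelle_centroids=(
            np.column_stack([positions, spot_z]) if len(pos) else np.empty((0, 3))
        ),
        per_organelle_enrichment=np.full(
            len(pos), params.recruitment_fraction * params.construct_level
        ),
        normalized_enrichment=params.recruitment_fraction,
        shell_truth=np.array([]),
        radial_exponent=float("nan"),
        roi_counts={"soma": soma_count, "growth_cone": growth_cone_count},
    )
    return stack, geometry, truth


def cell_seed(master_seed: int, condition: str, index: int) -> int:
    """Stable per-cell seed derived from (master seed, label, cell index)."""
    return zlib.crc32(f"{master_seed}:{condition}:{index}".encode()) & 0x7FFFFFFF


def simulate_condition_panel(
    conditions: dict[str, SimulationParams], n_cells_per_condition: int, seed: int
) -> list[PanelCell]:
    """A labeled panel of COS-7-like cells, e.g. 15 cells per condition.

    Per-cell seeds are derived deterministically from the master seed, the
    condition label and the cell index, so panels are reproducible and cells
    are independent.
    """
    if not conditions:
        raise ConfigError("empty condition map")
    if n_cells_per_condition < 1:
        raise ConfigError("n_cells_per_condition must be >= 1")
    panel = []
    for label, base in conditions.items():
        for i in range(n_cells_per_condition):
            p = replace(base, seed=cell_seed(seed, label, i))
            stack, geometry, truth = simulate_cos7_cell(p)
            panel.append(
                PanelCell(
                    condition=label, index=i, params=p,
                    stack=stack, geometry=geometry, truth=truth,
                )
            )
    return panel
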