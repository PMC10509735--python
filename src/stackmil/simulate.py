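"""Synthetic z-stacked H&E tile generator.

Emulates a focal-plane-stacked slide scan at desk scale: a planar tissue
scene (nuclei, stroma, distractor textures) is placed at random depths within
the section, and each focal plane is rendered by blurring every object with a
defocus kernel that widens with its axial distance from the plane.  Class
labels modulate nuclear morphology (mean radius and contour irregularity),
and, optionally, a fine-textured "signal granule" whose high-frequency
content is only resolvable in the focal plane it occupies — giving the stack
genuine axial information that a single plane cannot carry.

Appearance uses a two-stain Beer-Lambert color model: per-pixel hematoxylin
and eosin optical densities are accumulated per depth layer, defocus-blurred,
and exponentiated into RGB.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError
from .utils import derive_rng, derive_seed

__all__ = [
    "SynthConfig", "ZStackTile", "SpecimenBag", "TileScene", "SceneObject",
    "MARKERS", "sigma_defocus", "focal_depth", "generate_tile_scene",
    "render_slice", "render_tile", "scene_nucleus_mask", "generate_specimen",
    "apply_misalignment", "make_virtual_stack", "generate_cohort",
]

MARKERS = ("ER", "PR", "AR", "HER2", "Ki67")

# Ruifrok-Johnston H&E optical-density unit vectors (RGB absorbance).
_OD_HEMATOXYLIN = np.array([0.650, 0.704, 0.286])
_OD_EOSIN = np.array([0.072, 0.990, 0.105])


@dataclass(frozen=True)
class SynthConfig:
    """Acquisition and scene parameters for the synthetic scanner.

    Defaults follow the emulated protocol: 256 px tiles at 0.25 µm/px, 17
    focal planes at 0.5 µm spacing spanning ~8 µm around a 3-4 µm section,
    with ~2 µm axial resolution.
    """

    tile_size: int = 256
    n_slices: int = 17
    slice_interval: float = 0.5        # µm between focal planes
    tissue_thickness: float = 3.5      # µm section thickness
    axial_resolution: float = 2.0      # µm depth-of-focus scale of the objective
    pixel_size: float = 0.25           # µm per pixel
    nuclei_density: float = 40.0       # expected nuclei per tile
    morphology_effect: float = 0.0     # class separation in nuclear morphology
    signal_slice_bias: int | None = None  # focal plane carrying class texture
    misalignment_px: float = 0.0       # max |translation| jitter per slice
    misalignment_deg: float = 0.0      # max |rotation| jitter per slice
    tiles_per_specimen_range: tuple[int, int] = (8, 24)
    seed: int = 0
    # scene/optics details
    defocus_sigma0: float = 0.4        # px; in-focus PSF width
    nucleus_radius_px: float = 9.0
    nucleus_radius_sd: float = 1.8
    noise_level: float = 0.02
    distractor_rate: float = 1.0       # expected distractors per tile, per kind
    signal_contrast: float = 0.45      # mean OD of signal granules
    signal_granules: int = 2           # granules per tile when biased
    signal_granule_radius: float = 0.14  # granule radius as fraction of tile

    def __post_init__(self):
        if self.n_slices < 1:
            raise ConfigurationError("n_slices must be >= 1")
        if self.slice_interval <= 0:
            raise ConfigurationError("slice_interval must be > 0")
        if self.tile_size < 32:
            raise ConfigurationError("tile_size must be >= 32")
        lo, hi = self.tiles_per_specimen_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("tiles_per_specimen_range must satisfy 1 <= min <= max")
        if self.signal_slice_bias is not None and not (0 <= self.signal_slice_bias < self.n_slices):
            raise ConfigurationError("signal_slice_bias must index a slice")
        for name in ("tissue_thickness", "axial_resolution", "pixel_size",
                     "nuclei_density", "defocus_sigma0"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.misalignment_px < 0 or self.misalignment_deg < 0:
            raise ConfigurationError("misalignment bounds must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tiles_per_specimen_range"] = list(self.tiles_per_specimen_range)
        return d


@dataclass
class ZStackTile:
    """One tile's pixel volume across focal planes, with slide provenance.

    ``pixels`` has shape (H, W, 3, n_slices), dtype uint8, page k = plane k
    in ascending depth.
    """

    pixels: np.ndarray
    origin_xy: tuple[int, int]
    specimen_id: str
    pixel_size: float = 0.25

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4 or self.pixels.shape[2] != 3:
            raise ConfigurationError("tile pixels must have shape (H, W, 3, n_slices)")
        if self.pixels.dtype != np.uint8:
            raise ConfigurationError("tile pixels must be uint8")

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[3]

    def slice_image(self, z: int) -> np.ndarray:
        return self.pixels[:, :, :, z]


@dataclass
class SpecimenBag:
    """A specimen's variable-size set of tiles and its per-marker labels."""

    specimen_id: str
    tiles: list[ZStackTile]
    labels: dict[str, int]
    ground_truth_masks: list[np.ndarray] | None = None
    tile_meta: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if len(self.tiles) < 1:
            raise ConfigurationError("a bag needs at least one tile")
        for t in self.tiles:
            if t.specimen_id != self.specimen_id:
                raise ConfigurationError("all tiles must carry the bag's specimen_id")
        for m, v in self.labels.items():
            if v not in (0, 1):
                raise ConfigurationError(f"label for {m} must be 0 or 1")

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)


@dataclass
class SceneObject:
    """A planar stain splat at one depth; densities live on a local bbox."""

    kind: str
    depth_um: float
    y0: int
    x0: int
    h_density: np.ndarray  # hematoxylin OD, local patch
    e_density: np.ndarray  # eosin OD, local patch


@dataclass
class TileScene:
    tile_size: int
    objects: list[SceneObject]
    bg_e_density: np.ndarray   # full-tile eosin background (stroma)
    bg_depth_um: float
    noise_seed: int
    nucleus_mask: np.ndarray   # uint8, in-focus nucleus footprint
    n_nuclei: int


def focal_depth(z_index: int, config: SynthConfig) -> float:
    """Depth (µm) of focal plane ``z_index``; the stack is centered on the section."""
    center = config.tissue_thickness / 2.0
    return center + (z_index - (config.n_slices - 1) / 2.0) * config.slice_interval


def sigma_defocus(dz_um: float, config: SynthConfig) -> float:
    """Defocus blur width (px) at axial distance ``dz_um`` from the focal plane.

    sigma(dz) = sigma0 * sqrt(1 + (dz / axial_resolution)^2): minimal at focus,
    monotonically widening with axial distance on the scale of the objective's
    depth of focus.
    """
    s0 = config.defocus_sigma0
    return float(s0 * np.sqrt(1.0 + (dz_um / config.axial_resolution) ** 2))


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------

def _nucleus_splat(radius: float, irregularity: float, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Render one nucleus: (hematoxylin OD patch, boolean mask patch).

    The boundary radius is modulated by low-order Fourier harmonics of the
    polar angle (contour irregularity); chromatin is clumpy multiplicative
    texture inside the boundary.
    """
    r_max = radius * (1.0 + irregularity * 2.0) + 2.0
    half = int(np.ceil(r_max))
    ax = np.arange(-half, half + 1)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    rr = np.hypot(yy, xx)
    theta = np.arctan2(yy, xx)
    boundary = np.full_like(rr, radius)
    for m in (2, 3, 4, 5):
        amp = irregularity * rng.uniform(0.3, 1.0) / m
        phase = rng.uniform(0, 2 * np.pi)
        boundary = boundary + radius * amp * np.cos(m * theta + phase)
    inside = rr <= boundary
    # soft edge over ~1 px
    edge = np.clip((boundary - rr) + 0.5, 0.0, 1.0)
    chroma = rng.normal(size=rr.shape)
    chroma = ndimage.gaussian_filter(chroma, sigma=max(0.7, radius / 5.0))
    chroma = (chroma - chroma.mean()) / (chroma.std() + 1e-9)
    h = edge * (0.85 + 0.45 * np.clip(chroma, -1.5, 1.5))
    h = np.clip(h, 0.0, None)
    return h, inside


def _fibrosis_splat(tile: int, rng: np.random.Generator) -> np.ndarray:
    """A wavy collagen strand: dense eosin along a quadratic curve."""
    e = np.zeros((tile, tile))
    p0 = rng.uniform(0, tile, size=2)
    p1 = rng.uniform(0, tile, size=2)
    ctrl = (p0 + p1) / 2 + rng.normal(0, tile / 4, size=2)
    t = np.linspace(0, 1, 4 * tile)
    pts = ((1 - t)[:, None] ** 2 * p0 + 2 * ((1 - t) * t)[:, None] * ctrl
           + (t[:, None] ** 2) * p1)
    idx = np.clip(np.round(pts).astype(int), 0, tile - 1)
    e[idx[:, 0], idx[:, 1]] = 1.0
    e = ndimage.gaussian_filter(e, sigma=1.0)
    peak = e.max()
    if peak > 0:
        e *= 0.55 / peak
    return e


def _void_splat(radius: float, rim_od: float, clear: float
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disc-shaped clearing with a thin stained rim (adipocyte or lumen).

    Returns (h_rim, e_rim, clear_weight) patches; ``clear_weight`` in [0,1]
    multiplicatively suppresses background stroma inside the void.
    """
    half = int(np.ceil(radius + 2))
    ax = np.arange(-half, half + 1)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    rr = np.hypot(yy, xx)
    inside = np.clip(radius - rr + 0.5, 0.0, 1.0)
    rim = np.clip(1.0 - np.abs(rr - radius), 0.0, 1.0)
    return rim * rim_od, rim * rim_od * 0.4, inside * clear


def _signal_granule(radius: float, positive: bool, contrast: float,
                    rng: np.random.Generator) -> np.ndarray:
    """A texture disc whose class difference is resolvable only in focus.

    Positive: a lattice of small dense chromatin-like dots; negative: a flat
    disc with the same mean optical density.  In focus, the spiky density
    passes through the convex density-to-intensity transform and the granule
    reads brighter than its flat twin; defocus blur smooths the density
    toward the common mean, and both classes converge to the same appearance.
    """
    half = int(np.ceil(radius + 1))
    ax = np.arange(-half, half + 1)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    inside = (np.hypot(yy, xx) <= radius).astype(float)
    if positive:
        pitch = 4
        lattice = ((yy % pitch == 0) & (xx % pitch == 0)).astype(float)
        dots = ndimage.gaussian_filter(lattice, sigma=0.7)
        pattern = inside * dots
        # exactly match the flat twin's density mass inside the disc, so the
        # only class difference is texture, not total stain
        mass = pattern.sum()
        if mass > 0:
            pattern *= (inside.sum() * contrast) / mass
        return pattern
    return inside * contrast


def _paste(canvas: np.ndarray, patch: np.ndarray, cy: int, cx: int,
           op: str = "add") -> tuple[int, int, np.ndarray]:
    """Clip ``patch`` (centered at cy,cx) to the canvas; returns (y0,x0,clipped)."""
    ph, pw = patch.shape
    y0, x0 = cy - ph // 2, cx - pw // 2
    ys, xs = max(y0, 0), max(x0, 0)
    ye, xe = min(y0 + ph, canvas.shape[0]), min(x0 + pw, canvas.shape[1])
    if ye <= ys or xe <= xs:
        return 0, 0, np.zeros((0, 0))
    clipped = patch[ys - y0:ye - y0, xs - x0:xe - x0]
    if op == "add":
        canvas[ys:ye, xs:xe] += clipped
    elif op == "max":
        np.maximum(canvas[ys:ye, xs:xe], clipped, out=canvas[ys:ye, xs:xe])
    return ys, xs, clipped


def generate_tile_scene(config: SynthConfig, label: int,
                        rng: np.random.Generator) -> TileScene:
    """Build one tile's scene: stroma background, nuclei whose morphology is
    shifted by ``morphology_effect`` for positive labels, label-independent
    distractors, and (if configured) a class-texture granule at the biased
    focal plane."""
    tile = config.tile_size
    scale = tile / 256.0  # distractor geometry scales with tile size

    # stroma background: smooth eosin wash plus fine collagen grain; the grain
    # sits at the section midplane and anchors the best-focus slice centrally
    bg = rng.normal(size=(tile, tile))
    bg = ndimage.gaussian_filter(bg, sigma=max(2.0, 6.0 * scale))
    bg = (bg - bg.min()) / (np.ptp(bg) + 1e-9)
    grain = ndimage.gaussian_filter(rng.normal(size=(tile, tile)), sigma=0.7)
    grain = grain / (grain.std() + 1e-9)
    bg_e = 0.18 + 0.18 * bg + np.clip(0.22 * grain, -0.3, 0.3)
    bg_e = np.clip(bg_e, 0.02, None)
    clear_weight = np.zeros((tile, tile))

    objects: list[SceneObject] = []
    mask = np.zeros((tile, tile), dtype=np.uint8)

    # nuclei: positive labels draw from a shifted morphology distribution
    mu_r = config.nucleus_radius_px * (1.0 + 0.15 * config.morphology_effect * label)
    irr = 0.05 + 0.05 * config.morphology_effect * label
    n_nuclei = int(rng.poisson(config.nuclei_density))
    n_nuclei = max(n_nuclei, 1)
    for _ in range(n_nuclei):
        r = float(np.clip(rng.normal(mu_r, config.nucleus_radius_sd),
                          1.5, 4.0 * config.nucleus_radius_px))
        h, inside = _nucleus_splat(r, irr, rng)
        cy, cx = rng.integers(0, tile, size=2)
        # nuclei are comparable in size to the section thickness, so their
        # centers cluster around the midplane rather than spreading uniformly
        depth = float(np.clip(
            rng.normal(config.tissue_thickness / 2.0, config.tissue_thickness / 6.0),
            0.0, config.tissue_thickness))
        canvas = np.zeros((tile, tile))
        y0, x0, clipped = _paste(canvas, h, int(cy), int(cx))
        if clipped.size == 0:
            continue
        objects.append(SceneObject("nucleus", depth, y0, x0, clipped,
                                   0.12 * clipped))
        # paste the boolean footprint into the ground-truth mask
        mfloat = np.zeros((tile, tile))
        _paste(mfloat, inside.astype(float), int(cy), int(cx))
        mask |= (mfloat > 0.5).astype(np.uint8)

    # distractors: fibrosis strands, adipocyte voids, lumen rings (label-free)
    for _ in range(int(rng.poisson(config.distractor_rate))):
        e = _fibrosis_splat(tile, rng)
        depth = float(rng.uniform(0.0, config.tissue_thickness))
        objects.append(SceneObject("fibrosis", depth, 0, 0,
                                   0.05 * e, e))
    for kind, rim in (("adipocyte", 0.25), ("lumen", 0.7)):
        for _ in range(int(rng.poisson(config.distractor_rate))):
            radius = rng.uniform(0.06, 0.14) * tile
            h_rim, e_rim, clearing = _void_splat(radius, rim, clear=0.9)
            cy, cx = rng.integers(0, tile, size=2)
            depth = float(rng.uniform(0.0, config.tissue_thickness))
            canvas_h = np.zeros((tile, tile))
            y0, x0, ch = _paste(canvas_h, h_rim, int(cy), int(cx))
            if ch.size == 0:
                continue
            canvas_e = np.zeros((tile, tile))
            _paste(canvas_e, e_rim, int(cy), int(cx))
            ce = canvas_e[y0:y0 + ch.shape[0], x0:x0 + ch.shape[1]]
            objects.append(SceneObject(kind, depth, y0, x0, ch, ce))
            _paste(clear_weight, clearing, int(cy), int(cx), op="max")

    bg_e = bg_e * (1.0 - np.clip(clear_weight, 0.0, 1.0))

    # class-texture granules pinned to the biased focal plane
    if config.signal_slice_bias is not None:
        depth = focal_depth(config.signal_slice_bias, config)
        for _ in range(config.signal_granules):
            radius = config.signal_granule_radius * tile
            g = _signal_granule(radius, positive=(label == 1),
                                contrast=config.signal_contrast, rng=rng)
            cy, cx = rng.integers(int(radius), tile - int(radius) + 1, size=2)
            canvas = np.zeros((tile, tile))
            y0, x0, clipped = _paste(canvas, g, int(cy), int(cx))
            if clipped.size:
                objects.append(SceneObject("signal", depth, y0, x0, clipped,
                                           np.zeros_like(clipped)))

    return TileScene(tile_size=tile, objects=objects, bg_e_density=bg_e,
                     bg_depth_um=config.tissue_thickness / 2.0,
                     noise_seed=int(rng.integers(0, 2 ** 31)),
                     nucleus_mask=mask, n_nuclei=n_nuclei)


# ---------------------------------------------------------------------------
# optical rendering
# ---------------------------------------------------------------------------

def _depth_layers(scene: TileScene, config: SynthConfig
                  ) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Group objects into depth bins of width slice_interval/2; returns
    (depth, H-density, E-density) full-tile layers."""
    grid = config.slice_interval / 2.0
    tile = scene.tile_size
    layers: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def layer_for(depth: float) -> tuple[np.ndarray, np.ndarray]:
        key = round(depth / grid) * grid
        if key not in layers:
            layers[key] = (np.zeros((tile, tile)), np.zeros((tile, tile)))
        return layers[key]

    hbg, ebg = layer_for(scene.bg_depth_um)
    ebg += scene.bg_e_density
    for obj in scene.objects:
        h, e = layer_for(obj.depth_um)
        ph, pw = obj.h_density.shape
        h[obj.y0:obj.y0 + ph, obj.x0:obj.x0 + pw] += obj.h_density
        e[obj.y0:obj.y0 + ph, obj.x0:obj.x0 + pw] += obj.e_density
    return [(d, h, e) for d, (h, e) in sorted(layers.items())]


def _od_to_rgb(h_od: np.ndarray, e_od: np.ndarray, noise_rng: np.random.Generator,
               noise_level: float) -> np.ndarray:
    od = h_od[..., None] * _OD_HEMATOXYLIN + e_od[..., None] * _OD_EOSIN
    rgb = 255.0 * np.exp(-od)
    if noise_level > 0:
        smooth = noise_rng.normal(size=h_od.shape)
        smooth = ndimage.gaussian_filter(smooth, sigma=1.0)
        grain = noise_rng.normal(size=h_od.shape)
        factor = 1.0 + noise_level * smooth + 0.5 * noise_level * grain
        rgb = rgb * factor[..., None]
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def render_slice(scene: TileScene, z_index: int, config: SynthConfig) -> np.ndarray:
    """Render focal plane ``z_index``: every depth layer blurred by its
    defocus width, composited in optical density, converted to RGB.

    With a single-plane stack (n_slices == 1) every object is treated as
    in focus — a single-plane scan carries no axial structure.
    """
    if not (0 <= z_index < config.n_slices):
        raise IndexError(f"z_index {z_index} out of range for {config.n_slices} slices")
    plane = focal_depth(z_index, config)
    h_total = np.zeros((scene.tile_size, scene.tile_size))
    e_total = np.zeros_like(h_total)
    for depth, h, e in _depth_layers(scene, config):
        dz = 0.0 if config.n_slices == 1 else abs(depth - plane)
        sigma = sigma_defocus(dz, config)
        h_total += ndimage.gaussian_filter(h, sigma=sigma)
        e_total += ndimage.gaussian_filter(e, sigma=sigma)
    noise_rng = np.random.default_rng(
        np.random.SeedSequence([scene.noise_seed, z_index]))
    return _od_to_rgb(h_total, e_total, noise_rng, config.noise_level)


def render_tile(scene: TileScene, config: SynthConfig) -> np.ndarray:
    """All focal planes of one scene: (H, W, 3, n_slices) uint8."""
    slices = [render_slice(scene, z, config) for z in range(config.n_slices)]
    return np.stack(slices, axis=-1)


def scene_nucleus_mask(scene: TileScene, config: SynthConfig) -> np.ndarray:
    """In-focus nucleus footprint of the scene (uint8, 0/1)."""
    return scene.nucleus_mask.copy()


# ---------------------------------------------------------------------------
# bags, misalignment, virtual stacks, cohorts
# ---------------------------------------------------------------------------

def generate_specimen(config: SynthConfig, label: int, specimen_seed: int,
                      specimen_id: str | None = None) -> SpecimenBag:
    """One specimen bag: tile count drawn from ``tiles_per_specimen_range``,
    each tile rendered through the defocus model, ground-truth nucleus masks
    recorded.  Pure function of (config, label, specimen_seed)."""
    if label not in (0, 1):
        raise ConfigurationError("label must be 0 or 1")
    rng = derive_rng(config.seed, "specimen", specimen_seed, label)
    sid = specimen_id if specimen_id is not None else f"S{specimen_seed:05d}"
    lo, hi = config.tiles_per_specimen_range
    n_tiles = int(rng.integers(lo, hi + 1))
    grid_cols = max(1, int(np.ceil(np.sqrt(n_tiles))))
    tiles, masks, meta = [], [], []
    for i in range(n_tiles):
        scene = generate_tile_scene(config, label, rng)
        pixels = render_tile(scene, config)
        origin = ((i % grid_cols) * config.tile_size,
                  (i // grid_cols) * config.tile_size)
        tiles.append(ZStackTile(pixels=pixels, origin_xy=origin, specimen_id=sid,
                                pixel_size=config.pixel_size))
        m = scene_nucleus_mask(scene, config)
        masks.append(m)
        meta.append({"n_nuclei": scene.n_nuclei,
                     "nucleus_area_px": int(m.sum())})
    labels = {m: int(label) for m in MARKERS}
    return SpecimenBag(specimen_id=sid, tiles=tiles, labels=labels,
                       ground_truth_masks=masks, tile_meta=meta)


def _affine_slice(img: np.ndarray, tx: float, ty: float, deg: float,
                  order: int = 3) -> np.ndarray:
    """Rotate about the tile center then translate; reflection-filled edges.

    ``img`` is (H, W, 3) uint8; returns the same dtype/shape.
    """
    out = np.empty_like(img)
    theta = np.deg2rad(deg)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])  # (y, x) convention
    center = (np.array(img.shape[:2]) - 1) / 2.0
    offset = center - rot @ center - np.array([ty, tx])
    for ch in range(img.shape[2]):
        warped = ndimage.affine_transform(img[:, :, ch].astype(np.float64), rot,
                                          offset=offset, order=order, mode="reflect")
        out[:, :, ch] = np.clip(np.round(warped), 0, 255).astype(np.uint8)
    return out


def apply_misalignment(bag: SpecimenBag, config: SynthConfig, seed: int
                       ) -> tuple[SpecimenBag, list[list[dict]]]:
    """Jitter every non-reference slice by a random small affine (|t| <=
    misalignment_px per axis, |angle| <= misalignment_deg); the central slice
    is the reference.  Returns the jittered bag and the applied ground-truth
    transforms (one dict per tile per slice)."""
    rng = derive_rng(config.seed, "misalign", seed)
    ref = (config.n_slices - 1) // 2
    new_tiles: list[ZStackTile] = []
    transforms: list[list[dict]] = []
    for tile in bag.tiles:
        n_z = tile.n_slices
        pix = tile.pixels.copy()
        per_slice: list[dict] = []
        for z in range(n_z):
            if z == ref or (config.misalignment_px == 0 and config.misalignment_deg == 0):
                per_slice.append({"tx": 0.0, "ty": 0.0, "deg": 0.0})
                continue
            tx = float(rng.uniform(-config.misalignment_px, config.misalignment_px))
            ty = float(rng.uniform(-config.misalignment_px, config.misalignment_px))
            deg = float(rng.uniform(-config.misalignment_deg, config.misalignment_deg))
            pix[:, :, :, z] = _affine_slice(tile.pixels[:, :, :, z], tx, ty, deg)
            per_slice.append({"tx": tx, "ty": ty, "deg": deg})
        new_tiles.append(ZStackTile(pixels=pix, origin_xy=tile.origin_xy,
                                    specimen_id=tile.specimen_id,
                                    pixel_size=tile.pixel_size))
        transforms.append(per_slice)
    new_bag = SpecimenBag(specimen_id=bag.specimen_id, tiles=new_tiles,
                          labels=dict(bag.labels),
                          ground_truth_masks=bag.ground_truth_masks,
                          tile_meta=list(bag.tile_meta))
    return new_bag, transforms


def make_virtual_stack(in_focus: np.ndarray, config: SynthConfig,
                       specimen_id: str = "virtual",
                       origin_xy: tuple[int, int] = (0, 0)) -> ZStackTile:
    """A control stack with the defocus *appearance* of a real stack but no
    axial information: the central slice equals the input bit-exactly and
    every other slice is the input blurred with width growing with distance
    from the center.  The extra blur sigma0*d/axial_resolution composes with
    the capture PSF to reproduce sigma_defocus(d) exactly."""
    img = np.asarray(in_focus)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ConfigurationError("in_focus must be an (H, W, 3) RGB image")
    center = (config.n_slices - 1) // 2
    slices = []
    base = img.astype(np.float64)
    for z in range(config.n_slices):
        dz = abs(z - center) * config.slice_interval
        if dz == 0:
            slices.append(img.astype(np.uint8))
            continue
        sigma = config.defocus_sigma0 * dz / config.axial_resolution
        blurred = np.stack([ndimage.gaussian_filter(base[:, :, c], sigma=sigma)
                            for c in range(3)], axis=-1)
        slices.append(np.clip(np.round(blurred), 0, 255).astype(np.uint8))
    return ZStackTile(pixels=np.stack(slices, axis=-1), origin_xy=origin_xy,
                      specimen_id=specimen_id,
                      pixel_size=config.pixel_size)


def generate_cohort(config: SynthConfig, n_specimens: int, positive_fraction: float,
                    seed: int) -> tuple[list[SpecimenBag], pd.DataFrame]:
    """A labeled cohort: round(n * positive_fraction) positive bags, the rest
    negative, order shuffled; returns the bags and the label table in the
    pipeline's CSV dialect (specimen_id, ER, PR, AR, HER2, Ki67)."""
    if n_specimens < 2:
        raise ConfigurationError("n_specimens must be >= 2")
    if not (0.0 < positive_fraction < 1.0):
        raise ConfigurationError("positive_fraction must be in (0, 1)")
    n_pos = int(round(n_specimens * positive_fraction))
    labels = np.array([1] * n_pos + [0] * (n_specimens - n_pos))
    rng = derive_rng(seed, "cohort-order")
    rng.shuffle(labels)
    bags = []
    rows = []
    for i, lab in enumerate(labels):
        sid = f"S{i:05d}"
        bag = generate_specimen(dataclasses.replace(config, seed=derive_seed(seed, "cohort")),
                                int(lab), specimen_seed=i, specimen_id=sid)
        bags.append(bag)
        rows.append({"specimen_id": sid, **{m: int(lab) for m in MARKERS}})
    table = pd.DataFrame(rows, columns=["specimen_id", *MARKERS])
    return bags, table
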