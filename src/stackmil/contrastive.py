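"""Contrastive per-slice pretraining of the 2D encoder, and frozen feature
extraction producing one feature vector per focal plane (a D x Z stack).

Each focal-plane slice of each tile is a pretraining instance; the two views
of an instance are independent draws from the augmentation menu (random
resized crop, right-angle rotations, horizontal flip, color jitter, grayscale,
Gaussian blur, solarization).  The temperature-scaled InfoNCE objective pulls
the two views of a slice together and pushes apart views of different slices;
the projection head used during pretraining is discarded for extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize

from . import nn
from .errors import ConfigurationError, DataError, ValidationError
from .simulate import SpecimenBag
from .utils import content_hash, derive_rng

__all__ = [
    "AugmentationConfig", "SslConfig", "EncoderSpec", "FeatureStack",
    "SliceRecord", "ConvEncoder", "build_encoder", "augment_view",
    "info_nce_loss", "train_ssl", "extract_features", "extract_bag_features",
    "slices_from_bags", "save_encoder", "load_encoder",
]


@dataclass(frozen=True)
class AugmentationConfig:
    """View-generation menu; strengths follow common contrastive defaults."""

    crop_scale_range: tuple[float, float] = (0.4, 1.0)
    rotation_set: tuple[int, ...] = (0, 90, 180, 270)
    horizontal_flip_prob: float = 0.5
    color_jitter_prob: float = 0.8
    brightness: float = 0.4
    contrast: float = 0.4
    saturation: float = 0.4
    hue: float = 0.1
    grayscale_prob: float = 0.2
    gaussian_blur_prob: float = 0.5
    blur_sigma_range: tuple[float, float] = (0.1, 2.0)
    solarize_prob: float = 0.2
    solarize_threshold: int = 128
    output_size: int = 32

    def __post_init__(self):
        lo, hi = self.crop_scale_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError("crop_scale_range must lie within (0, 1]")
        for name in ("horizontal_flip_prob", "color_jitter_prob", "grayscale_prob",
                     "gaussian_blur_prob", "solarize_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must be a probability")
        if any(a % 90 != 0 for a in self.rotation_set):
            raise ConfigurationError("rotation_set must contain right angles only")


@dataclass(frozen=True)
class SslConfig:
    """Contrastive-pretraining hyperparameters (full-scale defaults)."""

    batch_size: int = 256
    epochs: int = 250
    learning_rate: float = 0.0003
    temperature: float = 0.5
    projection_dim: int = 128
    feature_dim: int = 1024
    precision_mode: str = "single"  # 'mixed' stores view batches in float32
    max_slices_per_epoch: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be > 0")
        if self.feature_dim < 1:
            raise ConfigurationError("feature_dim must be >= 1")
        if self.batch_size < 2:
            raise ConfigurationError("batch_size must be >= 2 for training")
        if self.precision_mode not in ("single", "mixed"):
            raise ConfigurationError("precision_mode must be 'single' or 'mixed'")


@dataclass(frozen=True)
class EncoderSpec:
    """2D encoder family: a strided small CNN whose final convolutional stage
    is the Grad-CAM tap layer.  ``conv_widths`` sets depth and capacity;
    full-scale runs would widen these, desk-scale runs keep them small."""

    architecture: str = "smallconv"
    input_size: int = 32
    feature_dim: int = 32
    conv_widths: tuple[int, ...] = (8, 16, 32)

    def __post_init__(self):
        if self.architecture != "smallconv":
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        if len(self.conv_widths) < 1:
            raise ConfigurationError("conv_widths must be non-empty")


@dataclass
class FeatureStack:
    """Per-tile encoded representation: one feature column per focal plane."""

    values: np.ndarray  # (D, Z)
    specimen_id: str = ""
    tile_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("FeatureStack values must be (D, Z)")


@dataclass
class SliceRecord:
    """One pretraining instance: a single focal-plane slice of a tile."""

    image: np.ndarray  # (H, W, 3) uint8
    specimen_id: str
    tile_id: str = ""
    z: int = 0


class ConvEncoder(nn.Module):
    """Strided conv stack -> global average + max pooling -> linear head.

    The pooled descriptor concatenates the spatial mean and the spatial
    maximum of each channel: the mean carries stain/occupancy statistics,
    the maximum carries peak texture responses (fine chromatin and other
    high-frequency structure that averaging washes out).
    ``forward_with_conv`` also returns the final conv activations, the layer
    Grad-CAM attributions are computed at.
    """

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        in_ch = 3
        convs = []
        for i, width in enumerate(spec.conv_widths):
            convs.append(nn.Conv2d(in_ch, width, kernel_size=3, rng=rng,
                                   stride=2, padding=1))
            in_ch = width
        self.convs = convs
        for i, c in enumerate(convs):
            setattr(self, f"conv{i}", c)
        self.head = nn.Linear(2 * in_ch, spec.feature_dim, rng=rng)

    def forward_with_conv(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        h = x
        for conv in self.convs:
            h = conv(h).relu()
        avg = h.mean(axis=(2, 3))
        peak = h.reshape(h.shape[0], h.shape[1], -1).max(axis=2)
        features = self.head(nn.concatenate([avg, peak], axis=1))
        return features, h

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.forward_with_conv(x)[0]


class ProjectionHead(nn.Module):
    """2-layer nonlinear head used only during pretraining."""

    def __init__(self, in_dim: int, proj_dim: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(in_dim, in_dim, rng=rng)
        self.fc2 = nn.Linear(in_dim, proj_dim, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.fc2(self.fc1(x).relu())


def build_encoder(spec: EncoderSpec, seed: int = 0) -> ConvEncoder:
    return ConvEncoder(spec, derive_rng(seed, "encoder-init"))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _jitter_colors(img: np.ndarray, cfg: AugmentationConfig,
                   rng: np.random.Generator) -> np.ndarray:
    f_b = rng.uniform(1 - cfg.brightness, 1 + cfg.brightness)
    f_c = rng.uniform(1 - cfg.contrast, 1 + cfg.contrast)
    f_s = rng.uniform(1 - cfg.saturation, 1 + cfg.saturation)
    d_h = rng.uniform(-cfg.hue, cfg.hue)
    img = img * f_b
    mean = img.mean()
    img = mean + (img - mean) * f_c
    gray = img.mean(axis=2, keepdims=True)
    img = gray + (img - gray) * f_s
    if cfg.hue > 0:
        hsv = rgb2hsv(np.clip(img, 0, 255) / 255.0)
        hsv[..., 0] = (hsv[..., 0] + d_h) % 1.0
        img = hsv2rgb(hsv) * 255.0
    return img


def augment_view(slice_image: np.ndarray, config: AugmentationConfig,
                 rng_state: np.random.Generator) -> np.ndarray:
    """One stochastic view of an RGB slice; same generator state reproduces
    the same view.  Output is uint8 with ``output_size`` dimensions."""
    img = np.asarray(slice_image)
    h, w = img.shape[:2]
    rng = rng_state

    # random resized crop (square, area scale within the configured range)
    lo, hi = config.crop_scale_range
    scale = rng.uniform(lo, hi)
    side = max(1, int(round(np.sqrt(scale) * min(h, w))))
    side = min(side, h, w)
    y0 = int(rng.integers(0, h - side + 1))
    x0 = int(rng.integers(0, w - side + 1))
    out = img[y0:y0 + side, x0:x0 + side].astype(np.float64)
    if side != config.output_size:
        out = resize(out, (config.output_size, config.output_size, 3),
                     preserve_range=True, anti_aliasing=side > config.output_size)

    angle = int(rng.choice(list(config.rotation_set)))
    if angle % 360:
        out = np.rot90(out, k=(angle // 90) % 4, axes=(0, 1))
    if rng.uniform() < config.horizontal_flip_prob:
        out = out[:, ::-1]
    if rng.uniform() < config.color_jitter_prob:
        out = _jitter_colors(out, config, rng)
    if rng.uniform() < config.grayscale_prob:
        out = np.repeat(out.mean(axis=2, keepdims=True), 3, axis=2)
    if rng.uniform() < config.gaussian_blur_prob:
        sigma = rng.uniform(*config.blur_sigma_range)
        out = np.stack([ndimage.gaussian_filter(out[..., c], sigma) for c in range(3)],
                       axis=-1)
    if rng.uniform() < config.solarize_prob:
        out = np.where(out >= config.solarize_threshold, 255.0 - out, out)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def info_nce_loss(projections: nn.Tensor | np.ndarray, temperature: float = 0.5
                  ) -> nn.Tensor:
    """Temperature-scaled contrastive loss over paired rows.

    Rows 2i and 2i+1 are the two views of instance i.  Rows are L2-normalized;
    for each anchor a the loss is -log( exp(sim(a, pos)/t) /
    sum_{o != a} exp(sim(a, o)/t) ), averaged over all 2B anchors.  With a
    single pair (B=1) the denominator equals the numerator and the loss is 0.
    """
    if temperature <= 0:
        raise ConfigurationError("temperature must be > 0")
    z = projections if isinstance(projections, nn.Tensor) else nn.Tensor(projections)
    n = z.shape[0]
    if n < 2 or n % 2 != 0:
        raise ValidationError("projections must hold an even number >= 2 of paired rows")
    z = nn.l2_normalize(z, axis=1)
    sim = (z @ z.T) * (1.0 / temperature)
    mask = np.where(np.eye(n, dtype=bool), -1e9, 0.0)  # exclude self-similarity
    logits = sim + nn.Tensor(mask)
    idx = np.arange(n)
    pos = logits[idx, idx ^ 1]
    denom = nn.logsumexp(logits, axis=1)
    return (denom - pos).mean()


# ---------------------------------------------------------------------------
# training and extraction
# ---------------------------------------------------------------------------

def slices_from_bags(bags: Iterable[SpecimenBag]) -> list[SliceRecord]:
    """Unroll bags into per-slice pretraining instances."""
    records = []
    for bag in bags:
        for i, tile in enumerate(bag.tiles):
            for z in range(tile.n_slices):
                records.append(SliceRecord(image=tile.pixels[:, :, :, z],
                                           specimen_id=bag.specimen_id,
                                           tile_id=f"{bag.specimen_id}_t{i:03d}", z=z))
    return records


def _to_batch(images: Sequence[np.ndarray], mixed: bool) -> nn.Tensor:
    arr = np.stack([np.moveaxis(im, 2, 0) for im in images]).astype(
        np.float32 if mixed else np.float64) / 255.0
    return nn.Tensor(arr.astype(np.float64))


def train_ssl(slices: Sequence[SliceRecord], encoder_spec: EncoderSpec,
              ssl_config: SslConfig, aug_config: AugmentationConfig,
              ) -> tuple[ConvEncoder, list[float], set[str]]:
    """Contrastive pretraining; returns (encoder, per-epoch mean loss trace,
    consumed specimen ids).  The consumed-id set is the fold-hygiene audit
    record: it must stay disjoint from held-out specimens."""
    slices = list(slices)
    if not slices:
        raise DataError("empty pretraining corpus")
    rng = derive_rng(ssl_config.seed, "ssl-train")
    encoder = build_encoder(encoder_spec, seed=ssl_config.seed)
    head = ProjectionHead(encoder_spec.feature_dim, ssl_config.projection_dim,
                          derive_rng(ssl_config.seed, "proj-init"))
    params = list(encoder.parameters()) + list(head.parameters())
    opt = nn.Adam(params, lr=ssl_config.learning_rate)
    consumed = {s.specimen_id for s in slices}
    mixed = ssl_config.precision_mode == "mixed"

    if len(slices) < ssl_config.batch_size:
        warnings.warn(
            f"corpus ({len(slices)} slices) smaller than batch size "
            f"{ssl_config.batch_size}; batches will be truncated", stacklevel=2)

    trace: list[float] = []
    for epoch in range(ssl_config.epochs):
        order = rng.permutation(len(slices))
        if ssl_config.max_slices_per_epoch is not None:
            order = order[:ssl_config.max_slices_per_epoch]
        losses = []
        for start in range(0, len(order), ssl_config.batch_size):
            batch_idx = order[start:start + ssl_config.batch_size]
            if len(batch_idx) < 2:
                continue
            views = []
            for i in batch_idx:
                img = slices[int(i)].image
                views.append(augment_view(img, aug_config, rng))
                views.append(augment_view(img, aug_config, rng))
            x = _to_batch(views, mixed)
            z = head(encoder(x))
            loss = info_nce_loss(z, ssl_config.temperature)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        trace.append(float(np.mean(losses)) if losses else float("nan"))
    encoder.eval()
    return encoder, trace, consumed


def extract_features(encoder: ConvEncoder, stack) -> FeatureStack:
    """Frozen per-slice encoding of one tile: column z is the encoder output
    on slice z, so a D x Z stack for a (H, W, 3, Z) tile.  Slices are treated
    independently; extraction is deterministic for fixed parameters."""
    pixels = stack.pixels if hasattr(stack, "pixels") else np.asarray(stack)
    if pixels.ndim != 4 or pixels.shape[2] != 3:
        raise ValidationError("expected a (H, W, 3, Z) tile stack")
    if pixels.shape[0] != encoder.spec.input_size:
        raise ValidationError(
            f"slice size {pixels.shape[0]} incompatible with encoder input "
            f"size {encoder.spec.input_size}")
    n_z = pixels.shape[3]
    batch = _to_batch([pixels[:, :, :, z] for z in range(n_z)], mixed=False)
    with nn.no_grad():
        feats = encoder(batch)  # (Z, D)
    sid = getattr(stack, "specimen_id", "")
    return FeatureStack(values=feats.data.T.copy(), specimen_id=sid)


def extract_bag_features(encoder: ConvEncoder, bags: Iterable[SpecimenBag]
                         ) -> dict[str, np.ndarray]:
    """Features for every tile of every bag: specimen_id -> (N, D, Z)."""
    out: dict[str, np.ndarray] = {}
    for bag in bags:
        stacks = [extract_features(encoder, t).values for t in bag.tiles]
        out[bag.specimen_id] = np.stack(stacks, axis=0)
    return out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_encoder(encoder: ConvEncoder, path: str | Path,
                 ssl_config: SslConfig | None = None, fold: int | None = None,
                 corpus_hash: str | None = None) -> Path:
    """Parameter archive (.npz) plus JSON sidecar with spec and provenance."""
    import dataclasses as _dc
    import json
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **encoder.state_dict())
    sidecar = {
        "encoder_spec": _dc.asdict(encoder.spec),
        "ssl_config": _dc.asdict(ssl_config) if ssl_config else None,
        "fold": fold,
        "corpus_hash": corpus_hash,
        "param_hash": content_hash({k: v for k, v in encoder.state_dict().items()}),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def load_encoder(path: str | Path) -> ConvEncoder:
    import json
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    spec_d = sidecar["encoder_spec"]
    spec_d["conv_widths"] = tuple(spec_d["conv_widths"])
    spec = EncoderSpec(**spec_d)
    encoder = build_encoder(spec, seed=0)
    with np.load(path) as archive:
        encoder.load_state_dict({k: archive[k] for k in archive.files})
    encoder.eval()
    return encoder
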