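"""Interpretation outputs: Grad-CAM slice-wise importance curves, attention
heatmap overlays, and a 2D embedding export for feature diagnostics.

Slice importance asks "which focal planes carry the evidence?": for every
tile slice, a Grad-CAM map is taken at the encoder's final convolutional
stage for the model's predicted class, rectified and summed over the spatial
axes, then averaged over tiles and specimens and normalized to a probability
vector over slices.  A model that truly uses axial structure concentrates
mass on informative planes; a depth-blind one yields a flat curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import nn
from .contrastive import ConvEncoder
from .errors import DataError, ValidationError
from .mil import AttentionScores, MilModel
from .simulate import SpecimenBag
from .utils import content_hash

__all__ = [
    "SliceImportance", "HeatmapOverlay", "slice_importance",
    "attention_heatmap", "embed_2d",
]


@dataclass
class SliceImportance:
    """Normalized per-focal-plane importance with a spread estimate."""

    importance: np.ndarray  # (Z,), nonnegative, sums to 1
    sd: np.ndarray          # (Z,), std across specimens
    n_specimens: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.importance = np.asarray(self.importance, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        if np.any(self.importance < -1e-12):
            raise ValidationError("importance must be nonnegative")
        if abs(self.importance.sum() - 1.0) > 1e-6:
            raise ValidationError("importance must sum to 1")


@dataclass
class HeatmapOverlay:
    """Attention painted over tile footprints on a specimen thumbnail."""

    base: np.ndarray           # (H, W, 3) uint8 thumbnail
    intensity: np.ndarray      # (H, W) float in [0, 1]
    tile_intensities: np.ndarray  # (N,) min-max normalized weights
    colormap: str = "inferno"
    provenance: dict = field(default_factory=dict)

    def render(self, alpha: float = 0.45) -> np.ndarray:
        """Blend the intensity map over the thumbnail; returns uint8 RGB."""
        import matplotlib
        colors = matplotlib.colormaps[self.colormap](self.intensity)[..., :3]
        out = (1 - alpha) * self.base.astype(np.float64) / 255.0 + alpha * colors
        return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)


def _bag_grad_cam(model: MilModel, encoder: ConvEncoder, tiles_pixels: Sequence[np.ndarray]
                  ) -> np.ndarray:
    """Per-slice Grad-CAM mass for one bag: (Z,) nonnegative vector.

    Forward runs every slice of every tile through the encoder with the
    graph retained; the backward pass starts from the predicted-class logit.
    """
    conv_acts: list[nn.Tensor] = []
    columns: list[nn.Tensor] = []
    for pix in tiles_pixels:
        n_z = pix.shape[3]
        batch = np.stack([np.moveaxis(pix[:, :, :, z], 2, 0) for z in range(n_z)])
        x = nn.Tensor(batch.astype(np.float64) / 255.0)
        feats, acts = encoder.forward_with_conv(x)  # (Z, D), (Z, C, h, w)
        acts.retain_grad()
        conv_acts.append(acts)
        columns.append(feats.T)  # (D, Z)
    bag_features = nn.stack(columns, axis=0)  # (N, D, Z)
    logits = model.forward_logits(bag_features)
    predicted = int(np.argmax(logits.data))
    model.zero_grad()
    encoder.zero_grad()
    logits[predicted].backward()

    n_z = tiles_pixels[0].shape[3]
    per_tile = []
    for acts in conv_acts:
        if acts.grad is None:
            per_tile.append(np.zeros(n_z))
            continue
        # channel weights: spatial mean of the gradient, per slice
        alpha = acts.grad.mean(axis=(2, 3))                      # (Z, C)
        cam = np.einsum("zc,zchw->zhw", alpha, acts.data)        # (Z, h, w)
        cam = np.maximum(cam, 0.0)                               # rectify
        per_tile.append(cam.sum(axis=(1, 2)))                    # (Z,)
    return np.mean(per_tile, axis=0)


def slice_importance(model: MilModel, encoder: ConvEncoder,
                     bags: Iterable[SpecimenBag]) -> SliceImportance:
    """Grad-CAM slice-wise importance over a held-out set.

    Per specimen: Grad-CAM maps at the encoder's final conv stage for the
    predicted class, rectified, summed over height and width, averaged over
    tiles, then normalized per specimen.  The curve is the specimen mean
    (renormalized); the spread is the across-specimen SD.  All-zero
    attributions (dead gradients) raise a diagnostic error.
    """
    per_specimen: list[np.ndarray] = []
    sids = []
    for bag in bags:
        vec = _bag_grad_cam(model, encoder, [t.pixels for t in bag.tiles])
        total = vec.sum()
        if total > 0:
            per_specimen.append(vec / total)
            sids.append(bag.specimen_id)
    if not per_specimen:
        raise DataError("dead gradients: Grad-CAM attributions are zero everywhere")
    mat = np.stack(per_specimen, axis=0)
    mean = mat.mean(axis=0)
    importance = mean / mean.sum()
    sd = mat.std(axis=0)
    return SliceImportance(importance=importance, sd=sd, n_specimens=len(sids),
                           provenance={"specimen_ids": sids,
                                       "mode": model.config.aggregation_mode})


def attention_heatmap(bag: SpecimenBag, scores: AttentionScores,
                      downscale: int = 4, colormap: str = "inferno",
                      provenance: dict | None = None) -> HeatmapOverlay:
    """Min-max normalized attention painted over tile footprints.

    Intensity_i = (w_i - min w) / (max w - min w); if all weights are equal
    every tile gets 0.5.  The base thumbnail shows each tile's best-focus
    slice at its slide origin, downscaled by ``downscale``.
    """
    w = scores.weights
    if len(w) != len(bag.tiles):
        raise ValidationError("scores must align one-to-one with bag tiles")
    span = w.max() - w.min()
    if span <= 0:
        tile_int = np.full(len(w), 0.5)
    else:
        tile_int = (w - w.min()) / span

    from .preprocess import select_best_focus
    tile_size = bag.tiles[0].pixels.shape[0]
    max_x = max(t.origin_xy[0] for t in bag.tiles) + tile_size
    max_y = max(t.origin_xy[1] for t in bag.tiles) + tile_size
    ds = max(1, int(downscale))
    ts = max(1, tile_size // ds)
    h, w_out = (max_y // tile_size) * ts, (max_x // tile_size) * ts
    base = np.full((h, w_out, 3), 255, dtype=np.uint8)
    intensity = np.zeros((h, w_out))
    for tile, ti in zip(bag.tiles, tile_int):
        z = select_best_focus(tile)
        img = tile.pixels[::ds, ::ds, :, z][:ts, :ts]
        ox, oy = tile.origin_xy[0] // tile_size * ts, tile.origin_xy[1] // tile_size * ts
        base[oy:oy + ts, ox:ox + ts] = img
        intensity[oy:oy + ts, ox:ox + ts] = ti
    prov = dict(provenance or {})
    prov.setdefault("specimen_id", bag.specimen_id)
    prov.setdefault("weights_hash", content_hash(w))
    return HeatmapOverlay(base=base, intensity=intensity, tile_intensities=tile_int,
                          colormap=colormap, provenance=prov)


def embed_2d(features: np.ndarray, labels: Sequence[int] | np.ndarray,
             seed: int = 0) -> tuple[np.ndarray, float]:
    """2D stochastic-neighbor embedding of feature vectors plus the silhouette
    score of the label clusters in the embedded space.  Deterministic for a
    fixed seed."""
    from sklearn.manifold import TSNE
    from sklearn.metrics import silhouette_score

    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] < 10:
        raise ValidationError("need an (M, D) matrix with M >= 10")
    perplexity = min(30.0, (x.shape[0] - 1) / 3.0)
    coords = TSNE(n_components=2, random_state=int(seed), init="pca",
                  perplexity=perplexity).fit_transform(x)
    sil = float(silhouette_score(coords, y)) if len(np.unique(y)) > 1 else float("nan")
    return np.asarray(coords, dtype=np.float64), sil
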