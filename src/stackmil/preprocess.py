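"""Stack registration, ROI-confined tiling, best-focus selection, label summaries.

Registration corrects the per-slice jitter a stage introduces between focal
planes: translation is initialized by phase correlation and refined jointly
with rotation by direct intensity optimization against the reference slice.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from shapely.geometry import Point, Polygon
from skimage.registration import phase_cross_correlation

from .errors import RegistrationError, ValidationError
from .simulate import MARKERS, ZStackTile, _affine_slice

__all__ = [
    "RoiAnnotation", "AffineTransform", "register_stack", "tile_region",
    "select_best_focus", "sharpness", "summarize_labels",
]


@dataclass
class RoiAnnotation:
    """Pathologist-style region annotation: closed polygons in slide pixel
    coordinates (0-based, x right, y down)."""

    specimen_id: str
    polygons: list[Polygon]

    def __post_init__(self):
        polys = []
        for p in self.polygons:
            if not isinstance(p, Polygon):
                p = Polygon(np.asarray(p, dtype=float))
            if len(p.exterior.coords) - 1 < 3:
                raise ValidationError("ROI polygons need at least 3 vertices")
            if p.area <= 0:
                raise ValidationError("ROI polygons must have nonzero area")
            polys.append(p)
        self.polygons = polys

    def contains(self, x: float, y: float) -> bool:
        pt = Point(x, y)
        return any(p.contains(pt) for p in self.polygons)


@dataclass
class AffineTransform:
    """Estimated jitter of one slice relative to the reference: rotation
    ``deg`` about the tile center followed by translation (``tx``, ``ty``)
    in pixels."""

    tx: float = 0.0
    ty: float = 0.0
    deg: float = 0.0

    def matrix(self, center_xy: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
        """2x3 matrix mapping source-slice (x, y, 1) to reference (x, y).

        A feature seen at source position p sits in the reference at
        R(-deg) @ (p - t - c) + c: undo the translation, then the rotation
        about the tile center c.  The linear part is a rotation, hence always
        invertible.
        """
        th = np.deg2rad(self.deg)
        c, s = np.cos(th), np.sin(th)
        rot_inv = np.array([[c, s], [-s, c]])  # R(-deg) in (x, y), y down
        cvec = np.asarray(center_xy, dtype=float)
        offset = rot_inv @ (-np.array([self.tx, self.ty]) - cvec) + cvec
        return np.hstack([rot_inv, offset[:, None]])

    def is_identity(self, tol_px: float = 1e-9, tol_deg: float = 1e-9) -> bool:
        return abs(self.tx) <= tol_px and abs(self.ty) <= tol_px and abs(self.deg) <= tol_deg


def _gray(img: np.ndarray) -> np.ndarray:
    return np.asarray(img, dtype=np.float64).mean(axis=2)


def _warp_gray(img: np.ndarray, tx: float, ty: float, deg: float, order: int) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    rot = np.array([[c, -s], [s, c]])  # (y, x) convention
    center = (np.array(img.shape) - 1) / 2.0
    offset = center - rot @ center - np.array([ty, tx])
    return ndimage.affine_transform(img, rot, offset=offset, order=order, mode="reflect")


def _estimate_slice(moving: np.ndarray, ref: np.ndarray) -> tuple[float, float, float]:
    """Correction parameters (tx, ty, deg) such that warping ``moving`` by
    them matches ``ref``; phase-correlation translation init, Powell refine."""
    shift, _, _ = phase_cross_correlation(ref, moving, upsample_factor=20,
                                          normalization=None)
    m = max(2, int(0.12 * min(ref.shape)))
    crop = (slice(m, ref.shape[0] - m), slice(m, ref.shape[1] - m))
    ref_c = ref[crop]

    def loss(p):
        w = _warp_gray(moving, p[0], p[1], p[2], order=1)
        return float(((w[crop] - ref_c) ** 2).mean())

    inits = [np.array([shift[1], shift[0], 0.0]),
             np.array([-shift[1], -shift[0], 0.0])]
    best = min(inits, key=loss)
    res = optimize.minimize(loss, best, method="Powell",
                            options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 200})
    tx, ty, deg = map(float, res.x)
    return tx, ty, deg


def register_stack(stack: ZStackTile, reference_index: int | None = None
                   ) -> tuple[ZStackTile, list[AffineTransform]]:
    """Register every slice to the reference slice by an estimated affine.

    The returned transforms report each slice's estimated jitter relative to
    the reference (identity for the reference slice itself).  By default the
    reference is the best-focus slice, which avoids registering against a
    degenerate blurry plane.
    """
    n_z = stack.n_slices
    if reference_index is None:
        reference_index = select_best_focus(stack)
    if not (0 <= reference_index < n_z):
        raise RegistrationError(f"reference_index {reference_index} out of range")
    grays = [_gray(stack.pixels[:, :, :, z]) for z in range(n_z)]
    for z, g in enumerate(grays):
        if g.std() < 1e-9:
            raise RegistrationError(f"slice {z} is constant; cannot register")
    ref = grays[reference_index]
    aligned = stack.pixels.copy()
    transforms: list[AffineTransform] = []
    for z in range(n_z):
        if z == reference_index:
            transforms.append(AffineTransform(0.0, 0.0, 0.0))
            continue
        ctx, cty, cdeg = _estimate_slice(grays[z], ref)
        # jitter = inverse of the correction: rotate-then-translate params
        th = np.deg2rad(-cdeg)
        c, s = np.cos(th), np.sin(th)
        jt = -(np.array([[c, -s], [s, c]]) @ np.array([ctx, cty]))
        transforms.append(AffineTransform(float(jt[0]), float(jt[1]), -cdeg))
        aligned[:, :, :, z] = _affine_slice(stack.pixels[:, :, :, z], ctx, cty, cdeg)
    out = ZStackTile(pixels=aligned, origin_xy=stack.origin_xy,
                     specimen_id=stack.specimen_id, pixel_size=stack.pixel_size)
    return out, transforms


def tile_region(slide: np.ndarray, roi: RoiAnnotation, tile_size: int
                ) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """Non-overlapping grid tiling confined to the ROI.

    The grid is anchored at slide origin (0, 0); a cell is emitted iff its
    center point falls inside any ROI polygon.  Returns (tile, (origin_x,
    origin_y)) pairs with 0-based origins; an ROI covering no cell center
    yields an empty list.
    """
    if tile_size < 1:
        raise ValidationError("tile_size must be >= 1")
    slide = np.asarray(slide)
    h, w = slide.shape[:2]
    out = []
    for oy in range(0, h - tile_size + 1, tile_size):
        for ox in range(0, w - tile_size + 1, tile_size):
            cx, cy = ox + tile_size / 2.0, oy + tile_size / 2.0
            if roi.contains(cx, cy):
                out.append((slide[oy:oy + tile_size, ox:ox + tile_size, ...],
                            (ox, oy)))
    return out


def sharpness(image_rgb: np.ndarray) -> float:
    """Variance of the Laplacian of the grayscale image (focus measure)."""
    return float(ndimage.laplace(_gray(image_rgb)).var())


def select_best_focus(stack: ZStackTile | np.ndarray) -> int:
    """Index of the sharpest slice (variance of Laplacian; ties -> lowest)."""
    pixels = stack.pixels if isinstance(stack, ZStackTile) else np.asarray(stack)
    scores = [sharpness(pixels[:, :, :, z]) for z in range(pixels.shape[3])]
    return int(np.argmax(scores))


def _percent_half_up(n_positive: int, n_total: int) -> float:
    pct = Decimal(100 * int(n_positive)) / Decimal(int(n_total))
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_labels(label_table: pd.DataFrame,
                     markers: Sequence[str] = MARKERS) -> dict[str, dict]:
    """Per-marker positive counts and percentages (half-up, 1 decimal).

    Rows with missing or non-binary labels raise a validation error listing
    the offending row indices; the summary is invariant to row order.
    """
    df = pd.DataFrame(label_table)
    summary: dict[str, dict] = {}
    for marker in markers:
        if marker not in df.columns:
            raise ValidationError(f"label table lacks column {marker!r}")
        col = df[marker]
        numeric = pd.to_numeric(col, errors="coerce")
        bad = df.index[~numeric.isin([0, 1])].tolist()
        if bad:
            raise ValidationError(
                f"non-binary or missing {marker} labels in rows {bad}")
        n_total = int(len(numeric))
        n_positive = int((numeric == 1).sum())
        summary[marker] = {
            "n_total": n_total,
            "n_positive": n_positive,
            "percent_positive": _percent_half_up(n_positive, n_total),
        }
    return summary
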