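"""On-disk formats: multi-page TIFF stacks, PNG masks, CSV tables/manifests,
GeoJSON ROIs, JSON transform ground truth and reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from shapely.geometry import Polygon, mapping, shape

from .errors import ValidationError
from .preprocess import RoiAnnotation
from .simulate import MARKERS, SpecimenBag, ZStackTile

__all__ = [
    "write_tile_tiff", "read_tile_tiff", "write_mask_png", "read_mask_png",
    "write_label_table", "read_label_table", "write_roi_geojson",
    "read_roi_geojson", "write_cohort", "read_cohort", "write_json", "read_json",
]


def write_tile_tiff(tile: ZStackTile, path: str | Path) -> Path:
    """Multi-page TIFF, page k = focal plane k in ascending depth."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pages = np.moveaxis(tile.pixels, 3, 0)  # (Z, H, W, 3)
    tifffile.imwrite(path, pages, photometric="rgb",
                     metadata={"specimen_id": tile.specimen_id,
                               "origin_x": int(tile.origin_xy[0]),
                               "origin_y": int(tile.origin_xy[1]),
                               "pixel_size_um": tile.pixel_size})
    return path


def read_tile_tiff(path: str | Path, specimen_id: str | None = None,
                   origin_xy: tuple[int, int] | None = None) -> ZStackTile:
    with tifffile.TiffFile(str(path)) as tf:
        pages = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if pages.ndim == 3:  # single page
        pages = pages[None]
    pixels = np.moveaxis(pages, 0, 3)
    sid = specimen_id or str(meta.get("specimen_id", "unknown"))
    if origin_xy is None:
        origin_xy = (int(meta.get("origin_x", 0)), int(meta.get("origin_y", 0)))
    return ZStackTile(pixels=pixels.astype(np.uint8), origin_xy=origin_xy,
                      specimen_id=sid,
                      pixel_size=float(meta.get("pixel_size_um", 0.25)))


def write_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)
    return path


def read_mask_png(path: str | Path) -> np.ndarray:
    return (np.asarray(Image.open(path)) > 0).astype(np.uint8)


def write_label_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["specimen_id", *MARKERS]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValidationError(f"label table missing columns {missing}")
    table[cols].to_csv(path, index=False)
    return path


def read_label_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "specimen_id" not in df.columns:
        raise ValidationError("label table lacks specimen_id column")
    return df


def write_roi_geojson(rois: list[RoiAnnotation], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features = []
    for roi in rois:
        for poly in roi.polygons:
            features.append({
                "type": "Feature",
                "properties": {"specimen_id": roi.specimen_id},
                "geometry": mapping(poly),
            })
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def read_roi_geojson(path: str | Path) -> list[RoiAnnotation]:
    doc = json.loads(Path(path).read_text())
    by_specimen: dict[str, list[Polygon]] = {}
    for feat in doc.get("features", []):
        sid = str(feat.get("properties", {}).get("specimen_id", "unknown"))
        geom = shape(feat["geometry"])
        polys = list(geom.geoms) if geom.geom_type == "MultiPolygon" else [geom]
        by_specimen.setdefault(sid, []).extend(polys)
    return [RoiAnnotation(specimen_id=sid, polygons=polys)
            for sid, polys in sorted(by_specimen.items())]


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_cohort(bags: list[SpecimenBag], table: pd.DataFrame, out_dir: str | Path,
                 transforms: dict[str, list[list[dict]]] | None = None) -> Path:
    """Persist a cohort: per-tile multi-page TIFFs, nucleus masks as PNG, the
    label table as CSV, a tile manifest CSV and (optionally) the misalignment
    ground truth as JSON."""
    out = Path(out_dir)
    (out / "tiles").mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for bag in bags:
        for i, tile in enumerate(bag.tiles):
            tid = f"{bag.specimen_id}_t{i:03d}"
            rel = f"tiles/{tid}.tiff"
            write_tile_tiff(tile, out / rel)
            if bag.ground_truth_masks is not None:
                write_mask_png(bag.ground_truth_masks[i], out / "masks" / f"{tid}.png")
            manifest_rows.append({"specimen_id": bag.specimen_id, "tile_id": tid,
                                  "origin_x": tile.origin_xy[0],
                                  "origin_y": tile.origin_xy[1], "path": rel})
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    write_label_table(table, out / "labels.csv")
    if transforms is not None:
        write_json(transforms, out / "transforms.json")
    return out


def read_cohort(cohort_dir: str | Path) -> tuple[list[SpecimenBag], pd.DataFrame]:
    root = Path(cohort_dir)
    table = read_label_table(root / "labels.csv")
    manifest = pd.read_csv(root / "manifest.csv")
    labels_by_sid = {
        row["specimen_id"]: {m: int(row[m]) for m in MARKERS}
        for _, row in table.iterrows()
    }
    bags = []
    for sid, group in manifest.groupby("specimen_id", sort=True):
        tiles, masks = [], []
        for _, row in group.sort_values("tile_id").iterrows():
            tile = read_tile_tiff(root / row["path"], specimen_id=sid,
                                  origin_xy=(int(row["origin_x"]), int(row["origin_y"])))
            tiles.append(tile)
            mask_path = root / "masks" / (row["tile_id"] + ".png")
            if mask_path.exists():
                masks.append(read_mask_png(mask_path))
        bags.append(SpecimenBag(specimen_id=str(sid), tiles=tiles,
                                labels=labels_by_sid[str(sid)],
                                ground_truth_masks=masks or None))
    return bags, table
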