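"""File formats: PNG/TIFF rasters, label-mask PNGs, expression TSV, GMT,
and JSON sidecars for ROI boxes and patch grids."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .pipeline import PatchGrid, RoiBox, Tile

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "write_roi_json",
    "read_roi_json",
    "write_grid_json",
    "read_grid_json",
]


def read_image(path) -> np.ndarray:
    """Read an RGB raster (PNG or TIFF; pyramidal TIFF: first page)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr[..., :3].astype(np.uint8)


def write_image(arr: np.ndarray, path) -> None:
    path = Path(path)
    arr = np.asarray(arr, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def read_mask(path) -> np.ndarray:
    """Single-channel label mask PNG with codes 0/1/2."""
    return np.asarray(Image.open(path).convert("L"), dtype=np.uint8)


def write_mask(mask: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="L").save(path)


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    """Genes x samples TSV: first column the gene ID, header sample IDs."""
    expr.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gmt(collection: dict[str, tuple[str, tuple[str, ...]]], path) -> None:
    """Standard GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
    with open(path, "w") as fh:
        for term, (desc, genes) in collection.items():
            fh.write("\t".join([term, desc, *genes]) + "\n")


def read_gmt(path) -> dict[str, tuple[str, tuple[str, ...]]]:
    out: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            out[parts[0]] = (parts[1], tuple(g for g in parts[2:] if g))
    return out


def write_roi_json(roi: RoiBox, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(roi), indent=2))


def read_roi_json(path) -> RoiBox:
    return RoiBox(**json.loads(Path(path).read_text()))


def write_grid_json(grid: PatchGrid, path) -> None:
    d = {
        "patch_w": grid.patch_w,
        "patch_h": grid.patch_h,
        "roi_height": grid.roi_height,
        "roi_width": grid.roi_width,
        "tiles": [dataclasses.asdict(t) for t in grid.tiles],
    }
    Path(path).write_text(json.dumps(d, indent=2))


def read_grid_json(path) -> PatchGrid:
    d = json.loads(Path(path).read_text())
    return PatchGrid(
        patch_w=d["patch_w"],
        patch_h=d["patch_h"],
        roi_height=d["roi_height"],
        roi_width=d["roi_width"],
        tiles=tuple(Tile(**t) for t in d["tiles"]),
    )
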