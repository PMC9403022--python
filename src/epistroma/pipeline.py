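"""Whole-slide processing: foreground detection, ROI extraction, tiling, stitching.

The stages mirror how a pathologist approaches a slide: work on a x16
thumbnail, find the stained tissue by clustering chroma, crop the smallest
rectangle around the largest tissue component, then sweep the crop with
fixed-size patches for the segmentation model and reassemble the patch
predictions into a global tissue mask.

Conventions: coordinates are row-major, 0-based, half-open everywhere.
Patch size is width x height (default 1128 x 720).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2lab
from sklearn.cluster import KMeans

__all__ = [
    "Slide",
    "RoiBox",
    "Tile",
    "PatchGrid",
    "PipelineConfig",
    "ProcessResult",
    "GroundTruthSegmenter",
    "downsample_slide",
    "rgb_to_ab",
    "cluster_foreground",
    "roi_from_mask",
    "upsample_mask",
    "tile_roi",
    "stitch_predictions",
    "process_slide",
]


@dataclass
class Slide:
    """An RGB raster with 8-bit colour semantics (uint8 or float in [0,255])
    plus the downsample factor relative to the original scan."""

    pixels: np.ndarray
    downsample: int = 1

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] < 1 or p.shape[1] < 1:
            raise ValueError("slide must be an H x W x 3 raster")
        self.pixels = p

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class RoiBox:
    """Full-resolution bounding box, half-open on both axes."""

    row_start: int
    col_start: int
    row_end: int
    col_end: int

    def __post_init__(self):
        if self.row_start >= self.row_end or self.col_start >= self.col_end:
            raise ValueError("RoiBox intervals must be non-empty")

    @property
    def height(self) -> int:
        return self.row_end - self.row_start

    @property
    def width(self) -> int:
        return self.col_end - self.col_start

    def iou(self, other: "RoiBox") -> float:
        ri = max(0, min(self.row_end, other.row_end) - max(self.row_start, other.row_start))
        ci = max(0, min(self.col_end, other.col_end) - max(self.col_start, other.col_start))
        inter = ri * ci
        union = self.height * self.width + other.height * other.width - inter
        return inter / union if union else 0.0


@dataclass(frozen=True)
class Tile:
    """One grid cell, with offsets relative to the ROI top-left corner."""

    row: int
    col: int
    bg_fraction: float
    retained: bool


@dataclass(frozen=True)
class PatchGrid:
    patch_w: int
    patch_h: int
    roi_height: int
    roi_width: int
    tiles: tuple[Tile, ...]

    @property
    def retained(self) -> tuple[Tile, ...]:
        return tuple(t for t in self.tiles if t.retained)


def downsample_slide(slide: Slide, factor: int) -> Slide:
    """Block-mean downsampling with ceil output dimensions; edge blocks
    average over their (partial) source pixels only."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return Slide(slide.pixels.copy(), downsample=slide.downsample)
    px = slide.pixels.astype(np.float64)
    h, w = px.shape[:2]
    r_idx = np.arange(0, h, factor)
    c_idx = np.arange(0, w, factor)
    sums = np.add.reduceat(np.add.reduceat(px, r_idx, axis=0), c_idx, axis=1)
    rc = np.minimum(r_idx + factor, h) - r_idx
    cc = np.minimum(c_idx + factor, w) - c_idx
    counts = rc[:, None] * cc[None, :]
    out = sums / counts[:, :, None]
    return Slide(out, downsample=slide.downsample * factor)


def rgb_to_ab(slide: Slide) -> np.ndarray:
    """CIELAB (sRGB/D65) chroma channels; the lightness channel L* carries
    only brightness and is discarded."""
    px = np.asarray(slide.pixels, dtype=np.float64) / 255.0
    lab = rgb2lab(np.clip(px, 0.0, 1.0))
    ab = lab[..., 1:3]
    if not np.all(np.isfinite(ab)):
        raise ValueError("non-finite chroma values")
    return ab


def cluster_foreground(ab: np.ndarray, seed: int = 0) -> np.ndarray:
    """Two-way K-means on (a*, b*); the cluster of the upper-left pixel is
    labelled background (0).  Corner tissue therefore mislabels the slide —
    a documented failure mode of the unstained-corner assumption."""
    ab = np.asarray(ab, dtype=np.float64)
    if ab.ndim != 3 or ab.shape[2] != 2:
        raise ValueError("expected an H x W x 2 chroma image")
    flat = ab.reshape(-1, 2)
    if np.unique(flat, axis=0).shape[0] < 2:
        warnings.warn("degenerate chroma image: all pixels identical; returning all-background")
        return np.zeros(ab.shape[:2], dtype=np.uint8)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(flat).reshape(ab.shape[:2])
    bg = labels[0, 0]
    return (labels != bg).astype(np.uint8)


def roi_from_mask(mask: np.ndarray, factor: int, slide_dims: tuple[int, int]) -> RoiBox:
    """Bounding box of the largest 8-connected foreground component, mapped
    to full resolution (offsets x factor, clamped to the slide bounds).
    Ties on component size break by first appearance in row-major scan."""
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("empty foreground: no ROI")
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    sizes = np.bincount(labeled.ravel())
    sizes[0] = 0
    max_size = sizes.max()
    candidates = set(np.flatnonzero(sizes == max_size).tolist())
    flat = labeled.ravel()
    pick = next(int(lab) for lab in flat if lab in candidates)
    rows, cols = np.nonzero(labeled == pick)
    H, W = slide_dims
    return RoiBox(
        row_start=min(int(rows.min()) * factor, H - 1),
        col_start=min(int(cols.min()) * factor, W - 1),
        row_end=min((int(rows.max()) + 1) * factor, H),
        col_end=min((int(cols.max()) + 1) * factor, W),
    )


def upsample_mask(mask: np.ndarray, factor: int, slide_dims: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour upsampling of a low-resolution mask to full
    resolution, cropped to the slide bounds."""
    big = np.repeat(np.repeat(mask, factor, axis=0), factor, axis=1)
    return big[: slide_dims[0], : slide_dims[1]]


def tile_roi(
    roi: RoiBox,
    foreground_full: np.ndarray,
    patch_w: int = 1128,
    patch_h: int = 720,
    bg_threshold: float = 0.8,
) -> PatchGrid:
    """Non-overlapping grid anchored at the ROI top-left corner.

    Edge tiles are conceptually padded with background to the full patch
    size; each tile's background fraction is background pixels over
    ``patch_w * patch_h``.  A tile is retained iff its background fraction is
    at most ``bg_threshold`` (strictly more is discarded, so a tile at
    exactly the threshold survives).
    """
    if patch_w < 1 or patch_h < 1:
        raise ValueError("patch dimensions must be >= 1")
    fg = np.asarray(foreground_full)
    tiles = []
    for r in range(0, roi.height, patch_h):
        for c in range(0, roi.width, patch_w):
            r_abs, c_abs = roi.row_start + r, roi.col_start + c
            r_hi = min(r_abs + patch_h, roi.row_end)
            c_hi = min(c_abs + patch_w, roi.col_end)
            fg_count = int(np.count_nonzero(fg[r_abs:r_hi, c_abs:c_hi]))
            bg_fraction = 1.0 - fg_count / (patch_w * patch_h)
            tiles.append(Tile(row=r, col=c, bg_fraction=bg_fraction, retained=bg_fraction <= bg_threshold))
    return PatchGrid(patch_w=patch_w, patch_h=patch_h, roi_height=roi.height, roi_width=roi.width, tiles=tuple(tiles))


def stitch_predictions(grid: PatchGrid, patch_masks: list[np.ndarray]) -> np.ndarray:
    """Reassemble per-patch label masks into the global ROI tissue mask.

    ``patch_masks`` holds one ``patch_h x patch_w`` mask per retained tile in
    grid order; discarded-tile footprints stay background (0)."""
    retained = grid.retained
    if len(patch_masks) != len(retained):
        raise ValueError(f"expected {len(retained)} patch masks, got {len(patch_masks)}")
    out = np.zeros((grid.roi_height, grid.roi_width), dtype=np.uint8)
    for tile, pm in zip(retained, patch_masks):
        pm = np.asarray(pm)
        if pm.shape != (grid.patch_h, grid.patch_w):
            raise ValueError("patch mask shape mismatch")
        r_hi = min(tile.row + grid.patch_h, grid.roi_height)
        c_hi = min(tile.col + grid.patch_w, grid.roi_width)
        out[tile.row : r_hi, tile.col : c_hi] = pm[: r_hi - tile.row, : c_hi - tile.col]
    return out


@dataclass(frozen=True)
class PipelineConfig:
    downsample: int = 16
    patch_w: int = 1128
    patch_h: int = 720
    bg_threshold: float = 0.8
    pad_value: int = 255  # edge tiles padded with white background
    seed: int = 0


@dataclass
class ProcessResult:
    """All intermediates of one slide run, for audit."""

    roi: RoiBox
    grid: PatchGrid
    tissue_mask: np.ndarray        # ROI-shaped labels 0/1/2 (the global mask)
    foreground_mask: np.ndarray    # low-resolution binary mask
    foreground_full: np.ndarray    # full-resolution binary mask
    thumbnail: Slide


class GroundTruthSegmenter:
    """Oracle 'model' that returns crops of a known label mask; used to test
    the pipeline independently of the network."""

    def __init__(self, truth_mask: np.ndarray):
        self.truth = np.asarray(truth_mask)

    def predict_patch(self, patch: np.ndarray, *, origin: tuple[int, int] | None = None) -> np.ndarray:
        if origin is None:
            raise ValueError("ground-truth segmenter needs the patch origin")
        r0, c0 = origin
        h, w = patch.shape[:2]
        out = np.zeros((h, w), dtype=np.uint8)
        r_hi = min(r0 + h, self.truth.shape[0])
        c_hi = min(c0 + w, self.truth.shape[1])
        if r_hi > r0 and c_hi > c0:
            out[: r_hi - r0, : c_hi - c0] = self.truth[r0:r_hi, c0:c_hi]
        return out


def _extract_patch(pixels: np.ndarray, r0: int, c0: int, h: int, w: int, pad_value: int) -> np.ndarray:
    out = np.full((h, w, 3), pad_value, dtype=pixels.dtype)
    r_hi, c_hi = min(r0 + h, pixels.shape[0]), min(c0 + w, pixels.shape[1])
    out[: r_hi - r0, : c_hi - c0] = pixels[r0:r_hi, c0:c_hi]
    return out


def process_slide(slide: Slide, model, config: PipelineConfig = PipelineConfig()) -> ProcessResult:
    """Run the full slide workflow: thumbnail -> chroma clustering -> ROI ->
    tiling -> per-patch prediction -> stitched global tissue mask.

    ``model`` must expose ``predict_patch(rgb_patch) -> label mask``; the
    optional keyword ``origin`` is passed when accepted (used by the
    ground-truth oracle).
    """
    thumb = downsample_slide(slide, config.downsample)
    ab = rgb_to_ab(thumb)
    m1 = cluster_foreground(ab, seed=config.seed)
    roi = roi_from_mask(m1, config.downsample, slide.shape)
    fg_full = upsample_mask(m1, config.downsample, slide.shape)
    grid = tile_roi(roi, fg_full, config.patch_w, config.patch_h, config.bg_threshold)

    preds = []
    for tile in grid.retained:
        r0, c0 = roi.row_start + tile.row, roi.col_start + tile.col
        patch = _extract_patch(slide.pixels, r0, c0, config.patch_h, config.patch_w, config.pad_value)
        try:
            pm = model.predict_patch(patch, origin=(r0, c0))
        except TypeError:
            pm = model.predict_patch(patch)
        preds.append(pm)
    m2 = stitch_predictions(grid, preds)
    return ProcessResult(roi=roi, grid=grid, tissue_mask=m2, foreground_mask=m1, foreground_full=fg_full, thumbnail=thumb)
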