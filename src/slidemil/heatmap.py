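"""Attention-derived tumour-localization heatmaps and tile galleries.

Raw (pre-softmax) attention scores are rescaled per slide to a bounded
p_att in [0, 1] by min-max normalization (softmax weights depend on bag
size, so they are not comparable across slides; the rank order of p_att
and of the softmax weights is identical). Tiles are scored on an
overlapping grid, each tile's p_att is painted over its footprint,
overlapping contributions are averaged, and the mean map is smoothed with
a Gaussian filter to remove the blocky appearance. Tiles with p_att above
0.6 form the tumour-suspect gallery; below 0.4, the normal gallery.

Against synthetic ground-truth masks, localization is scored by the IoU of
the thresholded smoothed map and by the pixelwise AUROC of the map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.metrics import roc_auc_score

from .preprocess import TILE_SIZE, ResolutionLevel, Tile

__all__ = [
    "HeatmapGrid", "GalleryCriteria", "normalize_attention",
    "attention_scan", "tile_gallery", "localization_score",
    "render_heatmap_png",
]


@dataclass
class GalleryCriteria:
    high_threshold: float = 0.6
    low_threshold: float = 0.4

    def __post_init__(self):
        if not self.low_threshold < self.high_threshold:
            raise ValueError("low threshold must be below high threshold")


@dataclass
class HeatmapGrid:
    score_sum: np.ndarray      # painted p_att mass per pixel
    overlap_count: np.ndarray  # tiles covering each pixel
    sigma_px: float

    @property
    def mean_map(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.overlap_count > 0,
                            self.score_sum / np.maximum(self.overlap_count, 1), 0.0)

    @property
    def smoothed_map(self) -> np.ndarray:
        # reflective boundaries keep the global mean essentially unchanged
        return ndimage.gaussian_filter(self.mean_map, sigma=self.sigma_px,
                                       mode="reflect")


def normalize_attention(raw_scores) -> np.ndarray:
    """Min-max rescale one slide's raw attention scores to p_att in [0, 1].

    Constant-score slides (no instance stands out) map to 0.5 everywhere.
    """
    raw = np.asarray(raw_scores, dtype=float)
    if raw.size == 0:
        raise ValueError("need at least one score")
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-12:
        return np.full_like(raw, 0.5)
    return (raw - lo) / (hi - lo)


def _scan_positions(extent: int, stride: int):
    pos = list(range(0, extent - TILE_SIZE + 1, stride))
    if pos and pos[-1] != extent - TILE_SIZE:
        pos.append(extent - TILE_SIZE)  # flush to the far edge
    return pos


def attention_scan(slide_image: np.ndarray, model, level: ResolutionLevel,
                   stride_px: int = 128, sigma_px: float | None = None,
                   preprocess_tile=None):
    """Score overlapping tiles and paint p_att over their footprints.

    ``preprocess_tile`` maps raw 8-bit tile pixels to the model's input
    (e.g. Macenko normalization + standardization + reduction); identity
    when omitted. Returns (HeatmapGrid, scored tiles, p_att array).
    Heatmap generation is pure inference; model state is untouched.
    """
    if stride_px <= 0:
        raise ValueError("stride must be positive")
    if stride_px > TILE_SIZE:
        warnings.warn("stride larger than the tile size leaves unscored gaps")
    if sigma_px is None:
        sigma_px = stride_px / 2
    h, w = slide_image.shape[:2]
    tiles, inputs = [], []
    for y in _scan_positions(h, stride_px):
        for x in _scan_positions(w, stride_px):
            px = slide_image[y:y + TILE_SIZE, x:x + TILE_SIZE]
            tiles.append(Tile(pixels=px, grid_row=y // stride_px,
                              grid_col=x // stride_px, origin=(x, y), level=level))
            inputs.append(preprocess_tile(px) if preprocess_tile else px)
    raw = model.attention_raw_scores(np.stack(inputs))
    p_att = normalize_attention(raw)

    score_sum = np.zeros((h, w))
    overlap = np.zeros((h, w), dtype=int)
    for tile, p in zip(tiles, p_att):
        x, y = tile.origin
        score_sum[y:y + TILE_SIZE, x:x + TILE_SIZE] += p
        overlap[y:y + TILE_SIZE, x:x + TILE_SIZE] += 1
    grid = HeatmapGrid(score_sum=score_sum, overlap_count=overlap,
                       sigma_px=sigma_px)
    return grid, tiles, p_att


def tile_gallery(tiles, p_att, side: str = "high",
                 criteria: GalleryCriteria = GalleryCriteria()):
    """Tiles passing the strict attention threshold, sorted by p_att.

    side="high": p_att > high_threshold, most suspicious first.
    side="low": p_att < low_threshold, most confidently normal first.
    Returns a list of (Tile, p_att).
    """
    p_att = np.asarray(p_att, dtype=float)
    if side == "high":
        keep = np.flatnonzero(p_att > criteria.high_threshold)
        order = keep[np.argsort(-p_att[keep])]
    elif side == "low":
        keep = np.flatnonzero(p_att < criteria.low_threshold)
        order = keep[np.argsort(p_att[keep])]
    else:
        raise ValueError("side must be 'high' or 'low'")
    return [(tiles[i], float(p_att[i])) for i in order]


def localization_score(grid: HeatmapGrid, tumour_mask: np.ndarray,
                       cut: float = 0.6):
    """IoU of {smoothed map > cut} vs the mask, and pixelwise mask-AUROC."""
    mask = np.asarray(tumour_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty tumour mask; localization is undefined")
    smoothed = grid.smoothed_map
    if smoothed.shape != mask.shape:
        raise ValueError("heatmap and mask shapes differ")
    pred = smoothed > cut
    union = (pred | mask).sum()
    iou = float((pred & mask).sum() / union) if union else 0.0
    flat_mask = mask.ravel()
    if flat_mask.all():
        auroc = float("nan")
    else:
        auroc = float(roc_auc_score(flat_mask, smoothed.ravel()))
    return {"iou": iou, "mask_auroc": auroc}


def render_heatmap_png(grid: HeatmapGrid, out_prefix, cmap: str = "GnBu"):
    """Write the raw mean map (16-bit) and a colour overlay (8-bit) PNG.

    With the default colormap high attention renders dark blue and low
    attention light green.
    """
    import imageio.v3 as iio
    from matplotlib import colormaps

    from pathlib import Path
    out_prefix = Path(out_prefix)
    mean16 = np.clip(grid.mean_map, 0, 1)
    iio.imwrite(out_prefix.with_suffix(".raw.png"),
                (mean16 * 65535).astype(np.uint16))
    rgba = colormaps[cmap](np.clip(grid.smoothed_map, 0, 1))
    iio.imwrite(out_prefix.with_suffix(".overlay.png"),
                (rgba[..., :3] * 255).astype(np.uint8))
    return out_prefix.with_suffix(".raw.png"), out_prefix.with_suffix(".overlay.png")
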