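"""Slide-to-tile preprocessing: resolution levels, tessellation, QC filters,
Macenko stain normalization, augmentation and channel standardization.

Working resolutions are indexed by a level R in {0, 1, 2, 3} mapping to
2 * 2^R microns per pixel from a 0.25 um/px native scan (downsample factor
8 * 2^R). Slides are cut into non-overlapping 256x256 tiles on a regular
grid anchored at (0, 0); partial edge tiles are dropped. A tile is rejected
when more than 75% of its pixels are background (all 8-bit channels above a
brightness cutoff) or when it carries too few Canny edges to be informative
(blur/featureless rejection). A slide is disregarded when fewer than
80 / 2^R valid tiles remain (80, 40, 20, 10 for R = 0..3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import feature, transform

__all__ = [
    "TILE_SIZE", "ResolutionLevel", "Tile", "StainProfile",
    "StandardizationParams", "TileFilterReport", "QCConfig",
    "downsample_to_level", "tessellate", "background_fraction",
    "is_informative", "filter_slide", "min_tile_threshold",
    "macenko_fit", "macenko_normalize", "augment", "standardize",
    "unstandardize", "DEFAULT_STANDARDIZATION",
]

TILE_SIZE = 256
NATIVE_MPP = 0.25


@dataclass(frozen=True)
class ResolutionLevel:
    R: int

    def __post_init__(self):
        if self.R not in (0, 1, 2, 3):
            raise ValueError("resolution level R must be in {0, 1, 2, 3}")

    @property
    def microns_per_pixel(self) -> float:
        return 2.0 * 2**self.R

    @property
    def downsample_factor(self) -> float:
        return self.microns_per_pixel / NATIVE_MPP  # 8 * 2^R


def min_tile_threshold(level: ResolutionLevel) -> int:
    """Minimum valid tiles for a slide to be kept: 80 / 2^R."""
    return 80 // 2**level.R


@dataclass
class Tile:
    pixels: np.ndarray          # (256, 256, 3)
    grid_row: int
    grid_col: int
    origin: tuple               # (x, y) top-left, level coordinates
    level: ResolutionLevel


@dataclass
class StainProfile:
    """Macenko reference: unit-norm OD stain vectors + concentration scales."""

    stain_matrix: np.ndarray       # (3, 2): columns hematoxylin, eosin
    max_concentrations: np.ndarray  # (2,) 99th-percentile scales
    level: ResolutionLevel

    def to_json(self, path: str | Path):
        Path(path).write_text(json.dumps({
            "stain_matrix": self.stain_matrix.tolist(),
            "max_concentrations": self.max_concentrations.tolist(),
            "level": self.level.R,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StainProfile":
        d = json.loads(Path(path).read_text())
        return cls(stain_matrix=np.array(d["stain_matrix"]),
                   max_concentrations=np.array(d["max_concentrations"]),
                   level=ResolutionLevel(d["level"]))


@dataclass
class StandardizationParams:
    channel_means: tuple
    channel_stds: tuple

    def __post_init__(self):
        if min(self.channel_stds) <= 0:
            raise ValueError("channel stds must be strictly positive")


# Training-cohort channel statistics on the unit-interval scale.
DEFAULT_STANDARDIZATION = StandardizationParams(
    channel_means=(0.8566, 0.7857, 0.8633),
    channel_stds=(0.1485, 0.1874, 0.1421),
)


@dataclass
class QCConfig:
    background_channel_cutoff: int = 220   # pixel is background iff all ch >
    background_max_fraction: float = 0.75  # reject iff fraction strictly above
    canny_low: float = 40 / 255
    canny_high: float = 100 / 255
    canny_sigma: float = 1.0
    min_edge_fraction: float = 0.02


@dataclass
class TileFilterReport:
    n_grid: int
    n_background_rejected: int
    n_defect_rejected: int
    n_valid: int
    slide_accepted: bool


# --------------------------------------------------------------------------
# resolution handling
# --------------------------------------------------------------------------

def downsample_to_level(image: np.ndarray, source_mpp: float,
                        target: ResolutionLevel) -> np.ndarray:
    """Area-averaged reduction from source_mpp to the target level.

    Integer factors use an exact box filter; non-integer factors fall back
    to anti-aliased resampling. Output dimensions are floor(input/factor).
    Upsampling requests are rejected.
    """
    factor = target.microns_per_pixel / source_mpp
    if factor < 1.0 - 1e-9:
        raise ValueError("target level is finer than the source image")
    if abs(factor - 1.0) < 1e-9:
        return image.copy()
    h, w = image.shape[:2]
    out_h, out_w = int(h // factor), int(w // factor)
    if np.isclose(factor, round(factor)):
        f = int(round(factor))
        x = image[: out_h * f, : out_w * f].astype(float)
        if x.ndim == 3:
            x = x.reshape(out_h, f, out_w, f, -1).mean(axis=(1, 3))
        else:
            x = x.reshape(out_h, f, out_w, f).mean(axis=(1, 3))
    else:
        x = transform.resize(image.astype(float), (out_h, out_w),
                             anti_aliasing=True, preserve_range=True)
    if image.dtype == np.uint8:
        return np.clip(np.round(x), 0, 255).astype(np.uint8)
    return x


def tessellate(image: np.ndarray, level: ResolutionLevel) -> list:
    """Cut a level image into non-overlapping 256x256 tiles, row-major.

    Edge remainders smaller than one tile are dropped. An image smaller
    than one tile yields an empty list.
    """
    h, w = image.shape[:2]
    tiles = []
    for gr in range(h // TILE_SIZE):
        for gc in range(w // TILE_SIZE):
            y, x = gr * TILE_SIZE, gc * TILE_SIZE
            tiles.append(Tile(
                pixels=image[y:y + TILE_SIZE, x:x + TILE_SIZE],
                grid_row=gr, grid_col=gc, origin=(x, y), level=level,
            ))
    return tiles


# --------------------------------------------------------------------------
# QC filters
# --------------------------------------------------------------------------

def background_fraction(tile_pixels: np.ndarray,
                        config: QCConfig = QCConfig()) -> float:
    """Fraction of pixels that are bright background (all channels > cutoff)."""
    px = np.asarray(tile_pixels)
    bg = (px > config.background_channel_cutoff).all(axis=-1)
    return float(bg.mean())


def is_informative(tile_pixels: np.ndarray,
                   config: QCConfig = QCConfig()) -> bool:
    """True iff the Canny edge-pixel fraction reaches the configured minimum.

    Blurred or featureless tiles produce almost no edges and fail.
    """
    px = np.asarray(tile_pixels).astype(float) / 255.0
    gray = px @ np.array([0.2125, 0.7154, 0.0721])
    edges = feature.canny(gray, sigma=config.canny_sigma,
                          low_threshold=config.canny_low,
                          high_threshold=config.canny_high)
    return float(edges.mean()) >= config.min_edge_fraction


def filter_slide(tiles: list, level: ResolutionLevel,
                 config: QCConfig = QCConfig(),
                 min_valid: int | None = None):
    """Apply background then informativeness filters; gate the slide.

    Returns (valid tiles, TileFilterReport). The slide is accepted when
    n_valid >= min_valid (default 80 / 2^R). Rejection is a reported state,
    not an error.
    """
    threshold = min_tile_threshold(level) if min_valid is None else min_valid
    valid, n_bg, n_defect = [], 0, 0
    for tile in tiles:
        if background_fraction(tile.pixels, config) > config.background_max_fraction:
            n_bg += 1
        elif not is_informative(tile.pixels, config):
            n_defect += 1
        else:
            valid.append(tile)
    report = TileFilterReport(
        n_grid=len(tiles), n_background_rejected=n_bg,
        n_defect_rejected=n_defect, n_valid=len(valid),
        slide_accepted=len(valid) >= threshold,
    )
    return valid, report


# --------------------------------------------------------------------------
# Macenko stain normalization
# --------------------------------------------------------------------------

_OD_EPS = 1.0


def _optical_density(rgb: np.ndarray) -> np.ndarray:
    """OD = -ln((I + 1) / 256) per channel, flattened to (n_pixels, 3).

    Natural-log OD, matching the customary transparency threshold
    beta = 0.15 of the stain-estimation method.
    """
    arr = np.asarray(rgb, dtype=float).reshape(-1, 3)
    return -np.log((arr + _OD_EPS) / 256.0)


def _od_to_rgb(od: np.ndarray) -> np.ndarray:
    return np.clip(256.0 * np.exp(-od) - _OD_EPS, 0, 255)


def macenko_fit(reference_image: np.ndarray, level: ResolutionLevel,
                beta: float = 0.15, alpha: float = 1.0,
                concentration_percentile: float = 99.0,
                min_pixels: int = 200) -> StainProfile:
    """Estimate the two stain vectors and concentration scales of an image.

    Standard Macenko procedure: transform to optical density, discard
    near-transparent pixels (mean OD < beta), take the plane spanned
    by the top-2 principal components, find the extreme angle directions at
    the alpha / (100 - alpha) percentiles, and record the
    ``concentration_percentile`` per-stain concentration as the reference
    scale. Vectors are unit-norm with non-negative OD components; the first
    column is hematoxylin (larger red-channel OD).
    """
    od = _optical_density(reference_image)
    od_tissue = od[od.mean(axis=1) >= beta]
    if len(od_tissue) < min_pixels:
        raise ValueError(
            f"reference contains too few stained pixels "
            f"({len(od_tissue)} < {min_pixels}); not usable as a stain reference"
        )

    def _fit_central_plane(unit_dirs):
        # stain mixtures span a subspace through the origin, so the plane
        # is the top-2 eigenspace of the *uncentered* second moment
        moment = unit_dirs.T @ unit_dirs / len(unit_dirs)
        _, eigvec = np.linalg.eigh(moment)
        plane = eigvec[:, [2, 1]]
        for i in range(2):                         # orient towards positive OD
            if plane[:, i].sum() < 0:
                plane[:, i] = -plane[:, i]
        return plane

    # The plane is estimated from OD *directions* (unit-normalized pixels):
    # raw-OD statistics weight pixels by squared magnitude, so a fraction
    # of a percent of dark gray artifact pixels (ink dots, marks, darkened
    # folds/edges) can rival the small stain-angle spread and tilt the
    # plane, whereas in direction space the tissue arc dominates and the
    # contaminants are a small minority removed by a one-step residual trim.
    dirs = od_tissue / np.linalg.norm(od_tissue, axis=1, keepdims=True)
    # iterated trim with re-admission: each round refits the plane on the
    # kept pixels and re-scores *all* pixels against it, so pixels wrongly
    # ejected under a contaminated early plane (deeply stained nuclei under
    # a fold-tilted fit) return once the contaminants are gone. The
    # threshold adapts to the residual scale but is capped at ~2 degrees
    # off-plane.
    keep = np.ones(len(dirs), dtype=bool)
    plane = _fit_central_plane(dirs)
    for _ in range(3):
        resid = np.linalg.norm(dirs - (dirs @ plane) @ plane.T, axis=1)
        new_keep = resid <= max(min(4.0 * np.median(resid), 0.04), 1e-6)
        if new_keep.sum() < min_pixels:
            break
        keep = new_keep
        plane = _fit_central_plane(dirs[keep])
    od_fit = od_tissue[keep] if keep.sum() >= min_pixels else od_tissue

    proj = (od_fit / np.linalg.norm(od_fit, axis=1, keepdims=True)) @ plane
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    phi_min, phi_max = np.percentile(phi, (alpha, 100 - alpha))
    v1 = plane @ np.array([np.cos(phi_min), np.sin(phi_min)])
    v2 = plane @ np.array([np.cos(phi_max), np.sin(phi_max)])
    he = np.column_stack([v1, v2] if v1[0] >= v2[0] else [v2, v1])
    he = np.clip(he, 0, None)
    he /= np.linalg.norm(he, axis=0, keepdims=True)
    # Concentration scales from the same in-plane pixels: deeply stained
    # nuclei keep their in-plane direction (dye saturation caps density,
    # not hue) so they stay in the 99th percentile, while gray artifact
    # pixels were trimmed above.
    conc = np.linalg.lstsq(he, od_fit.T, rcond=None)[0]
    max_c = np.percentile(conc, concentration_percentile, axis=1)
    return StainProfile(stain_matrix=he, max_concentrations=np.maximum(max_c, 1e-6),
                        level=level)


def macenko_normalize(tile_pixels: np.ndarray, reference: StainProfile,
                      source: StainProfile | None = None) -> np.ndarray:
    """Map a tile's stains to the reference profile.

    Concentrations are unmixed against the *source* profile (fitted on the
    tile itself when not supplied, e.g. fitted once per slide for speed and
    robustness on background-heavy tiles), rescaled so the source
    concentration scales match the reference ones, and recomposed with the
    reference stain matrix. Output is 8-bit RGB. The tile and profile must
    be at the same resolution level.
    """
    if source is None:
        source = macenko_fit(tile_pixels, reference.level)
    if source.level != reference.level:
        raise ValueError("source and reference profiles are at different levels")
    shape = np.asarray(tile_pixels).shape
    od = _optical_density(tile_pixels)
    conc = np.maximum(np.linalg.lstsq(source.stain_matrix, od.T, rcond=None)[0], 0.0)
    conc *= (reference.max_concentrations / source.max_concentrations)[:, None]
    od_new = (reference.stain_matrix @ conc).T
    rgb = _od_to_rgb(od_new).reshape(shape)
    return np.round(rgb).astype(np.uint8)


def check_level(tile: Tile, profile: StainProfile):
    if tile.level != profile.level:
        raise ValueError("stain profile level does not match tile level")


# --------------------------------------------------------------------------
# augmentation and standardization
# --------------------------------------------------------------------------

def augment(tile_pixels: np.ndarray, seed_or_rng,
            jitter: float = 0.05, geometric: bool = True,
            photometric: bool = True) -> np.ndarray:
    """Random k*90-degree rotation, flips, and small colour jitter.

    Brightness, saturation and contrast are each scaled by an independent
    factor drawn uniformly from [1 - jitter, 1 + jitter] (default +/-5%).
    Training-time only; validation and inference see unaugmented tiles.
    Accepts uint8 or float arrays; the dtype is preserved.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    x = np.asarray(tile_pixels)
    was_uint8 = x.dtype == np.uint8
    x = x.astype(float)
    scale = 255.0 if was_uint8 else 1.0

    if geometric:
        k = int(rng.integers(0, 4))
        x = np.rot90(x, k, axes=(0, 1))
        if rng.random() < 0.5:
            x = x[::-1, :, :]
        if rng.random() < 0.5:
            x = x[:, ::-1, :]
    if photometric:
        f_b, f_s, f_c = rng.uniform(1 - jitter, 1 + jitter, size=3)
        x = x * f_b                                        # brightness
        gray = (x @ np.array([0.2125, 0.7154, 0.0721]))[..., None]
        x = gray + (x - gray) * f_s                        # saturation
        x = x.mean() + (x - x.mean()) * f_c                # contrast
    x = np.clip(x, 0, scale)
    return np.round(x).astype(np.uint8) if was_uint8 else np.ascontiguousarray(x)


def standardize(tile_pixels: np.ndarray,
                params: StandardizationParams = DEFAULT_STANDARDIZATION
                ) -> np.ndarray:
    """8-bit tile -> unit scale -> per-channel (x - mean) / std."""
    x = np.asarray(tile_pixels, dtype=float) / 255.0
    return (x - np.asarray(params.channel_means)) / np.asarray(params.channel_stds)


def unstandardize(tile: np.ndarray,
                  params: StandardizationParams = DEFAULT_STANDARDIZATION
                  ) -> np.ndarray:
    """Inverse of standardize, back to 8-bit (exact up to quantization)."""
    x = tile * np.asarray(params.channel_stds) + np.asarray(params.channel_means)
    return np.clip(np.round(x * 255.0), 0, 255).astype(np.uint8)
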