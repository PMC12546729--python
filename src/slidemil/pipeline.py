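"""End-to-end glue: rendered slides -> QC'd, normalized instance pools.

The pixel encoder's fixed front end is a block-mean reduction of each
256x256 tile to 16x16x3; because that reduction commutes with 90-degree
rotations, flips and per-channel affine colour jitter, tiles are reduced
once per slide (on the unit-interval scale, before standardization) and
augmentation is applied to the cached reduced tiles at bag-sampling time.
"""

from __future__ import annotations

import numpy as np

from . import preprocess as pp
from .mil import reduce_tile
from .train import SlideBagDataset

__all__ = [
    "slide_pool_from_image", "dataset_from_cohort",
    "make_training_augment", "standardize_instances",
]


def slide_pool_from_image(image: np.ndarray, level: pp.ResolutionLevel,
                          normalize: bool = True,
                          reference: pp.StainProfile | None = None,
                          qc_config: pp.QCConfig = pp.QCConfig(),
                          min_valid: int | None = None,
                          encoder_pool: int = 16):
    """Tessellate, filter, optionally Macenko-normalize and reduce one slide.

    The source stain profile is fitted once on the whole slide image and
    reused for all its tiles. Returns (pool (M, encoder_pool^2*3) floats in
    [0, 1], tile origins, TileFilterReport) — pool is None when the slide
    is rejected by the 80/2^R gate (or the supplied ``min_valid``).
    """
    tiles = pp.tessellate(image, level)
    valid, report = pp.filter_slide(tiles, level, qc_config, min_valid=min_valid)
    if not report.slide_accepted:
        return None, [], report
    source = None
    if normalize:
        if reference is None:
            raise ValueError("normalization requested without a reference profile")
        source = pp.macenko_fit(image, level)
    reduced, origins = [], []
    for tile in valid:
        px = tile.pixels
        if normalize:
            px = pp.macenko_normalize(px, reference, source=source)
        reduced.append(reduce_tile(px.astype(float) / 255.0, pool=encoder_pool))
        origins.append(tile.origin)
    return np.stack(reduced), origins, report


def dataset_from_cohort(records_with_images, level: pp.ResolutionLevel,
                        normalize: bool = True,
                        reference: pp.StainProfile | None = None,
                        min_valid: int | None = None,
                        encoder_pool: int = 16):
    """Build a SlideBagDataset from (slide_id, image, label) triples.

    When normalization is on and no reference is given, the reference is
    fitted on a mosaic of QC-passed tiles drawn from the first accepted
    slides (deterministic given the record order). A multi-slide mosaic
    covers both tissue classes, so both stain directions are anchored by
    plenty of pixels — a single slide dominated by one stain yields a
    fragile angle estimate. Returns (dataset, reference, reports, skipped).
    """
    if normalize and reference is None:
        mosaic, n_slides_used = [], 0
        for slide_id, image, _ in records_with_images:
            tiles = pp.tessellate(image, level)
            valid, report = pp.filter_slide(tiles, level, min_valid=min_valid)
            if report.slide_accepted:
                mosaic.extend(t.pixels.reshape(-1, 3) for t in valid[:4])
                n_slides_used += 1
            if n_slides_used >= 8:
                break
        if not mosaic:
            raise ValueError("no slide passed QC; cannot fit a stain reference")
        reference = pp.macenko_fit(np.concatenate(mosaic)[:, None, :], level)
    pools, labels, ids, reports, skipped = [], [], [], {}, []
    for slide_id, image, label in records_with_images:
        pool, _, report = slide_pool_from_image(
            image, level, normalize=normalize, reference=reference,
            min_valid=min_valid, encoder_pool=encoder_pool)
        reports[slide_id] = report
        if pool is None:
            skipped.append(slide_id)
            continue
        pools.append(pool)
        labels.append(int(label))
        ids.append(slide_id)
    dataset = SlideBagDataset(pools=pools, labels=np.array(labels, dtype=int),
                              slide_ids=ids)
    return dataset, reference, reports, skipped


def standardize_instances(instances: np.ndarray,
                          params: pp.StandardizationParams = pp.DEFAULT_STANDARDIZATION,
                          encoder_pool: int = 16) -> np.ndarray:
    """Per-channel standardization of reduced unit-scale instance vectors."""
    x = instances.reshape(len(instances), encoder_pool, encoder_pool, 3)
    x = (x - np.asarray(params.channel_means)) / np.asarray(params.channel_stds)
    return x.reshape(len(instances), -1)


def make_training_augment(params: pp.StandardizationParams = pp.DEFAULT_STANDARDIZATION,
                          encoder_pool: int = 16, jitter: float = 0.05):
    """Bag-level augment function: rotate/flip/jitter each reduced tile,
    then standardize. Suitable as ``train(..., augment_fn=...)``."""

    def _augment(instances: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        shaped = instances.reshape(len(instances), encoder_pool, encoder_pool, 3)
        out = np.stack([pp.augment(t, rng, jitter=jitter) for t in shaped])
        out = (out - np.asarray(params.channel_means)) / np.asarray(params.channel_stds)
        return out.reshape(len(instances), -1)

    return _augment
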