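"""Synthetic slide cohorts and feature-level MIL bags.

Real colorectal H&E cohorts are private or external, so every pipeline
stage is exercised on generated data that reproduces the statistical
structure the method assumes:

* ~82% of slides contain tumour; among tumour slides roughly 53/82 are
  dominated by tumour tissue and 29/82 are mixtures of tumour and normal
  tissue (the cohort the training protocol was built for);
* tumour occupies one contiguous blob with darker, denser, high-frequency
  texture, so MIL witness tiles exist and localization has a ground truth;
* artifacts (pen marks, dots, folds, ...) occur with class-conditional
  prevalences matching the observed artifact table, for bias QA;
* slides are rendered as genuine two-stain (hematoxylin/eosin) optical-
  density mixtures, so Macenko stain estimation has a well-posed target
  and stain shifts between cohorts are a simple concentration scaling.

Feature-level bags skip imaging entirely: witness instances are drawn from
a mean-shifted Gaussian so pooling and training can be unit-tested fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
from scipy import ndimage

from .mil import bag_label_from_instances

__all__ = [
    "SyntheticSlideSpec", "SlideRecord", "CohortManifest", "FeatureBagSpec",
    "MECC_ARTIFACT_RATES", "TCGA_ARTIFACT_RATES",
    "generate_slide", "generate_cohort", "write_cohort", "generate_feature_bags",
]

# Unit-norm optical-density stain vectors (hematoxylin, eosin) used both to
# render slides and as ground truth for stain-estimation tests.
HEMATOXYLIN_OD = np.array([0.65, 0.70, 0.29])
EOSIN_OD = np.array([0.07, 0.99, 0.11])
HEMATOXYLIN_OD = HEMATOXYLIN_OD / np.linalg.norm(HEMATOXYLIN_OD)
EOSIN_OD = EOSIN_OD / np.linalg.norm(EOSIN_OD)

# Class-conditional artifact prevalences (tumour, normal) as observed in the
# two cohorts' artifact tables; used as generator defaults for bias QA.
MECC_ARTIFACT_RATES = {
    "black_dots": (0.65, 0.71),
    "black_spots": (0.67, 0.58),
    "folds": (0.62, 0.59),
    "pen_marks": (0.35, 0.26),
    "water_marks": (0.32, 0.25),
    "black_edges": (0.29, 0.23),
    "filaments": (0.18, 0.20),
}
TCGA_ARTIFACT_RATES = {
    "black_dots": (0.47, 0.45),
    "black_spots": (0.73, 0.74),
    "folds": (0.70, 0.63),
    "water_marks": (0.25, 0.22),
    "filaments": (0.35, 0.36),
    "dark_dye": (0.23, 0.16),
    "black_regions": (0.19, 0.16),
}

RENDERABLE_ARTIFACTS = (
    "pen_marks", "black_dots", "black_spots", "folds", "water_marks",
    "black_edges", "filaments", "blur", "bubbles", "dark_dye", "black_regions",
)


@dataclass
class SyntheticSlideSpec:
    width_px: int = 1024
    height_px: int = 1024
    class_label: str = "normal"            # {"tumour", "normal"}
    tumour_area_fraction: float = 0.0      # 0 for normal slides
    mixture: bool = False
    artifact_flags: tuple = ()
    seed: int = 0
    stain_gains: tuple = (1.0, 1.0)        # (H, E) concentration scaling
    stain_angles: tuple = (0.0, 0.0)       # (H, E) vector rotation, degrees

    def __post_init__(self):
        if self.class_label not in ("tumour", "normal"):
            raise ValueError("class_label must be 'tumour' or 'normal'")
        if (self.tumour_area_fraction > 0) != (self.class_label == "tumour"):
            raise ValueError("tumour_area_fraction > 0 iff class_label == 'tumour'")
        if min(self.width_px, self.height_px) < 512:
            raise ValueError("slides must be at least 512x512 px")


@dataclass
class SlideRecord:
    slide_id: str
    spec: SyntheticSlideSpec
    label: int                 # 1 = tumour
    cohort: str
    artifact_flags: dict       # artifact name -> 0/1
    path: str = ""
    mask_path: str = ""


@dataclass
class CohortManifest:
    records: list
    cohort_tag: str
    params: dict = field(default_factory=dict)

    @property
    def prevalence(self) -> float:
        labels = [r.label for r in self.records]
        return float(np.mean(labels))

    def to_frame(self) -> pd.DataFrame:
        artifact_names = sorted({k for r in self.records for k in r.artifact_flags})
        rows = []
        for r in self.records:
            row = {"slide_id": r.slide_id, "path": r.path, "label": r.label,
                   "cohort": r.cohort, "mask_path": r.mask_path}
            for name in artifact_names:
                row[name] = int(r.artifact_flags.get(name, 0))
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class FeatureBagSpec:
    n_bags: int = 200
    bag_size: int = 32
    feature_dim: int = 32
    witness_rate: float = 0.3
    class_separation: float = 3.0
    positive_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.witness_rate <= 1):
            raise ValueError("witness_rate must be in (0, 1]")
        if self.bag_size < 1 or self.feature_dim < 1:
            raise ValueError("bag_size and feature_dim must be >= 1")


# --------------------------------------------------------------------------
# low-level texture helpers
# --------------------------------------------------------------------------

def _smooth_field(rng, shape, scale):
    """Low-frequency Gaussian field in [0, 1] via coarse noise upsampling."""
    ch = max(shape[0] // scale, 1) + 2
    cw = max(shape[1] // scale, 1) + 2
    coarse = rng.standard_normal((ch, cw))
    fine = ndimage.zoom(coarse, (shape[0] / ch, shape[1] / cw), order=3)
    fine = fine[: shape[0], : shape[1]]
    lo, hi = fine.min(), fine.max()
    return (fine - lo) / max(hi - lo, 1e-12)


def _rotated_stains(h_deg: float, e_deg: float):
    """Rotate each stain vector within the H-E plane (dye-character drift).

    A positive angle moves the vector towards the other stain; results are
    clipped to non-negative OD and renormalized.
    """
    out = []
    for vec, other, deg in ((HEMATOXYLIN_OD, EOSIN_OD, h_deg),
                            (EOSIN_OD, HEMATOXYLIN_OD, e_deg)):
        ortho = other - (other @ vec) * vec
        ortho /= np.linalg.norm(ortho)
        a = np.radians(deg)
        v = np.clip(np.cos(a) * vec + np.sin(a) * ortho, 0, None)
        out.append(v / np.linalg.norm(v))
    return out


def _tumour_blob(rng, shape, target_fraction):
    """One contiguous star-convex blob covering target_fraction +/- a few %.

    The blob is a disc whose radius is modulated by smooth angular noise;
    the radius is rescaled once from the measured area so the final mask
    fraction lands within the requested tolerance.
    """
    h, w = shape
    cy = rng.uniform(0.32, 0.68) * h
    cx = rng.uniform(0.32, 0.68) * w
    n_theta = 256
    wobble = rng.standard_normal(8)
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    mod = np.zeros(n_theta)
    for k, a in enumerate(wobble, start=2):
        mod += a * np.cos(k * theta + rng.uniform(0, 2 * np.pi)) / k
    mod = 1.0 + 0.30 * mod / max(np.abs(mod).max(), 1e-12)

    yy, xx = np.mgrid[0:h, 0:w]
    r_pix = np.hypot(yy - cy, xx - cx)
    t_pix = np.mod(np.arctan2(yy - cy, xx - cx), 2 * np.pi)
    mod_pix = np.interp(t_pix, theta, mod, period=2 * np.pi)

    r0 = np.sqrt(target_fraction * h * w / np.pi)
    mask = r_pix <= r0 * mod_pix
    for _ in range(3):  # clipping at borders shrinks the area; correct it
        frac = mask.mean()
        if abs(frac - target_fraction) <= 0.03 * max(target_fraction, 1e-9):
            break
        r0 *= np.sqrt(target_fraction / max(frac, 1e-12))
        mask = r_pix <= r0 * mod_pix
    return mask


# --------------------------------------------------------------------------
# artifact renderers (simple parametric primitives; realism is a non-goal)
# --------------------------------------------------------------------------

def _disc(img, cy, cx, r, color, alpha=1.0):
    h, w = img.shape[:2]
    y0, y1 = max(int(cy - r), 0), min(int(cy + r) + 1, h)
    x0, x1 = max(int(cx - r), 0), min(int(cx + r) + 1, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    patch = img[y0:y1, x0:x1]
    patch[inside] = (1 - alpha) * patch[inside] + alpha * np.asarray(color, dtype=float)


def _stroke(img, rng, color, thickness, n_steps=12, step=40, alpha=0.85):
    h, w = img.shape[:2]
    y, x = rng.uniform(0.1, 0.9) * h, rng.uniform(0.1, 0.9) * w
    angle = rng.uniform(0, 2 * np.pi)
    for _ in range(n_steps):
        angle += rng.normal(0, 0.5)
        ny, nx = y + step * np.sin(angle), x + step * np.cos(angle)
        n_sub = int(step)
        for t in np.linspace(0, 1, n_sub):
            _disc(img, y + t * (ny - y), x + t * (nx - x), thickness, color, alpha)
        y, x = ny, nx


def _render_artifacts(img, flags, rng):
    """Paint requested artifacts onto an RGB float image in place."""
    annotations = {}
    for name in sorted(flags):
        if name not in RENDERABLE_ARTIFACTS:
            continue
        h, w = img.shape[:2]
        if name == "pen_marks":
            for _ in range(rng.integers(1, 3)):
                _stroke(img, rng, color=(30, 110, 60), thickness=rng.integers(4, 8))
            annotations[name] = "green ink strokes"
        elif name == "black_dots":
            pts = rng.uniform(0, 1, size=(int(rng.integers(25, 60)), 2))
            for py, px in pts:
                _disc(img, py * h, px * w, rng.integers(1, 4), (15, 15, 15))
            annotations[name] = f"{len(pts)} dots"
        elif name == "black_spots":
            for _ in range(rng.integers(3, 8)):
                _disc(img, rng.uniform(0, h), rng.uniform(0, w),
                      rng.integers(5, 15), (35, 30, 35), alpha=0.9)
            annotations[name] = "dark blobs"
        elif name == "folds":
            y0 = rng.uniform(0.2, 0.8) * h
            slope = rng.normal(0, 0.3)
            width = rng.integers(12, 28)
            yy = np.arange(h)[:, None]
            xx = np.arange(w)[None, :]
            band = np.abs(yy - (y0 + slope * xx)) < width
            img[band] *= 0.55
            annotations[name] = "darkened streak"
        elif name == "water_marks":
            for _ in range(rng.integers(2, 5)):
                cy, cx = rng.uniform(0, h), rng.uniform(0, w)
                _disc(img, cy, cx, rng.integers(20, 50), (250, 250, 250), alpha=0.35)
            annotations[name] = "pale rounded marks"
        elif name == "black_edges":
            side = rng.integers(0, 4)
            depth = int(rng.integers(8, 20))
            if side == 0:
                img[:depth] *= 0.2
            elif side == 1:
                img[-depth:] *= 0.2
            elif side == 2:
                img[:, :depth] *= 0.2
            else:
                img[:, -depth:] *= 0.2
            annotations[name] = "darkened border"
        elif name == "filaments":
            for _ in range(rng.integers(1, 4)):
                _stroke(img, rng, color=(50, 45, 50), thickness=1,
                        n_steps=20, step=25, alpha=0.9)
            annotations[name] = "thin dark threads"
        elif name == "blur":
            py, px = rng.uniform(0.1, 0.6, size=2)
            size = int(min(h, w) * 0.25)
            y0, x0 = int(py * h), int(px * w)
            patch = img[y0:y0 + size, x0:x0 + size]
            img[y0:y0 + size, x0:x0 + size] = ndimage.gaussian_filter(
                patch, sigma=(5, 5, 0))
            annotations[name] = "defocused patch"
        elif name == "bubbles":
            for _ in range(rng.integers(2, 6)):
                cy, cx = rng.uniform(0, h), rng.uniform(0, w)
                r = rng.integers(12, 30)
                _disc(img, cy, cx, r, (252, 252, 252), alpha=0.6)
                _disc(img, cy, cx, r, (120, 120, 120), alpha=0.25)
                _disc(img, cy, cx, max(r - 3, 1), (252, 252, 252), alpha=0.55)
            annotations[name] = "air bubbles"
        elif name == "dark_dye":
            img *= 0.8
            annotations[name] = "globally darkened stain"
        elif name == "black_regions":
            py, px = rng.uniform(0.1, 0.7, size=2)
            size = int(min(h, w) * rng.uniform(0.08, 0.18))
            img[int(py * h):int(py * h) + size, int(px * w):int(px * w) + size] = 5.0
            annotations[name] = "black rectangle"
    return annotations


# --------------------------------------------------------------------------
# slide rendering
# --------------------------------------------------------------------------

def generate_slide(spec: SyntheticSlideSpec):
    """Render one synthetic H&E-like slide.

    Returns (rgb uint8 image, binary tumour mask, artifact annotations).
    Normal tissue is a pale, low-frequency gland-like eosin pattern; tumour
    is a contiguous blob of dense, dark, high-frequency hematoxylin-heavy
    texture. Pixels are composed in optical density from the two stain
    vectors, then exponentiated back to RGB, so the image is a true
    two-stain mixture.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    shape = (h, w)

    # tissue mask: smooth field thresholded so ~88% of the slide is tissue
    field = _smooth_field(rng, shape, scale=160)
    tissue = field >= np.quantile(field, 0.12)

    # stain concentration fields; nuclear speckle gives the fine-grained
    # contrast real tissue has (and the edge content the QC filter expects).
    # Base levels, gland contrast and nuclear density vary per slide —
    # biological heterogeneity that no stain normalization should remove.
    base_h = rng.uniform(0.10, 0.22)
    base_e = rng.uniform(0.24, 0.40)
    gland_amp = rng.uniform(0.12, 0.24)
    nuclei_amp = rng.uniform(0.9, 1.3)
    nuclei_quantile = rng.uniform(0.84, 0.92)
    gland = _smooth_field(rng, shape, scale=48)
    micro = _smooth_field(rng, shape, scale=12)
    speckle = ndimage.gaussian_filter(rng.random(shape), sigma=1.2)
    nuclei = speckle > np.quantile(speckle, nuclei_quantile)   # sparse nuclei
    c_h = base_h + 0.10 * gland + 0.05 * micro + nuclei_amp * nuclei
    c_e = base_e + gland_amp * (1 - gland) + 0.06 * micro      # pink stroma

    if spec.tumour_area_fraction > 0:
        # tumour: hyperchromatic, hematoxylin-dominant tissue. The eosin
        # loss roughly offsets the hematoxylin excess, so tumour and normal
        # tissue have similar overall darkness, and both share the same
        # gland/micro modulation fields, so the within-region colour
        # *variation* has the same structure. The discriminative cue is the
        # mean H:E stain balance (purple vs pink) — the quantity stain
        # normalization exists to make comparable across slides.
        # tumour: hyperchromatic, hematoxylin-dominant tissue sharing the
        # structural modulation fields of normal tissue; eosin loss roughly
        # offsets the hematoxylin excess, so overall darkness is similar
        # and the class cue is the mean H:E stain balance (purple vs pink)
        # — the quantity stain normalization makes comparable across slides
        mask = _tumour_blob(rng, shape, spec.tumour_area_fraction)
        mask &= tissue
        grain = rng.standard_normal(shape) * 0.12
        base_th = rng.uniform(0.50, 0.72)
        base_te = rng.uniform(0.01, 0.06)
        c_h = np.where(mask, base_th + 0.10 * gland + 0.05 * micro
                       + nuclei_amp * 0.85 * nuclei + grain, c_h)
        c_e = np.where(mask, base_te + gland_amp * (1 - gland) + 0.06 * micro, c_e)
    else:
        mask = np.zeros(shape, dtype=bool)

    gh, ge = spec.stain_gains
    h_vec, e_vec = _rotated_stains(*spec.stain_angles)
    # dye density saturates: concentrations cap at a physical ceiling, which
    # keeps saturated pixels on their stain direction (no hue distortion)
    ch_eff = np.minimum(np.clip(c_h, 0, None) * gh, 3.2)
    ce_eff = np.minimum(np.clip(c_e, 0, None) * ge, 3.2)
    od = ch_eff[..., None] * h_vec + ce_eff[..., None] * e_vec
    img = 256.0 * np.power(10.0, -od) - 1.0

    # background: unstained glass, near-white with slight sensor noise
    bg = 250.0 + rng.normal(0, 1.5, size=shape)
    img[~tissue] = bg[~tissue, None]

    annotations = _render_artifacts(img, spec.artifact_flags, rng)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return img, mask, annotations


def generate_cohort(n_slides: int, prevalence: float = 0.82,
                    mixture_fraction: float = 0.29 / 0.82,
                    artifact_rates: dict | None = None,
                    seed: int = 0, cohort_tag: str = "synthetic",
                    width_px: int = 1024, height_px: int = 1024,
                    stain_gains: tuple = (1.0, 1.0),
                    stain_gain_range: tuple | None = None,
                    stain_angle_sd: float = 0.0) -> CohortManifest:
    """Draw slide specifications for a cohort; images are rendered lazily.

    Class counts follow the prevalence (rounded); among tumour slides,
    ``mixture_fraction`` are mixtures (tumour area ~ U(0.15, 0.40)) and the
    rest are tumour-dominated (~ U(0.55, 0.85)). Artifact flags are drawn
    class-conditionally from ``artifact_rates`` (default: the MECC-shaped
    table above).

    ``stain_gains`` applies one fixed (H, E) concentration scaling to every
    slide; ``stain_gain_range`` instead draws each slide's two gains
    independently and uniformly from that range, and ``stain_angle_sd``
    additionally perturbs each slide's stain vectors by Gaussian in-plane
    rotations (degrees). Together they emulate slide-to-slide staining
    heterogeneity — concentration and dye character — which is exactly the
    variation Macenko normalization corrects.
    """
    if n_slides < 2:
        raise ValueError("need at least 2 slides")
    if not (0 < prevalence < 1):
        raise ValueError("prevalence must be in (0, 1)")
    rates = dict(artifact_rates) if artifact_rates is not None else dict(MECC_ARTIFACT_RATES)
    for name, (rt, rn) in rates.items():
        if not (0 <= rt <= 1 and 0 <= rn <= 1):
            raise ValueError(f"artifact rate for {name!r} outside [0, 1]")

    rng = np.random.default_rng(seed)
    n_tumour = int(round(n_slides * prevalence))
    n_mix = int(round(n_tumour * mixture_fraction))
    labels = [1] * n_tumour + [0] * (n_slides - n_tumour)
    mixture = [i < n_mix for i in range(n_tumour)] + [False] * (n_slides - n_tumour)
    order = rng.permutation(n_slides)

    records = []
    for new_idx, idx in enumerate(order):
        label = labels[idx]
        mix = mixture[idx]
        if label == 1:
            area = rng.uniform(0.15, 0.40) if mix else rng.uniform(0.55, 0.85)
        else:
            area = 0.0
        flags = {}
        for name in sorted(rates):
            rt, rn = rates[name]
            flags[name] = int(rng.random() < (rt if label == 1 else rn))
        if stain_gain_range is not None:
            slide_gains = tuple(rng.uniform(*stain_gain_range, size=2))
        else:
            slide_gains = tuple(stain_gains)
        slide_angles = (tuple(rng.normal(0, stain_angle_sd, size=2))
                        if stain_angle_sd > 0 else (0.0, 0.0))
        spec = SyntheticSlideSpec(
            width_px=width_px, height_px=height_px,
            class_label="tumour" if label else "normal",
            tumour_area_fraction=float(area), mixture=mix,
            artifact_flags=tuple(name for name, v in flags.items() if v),
            seed=int(rng.integers(0, 2**31 - 1)),
            stain_gains=slide_gains,
            stain_angles=slide_angles,
        )
        records.append(SlideRecord(
            slide_id=f"{cohort_tag}_{new_idx:04d}", spec=spec, label=label,
            cohort=cohort_tag, artifact_flags=flags,
        ))
    params = {"n_slides": n_slides, "prevalence": prevalence,
              "mixture_fraction": mixture_fraction, "seed": seed,
              "width_px": width_px, "height_px": height_px,
              "stain_gains": list(stain_gains),
              "stain_gain_range": list(stain_gain_range) if stain_gain_range else None,
              "stain_angle_sd": stain_angle_sd,
              "artifact_rates": {k: list(v) for k, v in rates.items()}}
    return CohortManifest(records=records, cohort_tag=cohort_tag, params=params)


def write_cohort(manifest: CohortManifest, out_dir: str | Path) -> Path:
    """Render every slide to PNG (plus mask PNG) and write the manifest CSV.

    Returns the manifest path. Generator parameters are echoed to JSON.
    """
    out = Path(out_dir)
    (out / "slides").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for rec in manifest.records:
        img, mask, _ = generate_slide(rec.spec)
        rec.path = str(out / "slides" / f"{rec.slide_id}.png")
        rec.mask_path = str(out / "masks" / f"{rec.slide_id}_mask.png")
        iio.imwrite(rec.path, img)
        iio.imwrite(rec.mask_path, (mask * 255).astype(np.uint8))
    frame = manifest.to_frame()
    manifest_path = out / "manifest.csv"
    frame.to_csv(manifest_path, index=False)
    (out / "generator_params.json").write_text(json.dumps(manifest.params, indent=2))
    return manifest_path


# --------------------------------------------------------------------------
# feature-level bags
# --------------------------------------------------------------------------

def generate_feature_bags(spec: FeatureBagSpec):
    """Bags of Gaussian feature vectors obeying the MIL label rule.

    Background instances ~ N(0, I); witnesses are shifted by
    ``class_separation`` along a fixed unit direction, i.e. the Mahalanobis
    distance between witness and background distributions equals the
    separation. Positive bags get at least one witness (witness_rate = 0
    would contradict the MIL assumption and is rejected by the spec type).

    Returns a list of (features (N, D), instance_labels (N,), bag_label).
    """
    rng = np.random.default_rng(spec.seed)
    direction = rng.standard_normal(spec.feature_dim)
    direction /= np.linalg.norm(direction)

    n_pos = int(round(spec.n_bags * spec.positive_fraction))
    bag_labels = np.zeros(spec.n_bags, dtype=int)
    bag_labels[:n_pos] = 1
    rng.shuffle(bag_labels)

    bags = []
    for y_bag in bag_labels:
        x = rng.standard_normal((spec.bag_size, spec.feature_dim))
        y_inst = np.zeros(spec.bag_size, dtype=int)
        if y_bag == 1:
            y_inst = (rng.random(spec.bag_size) < spec.witness_rate).astype(int)
            if y_inst.sum() == 0:
                y_inst[rng.integers(spec.bag_size)] = 1
            x[y_inst == 1] += spec.class_separation * direction
        assert bag_label_from_instances(y_inst) == y_bag
        bags.append((x, y_inst, int(y_bag)))
    return bags
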