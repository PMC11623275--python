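"""Synthetic optic-nerve-head (ONH) fundus phantoms.

Each phantom emulates the appearance of a square ONH crop from a fundus
photograph: a darker reddish textured background, a bright elliptical optic
disc, a brighter concentric elliptical cup whose vertical diameter is a
chosen fraction (the cup-to-disc ratio, CDR) of the disc's, a few dark
curvilinear vessel-like strokes, and additive Gaussian pixel noise. The
ground-truth mask records the exact disc/cup geometry; the binary glaucoma
label follows the clinical CDR rule (glaucoma when CDR exceeds a
threshold), with configurable class imbalance and label-flip outliers so
that loss-function robustness can be studied under controlled conditions.

Ellipse vertical radii are snapped to half-integers around an integer
center row so that the mask-measured vertical diameter equals the rendered
one exactly; the recorded ``true_cdr`` is always measured from the emitted
mask.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import draw as skdraw
from skimage import transform as sktransform

BACKGROUND, DISC, CUP = 0, 1, 2

# per-channel tint giving the phantom its fundus-like orange-red cast
_TINT = np.array([1.15, 0.85, 0.55])
_BG_LEVEL = 0.30
_DISC_LEVEL = 0.62
_CUP_LEVEL = 0.88


@dataclass
class PhantomConfig:
    """Generation parameters for a phantom dataset.

    ``cdr_normal`` / ``cdr_glaucoma`` are the CDR sampling intervals of the
    two classes and must lie strictly below / above ``cdr_threshold``.
    ``label_flip_rate`` injects outliers by flipping each label
    independently (the clean label is preserved for diagnostics).
    ``noise_sd`` is the additive Gaussian noise level on the [0, 1]
    intensity scale.
    """

    n_images: int = 600
    image_size: int = 224
    glaucoma_fraction: float = 1 / 6
    cdr_normal: tuple = (0.2, 0.45)
    cdr_glaucoma: tuple = (0.65, 0.9)
    cdr_threshold: float = 0.6
    label_flip_rate: float = 0.05
    noise_sd: float = 0.05
    vessel_count: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images <= 0:
            raise ValueError("n_images must be positive")
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")
        if not (0 < self.glaucoma_fraction < 1):
            raise ValueError("glaucoma_fraction must be in (0, 1)")
        for name, (lo, hi) in (("cdr_normal", self.cdr_normal),
                               ("cdr_glaucoma", self.cdr_glaucoma)):
            if not (0 < lo < hi < 1):
                raise ValueError(f"{name} must be an interval inside (0, 1)")
        if self.cdr_normal[1] >= self.cdr_threshold:
            raise ValueError("cdr_normal must lie entirely below cdr_threshold")
        if self.cdr_glaucoma[0] <= self.cdr_threshold:
            raise ValueError("cdr_glaucoma must lie entirely above cdr_threshold")
        if not (0 <= self.label_flip_rate < 0.5):
            raise ValueError("label_flip_rate must be in [0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cdr_normal"] = list(self.cdr_normal)
        d["cdr_glaucoma"] = list(self.cdr_glaucoma)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        d["cdr_normal"] = tuple(d["cdr_normal"])
        d["cdr_glaucoma"] = tuple(d["cdr_glaucoma"])
        return cls(**d)


@dataclass
class Sample:
    """One phantom: image (H, W, 3) in [0, 1], mask (H, W) in {0, 1, 2},
    glaucoma label, mask-measured CDR, and the pre-flip clean label."""

    image: np.ndarray
    mask: np.ndarray
    label: int
    true_cdr: float
    clean_label: int


class PhantomDataset:
    """An in-memory list of phantoms with array views for training."""

    def __init__(self, samples: list[Sample], config: PhantomConfig | None = None):
        self.samples = samples
        self.config = config

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, i) -> Sample:
        return self.samples[i]

    @property
    def images(self) -> np.ndarray:
        return np.stack([s.image for s in self.samples])

    @property
    def masks(self) -> np.ndarray:
        return np.stack([s.mask for s in self.samples])

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=np.int64)

    @property
    def clean_labels(self) -> np.ndarray:
        return np.array([s.clean_label for s in self.samples], dtype=np.int64)

    @property
    def true_cdrs(self) -> np.ndarray:
        return np.array([s.true_cdr for s in self.samples])

    def subset(self, indices) -> "PhantomDataset":
        return PhantomDataset([self.samples[i] for i in indices], self.config)


def _snap_half(x: float) -> float:
    """Nearest half-integer k + 0.5 (at least 0.5)."""
    return max(round(x - 0.5) + 0.5, 0.5)


def _ellipse_mask(size: int, cy: int, cx: int, rv: float, rh: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / rv) ** 2 + ((xx - cx) / rh) ** 2 <= 1.0


def measured_vertical_cdr(mask: np.ndarray) -> float:
    """Vertical cup diameter / vertical disc diameter, in mask rows."""
    disc_rows = np.flatnonzero((mask >= DISC).any(axis=1))
    cup_rows = np.flatnonzero((mask == CUP).any(axis=1))
    if disc_rows.size == 0 or cup_rows.size == 0:
        raise ValueError("mask contains no disc or no cup region")
    return (cup_rows[-1] - cup_rows[0] + 1) / (disc_rows[-1] - disc_rows[0] + 1)


def _draw_vessels(image: np.ndarray, rng: np.random.Generator, count: int) -> None:
    """Dark curvilinear strokes (quadratic Beziers) radiating across the
    crop, mimicking retinal vessels; purely a distractor for the learner."""
    size = image.shape[0]
    canvas = np.zeros((size, size), dtype=bool)
    for _ in range(count):
        r0, c0 = rng.integers(0, size, 2)
        r2, c2 = rng.integers(0, size, 2)
        r1 = (r0 + r2) // 2 + rng.integers(-size // 4, size // 4 + 1)
        c1 = (c0 + c2) // 2 + rng.integers(-size // 4, size // 4 + 1)
        rr, cc = skdraw.bezier_curve(r0, c0, int(r1), int(c1), r2, c2, weight=1,
                                     shape=canvas.shape)
        canvas[rr, cc] = True
    if count:
        canvas = ndimage.binary_dilation(canvas, iterations=max(1, size // 128))
        # vessels are dark and reddish: attenuate green/blue more strongly
        atten = np.where(canvas[..., None], [0.55, 0.40, 0.40], 1.0)
        image *= atten


def render_phantom(cdr: float, cfg: PhantomConfig,
                   rng: np.random.Generator) -> Sample:
    """Render a single phantom with the requested cup-to-disc ratio.

    The label is derived from the mask-measured CDR against
    ``cfg.cdr_threshold``; no label flipping happens here (see
    :func:`generate_dataset`).
    """
    if not (0 < cdr < 1):
        raise ValueError(f"cdr must be in (0, 1), got {cdr}")
    size = cfg.image_size
    jitter = 0.1 * size

    # geometry: half-integer vertical radii around integer centers make the
    # mask-measured vertical diameters exact
    cy = int(size / 2 + rng.uniform(-jitter, jitter))
    cx = int(size / 2 + rng.uniform(-jitter, jitter))
    rv_d = _snap_half(0.29 * size * rng.uniform(0.9, 1.05))
    rh_d = max(_snap_half(rv_d * rng.uniform(0.85, 1.0)), 1.5)
    rv_c = _snap_half(cdr * rv_d)
    rh_c = min(max(_snap_half(rv_c * rng.uniform(0.85, 1.0)), 1.5), rh_d - 1.0)

    disc = _ellipse_mask(size, cy, cx, rv_d, rh_d)
    cup = _ellipse_mask(size, cy, cx, rv_c, rh_c)
    cup &= disc  # guaranteed by geometry; enforced for safety
    mask = np.zeros((size, size), dtype=np.uint8)
    mask[disc] = DISC
    mask[cup] = CUP

    # intensity: textured background, brighter disc, brightest cup
    texture = ndimage.gaussian_filter(rng.standard_normal((size, size)), size / 10)
    texture /= max(np.abs(texture).max(), 1e-9)
    base = _BG_LEVEL + 0.05 * texture
    base[disc] = _DISC_LEVEL + 0.03 * texture[disc]
    base[cup] = _CUP_LEVEL + 0.02 * texture[cup]
    image = np.clip(base[..., None] * _TINT[None, None, :], 0, 1)

    _draw_vessels(image, rng, cfg.vessel_count)

    if cfg.noise_sd > 0:
        image = image + rng.normal(0, cfg.noise_sd, image.shape)
    image = np.clip(image, 0, 1).astype(np.float32)

    true_cdr = measured_vertical_cdr(mask)
    label = int(true_cdr > cfg.cdr_threshold)
    return Sample(image=image, mask=mask, label=label,
                  true_cdr=float(true_cdr), clean_label=label)


def generate_dataset(cfg: PhantomConfig) -> PhantomDataset:
    """Generate a fully reproducible phantom dataset.

    Exactly ``round(n_images * glaucoma_fraction)`` samples draw their CDR
    uniformly from ``cdr_glaucoma``, the rest from ``cdr_normal``; labels
    are then flipped independently with probability ``label_flip_rate``
    (``clean_label`` keeps the pre-flip value). Sample order is shuffled.
    """
    rng = np.random.default_rng(cfg.seed)
    n_pos = int(round(cfg.n_images * cfg.glaucoma_fraction))
    cdrs = np.concatenate([
        rng.uniform(*cfg.cdr_glaucoma, size=n_pos),
        rng.uniform(*cfg.cdr_normal, size=cfg.n_images - n_pos),
    ])
    order = rng.permutation(cfg.n_images)
    samples = [render_phantom(float(cdrs[i]), cfg, rng) for i in order]
    if cfg.label_flip_rate > 0:
        flips = rng.random(cfg.n_images) < cfg.label_flip_rate
        for s, f in zip(samples, flips):
            if f:
                s.label = 1 - s.clean_label
    return PhantomDataset(samples, cfg)


# ------------------------------------------------------------ preprocessing


def crop_onh(image: np.ndarray, mask: np.ndarray, out_size: int,
             margin: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Square ONH crop around the disc, resampled to ``out_size``.

    The crop window is the disc bounding box padded to a square of
    ``margin`` times the box side, clamped with edge padding when it
    exceeds the frame. The image is resampled bilinearly, the mask with
    nearest-neighbour so labels are preserved exactly.
    """
    rows = np.flatnonzero((mask > 0).any(axis=1))
    cols = np.flatnonzero((mask > 0).any(axis=0))
    if rows.size == 0:
        raise ValueError("no optic disc found in mask")
    cy = (rows[0] + rows[-1]) / 2
    cx = (cols[0] + cols[-1]) / 2
    box = max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1)
    half = int(np.ceil(box * margin / 2))
    top, left = int(round(cy)) - half, int(round(cx)) - half
    side = 2 * half + 1

    pad = max(0, -top, -left, top + side - image.shape[0], left + side - image.shape[1])
    img_p = np.pad(image, ((pad, pad), (pad, pad), (0, 0)), mode="edge")
    mask_p = np.pad(mask, pad, mode="constant")
    top, left = top + pad, left + pad
    img_c = img_p[top:top + side, left:left + side]
    mask_c = mask_p[top:top + side, left:left + side]

    img_out = sktransform.resize(img_c, (out_size, out_size), order=1,
                                 anti_aliasing=False, preserve_range=True)
    mask_out = sktransform.resize(mask_c, (out_size, out_size), order=0,
                                  anti_aliasing=False, preserve_range=True)
    return img_out.astype(np.float32), mask_out.astype(np.uint8)


# ------------------------------------------------------------- augmentation


def hflip(sample: Sample) -> Sample:
    return replace(sample, image=sample.image[:, ::-1].copy(),
                   mask=sample.mask[:, ::-1].copy())


def vflip(sample: Sample) -> Sample:
    return replace(sample, image=sample.image[::-1].copy(),
                   mask=sample.mask[::-1].copy())


def rotate(sample: Sample, angle: float) -> Sample:
    """Rotate image (bilinear) and mask (nearest) by the same angle."""
    img = sktransform.rotate(sample.image, angle, order=1, mode="edge",
                             preserve_range=True).astype(np.float32)
    msk = sktransform.rotate(sample.mask, angle, order=0, mode="constant",
                             preserve_range=True).astype(np.uint8)
    return replace(sample, image=img, mask=msk)


def scale_brightness(sample: Sample, factor: float) -> Sample:
    return replace(sample, image=np.clip(sample.image * factor, 0, 1))


def augment(sample: Sample, rng: np.random.Generator) -> Sample:
    """Random composition of flips, rotation in +/-15 degrees, and
    brightness scaling in [0.9, 1.1]; geometry applies identically to image
    and mask; label and true_cdr are unchanged."""
    out = sample
    if rng.random() < 0.5:
        out = hflip(out)
    if rng.random() < 0.5:
        out = vflip(out)
    if rng.random() < 0.5:
        out = rotate(out, float(rng.uniform(-15, 15)))
    out = scale_brightness(out, float(rng.uniform(0.9, 1.1)))
    return out


# ---------------------------------------------------------------------- I/O

MANIFEST_COLUMNS = ["filename", "mask_filename", "label", "clean_label", "true_cdr"]


def write_dataset(dataset: PhantomDataset, out_dir) -> Path:
    """Write PNG images/masks and a CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(dataset.samples):
        img_name = f"images/phantom_{i:05d}.png"
        mask_name = f"masks/phantom_{i:05d}.png"
        Image.fromarray((s.image * 255).round().astype(np.uint8)).save(out_dir / img_name)
        Image.fromarray(s.mask, mode="L").save(out_dir / mask_name)
        rows.append([img_name, mask_name, s.label, s.clean_label, f"{s.true_cdr:.6f}"])
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        writer.writerows(rows)
    return manifest


def read_dataset(data_dir) -> PhantomDataset:
    """Read a dataset previously written by :func:`write_dataset` (or user
    data in the same PNG + CSV-manifest layout)."""
    data_dir = Path(data_dir)
    manifest = data_dir / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"manifest not found: {manifest}")
    samples = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            image = np.asarray(Image.open(data_dir / row["filename"]).convert("RGB"),
                               dtype=np.float32) / 255.0
            mask = np.asarray(Image.open(data_dir / row["mask_filename"]),
                              dtype=np.uint8)
            samples.append(Sample(
                image=image, mask=mask, label=int(row["label"]),
                clean_label=int(row["clean_label"]),
                true_cdr=float(row["true_cdr"]),
            ))
    return PhantomDataset(samples)
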