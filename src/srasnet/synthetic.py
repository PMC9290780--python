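"""Synthetic chromosome-like image generation.

Real Q-banded chromatid crops differ along three axes of class identity:
overall length, centromere position (the constriction separating short and
long arms), and the banding pattern along the axis.  The generator
realises exactly these three axes: each of the 24 classes (label 0 = Y,
1-22 = autosomes, 23 = X) owns a :class:`ClassTemplate` with a distinct
characteristic length, a centromere fraction, and a fixed ordered band
pattern.  Images are rendered polarised (short arm at the top) as
content-positive objects on an exactly-zero background, at intentionally
non-uniform sizes, so every downstream stage (boundary location, cropping,
super-resolution pairing, oversampling, classification) can be exercised
without any external dataset.

Paired low-resolution inputs for super-resolution training come from
:func:`degrade_to_lr` (Gaussian blur, block-mean decimation, mild sensor
noise).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .manifest import DatasetManifest, ManifestRecord

__all__ = [
    "ClassTemplate",
    "JitterSpec",
    "DatasetConfig",
    "default_templates",
    "bioimlab_counts",
    "default_imbalanced_counts",
    "generate_chromosome_image",
    "degrade_to_lr",
    "plan_dataset",
    "generate_dataset",
    "four_to_one_split_counts",
    "load_grayscale",
]

N_CLASSES = 24
Y_CLASS = 0
X_CLASS = 23

# Approximate relative cytogenetic lengths (chromosome 1 = 1.0).  The X is
# deliberately close to the 6-12 group, the Y short; all values distinct so
# a trivial length feature ranks the classes.
_REL_LENGTH = {
    1: 1.00, 2: 0.955, 3: 0.81, 4: 0.765, 5: 0.735, 6: 0.69, 7: 0.645,
    8: 0.59, 9: 0.565, 10: 0.545, 11: 0.535, 12: 0.525, 13: 0.445,
    14: 0.425, 15: 0.405, 16: 0.36, 17: 0.34, 18: 0.315, 19: 0.265,
    20: 0.245, 21: 0.195, 22: 0.215, Y_CLASS: 0.175, X_CLASS: 0.615,
}

# Centromere position as a fraction from the top (short arm up).
_CENTROMERE = {
    1: 0.48, 2: 0.39, 3: 0.46, 4: 0.27, 5: 0.27, 6: 0.39, 7: 0.39,
    8: 0.34, 9: 0.35, 10: 0.34, 11: 0.40, 12: 0.30, 13: 0.17, 14: 0.17,
    15: 0.18, 16: 0.41, 17: 0.33, 18: 0.29, 19: 0.46, 20: 0.44, 21: 0.26,
    22: 0.27, Y_CLASS: 0.28, X_CLASS: 0.38,
}


@dataclass(frozen=True)
class ClassTemplate:
    """Geometry and banding of one chromosome class."""

    class_id: int
    length_px: int
    width_px: int
    band_pattern: tuple[tuple[float, float, float], ...]  # (pos, width, level)
    centromere_pos: float

    def __post_init__(self):
        if not 0 <= self.class_id < N_CLASSES:
            raise ValueError(f"class_id {self.class_id} outside 0-23")
        if self.length_px <= 0 or not self.band_pattern:
            raise ValueError("template needs positive length and >=1 band")
        if self.length_px <= self.width_px:
            raise ValueError("length_px must exceed width_px")
        if not 0.0 < self.centromere_pos < 1.0:
            raise ValueError("centromere_pos must lie in (0, 1)")
        pos = [b[0] for b in self.band_pattern]
        if any(b >= a for a, b in zip(pos[1:], pos[:-1])):
            raise ValueError("band positions must be strictly increasing")


@dataclass(frozen=True)
class JitterSpec:
    """Per-image randomness: size jitter, rotation, band-intensity noise."""

    length_sd: float = 0.03          # relative sd of object length
    max_rotation_deg: float = 5.0    # uniform in +/- this
    band_noise_sd: float = 0.04      # additive Gaussian on band levels
    pixel_noise_sd: float = 3.0      # grey levels, inside the object only


def default_templates(height_scale: float = 1.0) -> dict[int, ClassTemplate]:
    """Build the 24 class templates.

    ``height_scale`` scales every length/width; at 1.0 the longest class
    renders around 190 px tall and the shortest around 40 px, matching a
    low-magnification microscope crop regime.
    """
    templates: dict[int, ClassTemplate] = {}
    for cid in range(N_CLASSES):
        rel = _REL_LENGTH[cid]
        length = max(12, int(round((38 + rel * 152) * height_scale)))
        width = max(5, int(round((9 + rel * 8) * height_scale)))
        if width >= length:
            width = length - 1
        # Band pattern is a fixed, class-specific draw: longer chromosomes
        # carry more bands.
        trng = np.random.default_rng(9000 + cid)
        n_bands = 3 + int(rel * 6)
        edges = np.sort(trng.uniform(0.05, 0.95, n_bands))
        # enforce strict increase with a minimum gap
        for i in range(1, n_bands):
            edges[i] = max(edges[i], edges[i - 1] + 0.02)
        edges = np.clip(edges, 0.0, 0.99)
        bands = tuple(
            (float(p), float(trng.uniform(0.05, 0.14)),
             float(trng.uniform(0.35, 1.0)))
            for p in edges
        )
        templates[cid] = ClassTemplate(
            class_id=cid,
            length_px=length,
            width_px=width,
            band_pattern=bands,
            centromere_pos=_CENTROMERE[cid],
        )
    return templates


def _axial_intensity(template: ClassTemplate, u: np.ndarray,
                     band_levels: np.ndarray) -> np.ndarray:
    """Intensity profile along the normalised axis coordinate u in [0,1]."""
    base = np.full_like(u, 0.55)
    for (pos, width, _), level in zip(template.band_pattern, band_levels):
        inside = np.abs(u - pos) <= width / 2.0
        base[inside] = level
    return base


def _width_profile(template: ClassTemplate, u: np.ndarray) -> np.ndarray:
    """Half-width across the axis: tapered ends, centromeric constriction."""
    taper = np.clip(np.minimum(u, 1.0 - u) / 0.08, 0.25, 1.0)
    constriction = 1.0 - 0.55 * np.exp(
        -((u - template.centromere_pos) ** 2) / (2 * 0.035 ** 2))
    half = (template.width_px / 2.0) * taper * constriction
    return np.maximum(half, 1.0)


def generate_chromosome_image(template: ClassTemplate, rng_seed: int,
                              jitter: JitterSpec | None = None) -> np.ndarray:
    """Render one chromatid as an 8-bit image (background exactly 0).

    The object is a banded elongated region whose axis runs top to bottom
    (short arm up), rotated by a small random angle and placed with random
    margins, so image sizes differ from call to call.
    """
    jitter = jitter or JitterSpec()
    rng = np.random.default_rng(rng_seed)

    length = max(10, int(round(template.length_px *
                               (1.0 + rng.normal(0.0, jitter.length_sd)))))
    angle = math.radians(rng.uniform(-jitter.max_rotation_deg,
                                     jitter.max_rotation_deg))
    band_levels = np.clip(
        np.array([lvl for (_, _, lvl) in template.band_pattern])
        + rng.normal(0.0, jitter.band_noise_sd, len(template.band_pattern)),
        0.15, 1.0)

    half_w_max = template.width_px / 2.0 + 1.0
    margin_top = int(rng.integers(3, 10))
    margin_left = int(rng.integers(3, 10))
    extra = int(math.ceil(abs(math.sin(angle)) * length)) + 2
    h = length + margin_top + int(rng.integers(3, 10)) + extra
    w = int(2 * half_w_max) + margin_left + int(rng.integers(3, 10)) + extra

    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    # axis origin: top of the object
    cy, cx = margin_top + extra / 2.0, margin_left + half_w_max + extra / 2.0
    ca, sa = math.cos(angle), math.sin(angle)
    u_px = (rows - cy) * ca + (cols - cx) * sa      # along the axis
    v_px = -(rows - cy) * sa + (cols - cx) * ca     # across the axis

    u = u_px / length
    inside_axis = (u >= 0.0) & (u <= 1.0)
    uc = np.clip(u, 0.0, 1.0)
    mask = inside_axis & (np.abs(v_px) <= _width_profile(template, uc))
    if not mask.any():  # pragma: no cover - geometry always non-empty
        raise RuntimeError("degenerate render produced empty content")

    intensity = _axial_intensity(template, uc, band_levels)
    img = np.zeros((h, w), dtype=np.float64)
    img[mask] = intensity[mask] * 235.0
    img[mask] += rng.normal(0.0, jitter.pixel_noise_sd, int(mask.sum()))
    img[mask] = np.clip(img[mask], 25.0, 255.0)
    return img.astype(np.uint8)


def degrade_to_lr(hr: np.ndarray, scale: int, noise_sd: float = 2.0,
                  rng_seed: int = 0) -> np.ndarray:
    """Produce the low-resolution counterpart of ``hr``.

    Gaussian blur (anti-aliasing), block-mean decimation by ``scale`` and
    additive sensor noise; output dims are ``floor(dims / scale)`` and the
    intensity range stays within ``[0, hr.max()]``.
    """
    if scale < 2:
        raise ValueError("scale must be >= 2")
    hr = np.asarray(hr, dtype=np.float64)
    if hr.shape[0] < scale or hr.shape[1] < scale:
        raise ValueError("image smaller than the decimation factor")
    from scipy.ndimage import gaussian_filter

    blurred = gaussian_filter(hr, sigma=0.5 * (scale - 1), mode="nearest")
    h2, w2 = hr.shape[0] // scale, hr.shape[1] // scale
    block = blurred[: h2 * scale, : w2 * scale].reshape(h2, scale, w2, scale)
    lr = block.mean(axis=(1, 3))
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        lr = lr + rng.normal(0.0, noise_sd, lr.shape)
    return np.clip(np.round(lr), 0, hr.max()).astype(np.uint8)


def four_to_one_split_counts(total: int) -> tuple[int, int]:
    """(train, test) sizes of a 4:1 split of ``total`` (test rounded up)."""
    test = math.ceil(total / 5)
    return total - test, test


def bioimlab_counts() -> dict[int, int]:
    """Per-class counts of the public Q-band reference set being emulated:
    238 per autosome, 193 X, 45 Y — 5474 chromatids in all."""
    counts = {cid: 238 for cid in range(1, 23)}
    counts[X_CLASS] = 193
    counts[Y_CLASS] = 45
    return counts


def default_imbalanced_counts() -> dict[int, int]:
    """Desk-scale default mimicking the same imbalance: 40 per autosome,
    20 X, 8 Y."""
    counts = {cid: 40 for cid in range(1, 23)}
    counts[X_CLASS] = 20
    counts[Y_CLASS] = 8
    return counts


@dataclass
class DatasetConfig:
    counts: dict[int, int] = field(default_factory=default_imbalanced_counts)
    seed: int = 0
    out_dir: str | Path = "synthetic"
    height_scale: float = 1.0
    jitter: JitterSpec = field(default_factory=JitterSpec)
    make_lr_pairs: bool = False
    sr_scale: int = 2
    lr_noise_sd: float = 2.0


def plan_dataset(counts: dict[int, int],
                 out_dir: str | Path = "synthetic") -> DatasetManifest:
    """Deterministic manifest layout (paths, labels, splits) without
    rendering.  Per class, the 4:1 train/test split puts ``ceil(n/5)``
    images in the test partition."""
    out_dir = Path(out_dir)
    records = []
    for cid in sorted(counts):
        n = counts[cid]
        if n < 0:
            raise ValueError("per-class counts must be >= 0")
        if not 0 <= cid < N_CLASSES:
            raise ValueError(f"class id {cid} outside 0-23")
        _, n_test = four_to_one_split_counts(n) if n else (0, 0)
        for k in range(n):
            split = "test" if k < n_test else "train"
            path = out_dir / f"class{cid:02d}_{k:04d}.png"
            records.append(ManifestRecord(str(path), cid, split))
    return DatasetManifest(records)


def generate_dataset(config: DatasetConfig) -> DatasetManifest:
    """Render the dataset described by ``config`` and write PNGs plus
    ``manifest.csv`` / ``manifest.json``; returns the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    templates = default_templates(config.height_scale)
    manifest = plan_dataset(config.counts, out_dir)
    root = np.random.SeedSequence(config.seed)
    lr_dir = out_dir / "lr"
    if config.make_lr_pairs:
        lr_dir.mkdir(exist_ok=True)
    for idx, rec in enumerate(manifest.records):
        img_seed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
        # spawn() advances the sequence, keeping every image independent
        img = generate_chromosome_image(templates[rec.label], img_seed,
                                        config.jitter)
        Image.fromarray(img, mode="L").save(rec.path)
        if config.make_lr_pairs:
            lr = degrade_to_lr(img, config.sr_scale, config.lr_noise_sd,
                               rng_seed=img_seed + 1)
            Image.fromarray(lr, mode="L").save(lr_dir / Path(rec.path).name)
    manifest.to_csv(out_dir / "manifest.csv")
    manifest.to_json(out_dir / "manifest.json")
    return manifest


def load_grayscale(path: str | Path, zero_background: bool = False) -> np.ndarray:
    """Read an image as 8-bit grayscale.

    ``zero_background=True`` adapts real light-background scans to the
    content-positive convention the boundary equations require: the image
    is inverted if its border is brighter than its interior and an Otsu
    threshold maps background pixels to exactly 0.
    """
    img = np.asarray(Image.open(path).convert("L"))
    if not zero_background:
        return img
    border = np.concatenate([img[0], img[-1], img[:, 0], img[:, -1]])
    if border.mean() > img.mean():
        img = 255 - img
    from skimage.filters import threshold_otsu

    t = threshold_otsu(img)
    out = img.copy()
    out[out <= t] = 0
    return out
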