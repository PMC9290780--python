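"""SMOTE oversampling of the rare sex-chromosome classes.

In a pooled chromatid library every cell contributes two copies of each
autosome but at most two X and one Y, so the X (label 23) and especially
the Y (label 0) classes are heavily under-represented and classifiers
learn them poorly.  Synthetic minority samples are created by linear
interpolation between a minority sample and one of its K nearest minority
neighbours (Euclidean distance on flattened, size-standardised images):

    x_new = x_i + u * (x_k - x_i),   u ~ Uniform(0, 1)

The per-seed synthesis count (sampling magnification) is
``eta = round((|S_max| - |S_min|) / |S_min|)``; any residual shortfall
after integer eta is topped up with extra draws so post-balance counts
match the majority exactly.  Only the training split is ever modified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .manifest import DatasetManifest, ManifestRecord

__all__ = ["MinoritySet", "SmoteConfig", "k_nearest_minority",
           "sampling_magnification", "synthesize", "smote_oversample",
           "balance_dataset"]

logger = logging.getLogger(__name__)


@dataclass
class MinoritySet:
    samples: np.ndarray  # (n, d) flattened feature vectors
    class_id: int
    K: int = 5

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or len(self.samples) < 2:
            raise ValueError("need >= 2 same-dimension minority samples")
        if not 1 <= self.K:
            raise ValueError("K must be positive")


@dataclass
class SmoteConfig:
    K: int = 5
    eta_override: int | None = None
    rng_seed: int = 0


def k_nearest_minority(minority: MinoritySet, i: int) -> list[int]:
    """Indices of the K nearest neighbours of sample ``i`` (excluded),
    ties broken toward the lower index."""
    n = len(minority.samples)
    if minority.K >= n:
        raise ValueError(f"K={minority.K} must be < {n} samples")
    d = np.linalg.norm(minority.samples - minority.samples[i], axis=1)
    d[i] = np.inf
    order = np.argsort(d, kind="stable")
    return [int(j) for j in order[:minority.K]]


def sampling_magnification(n_majority: int, n_minority: int) -> int:
    """eta = (|S_max| - |S_min|) / |S_min|, rounded to the nearest integer
    (half-to-even), floored at 0."""
    if n_minority < 1:
        raise ValueError("minority count must be >= 1")
    if n_majority <= n_minority:
        return 0
    return int(round((n_majority - n_minority) / n_minority))


def synthesize(x: np.ndarray, neighbour: np.ndarray, u: float) -> np.ndarray:
    """One interpolated sample x + u * (neighbour - x)."""
    return x + u * (neighbour - x)


def smote_oversample(minority: MinoritySet, config: SmoteConfig,
                     eta: int | None = None) -> np.ndarray:
    """Generate ``eta`` synthetic vectors per seed sample.

    Neighbours are drawn without replacement from the K nearest of each
    seed; if ``eta > K`` the draw falls back to with-replacement (logged).
    Deterministic for a fixed ``rng_seed``.
    """
    if eta is None:
        eta = config.eta_override
    if eta is None:
        raise ValueError("eta must be given via argument or eta_override")
    if eta < 0:
        raise ValueError("eta must be >= 0")
    rng = np.random.default_rng(config.rng_seed)
    out = []
    k = minority.K
    for i in range(len(minority.samples)):
        neigh = k_nearest_minority(minority, i)
        if eta > k:
            logger.warning(
                "eta=%d exceeds K=%d; drawing neighbours with replacement",
                eta, k)
            chosen = rng.choice(neigh, size=eta, replace=True)
        else:
            chosen = rng.choice(neigh, size=eta, replace=False)
        for j in chosen:
            u = rng.uniform(0.0, 1.0)
            out.append(synthesize(minority.samples[i],
                                  minority.samples[int(j)], u))
    d = minority.samples.shape[1]
    return np.asarray(out, dtype=np.float64).reshape(len(out), d)


def _load_flat(paths: list[str]) -> tuple[np.ndarray, tuple[int, int]]:
    imgs = [np.asarray(Image.open(p).convert("L")) for p in paths]
    shape = imgs[0].shape
    if any(im.shape != shape for im in imgs):
        raise ValueError("images must share one size (run the size "
                         "standardisation stage first)")
    return np.stack([im.ravel().astype(np.float64) for im in imgs]), shape


def balance_dataset(manifest: DatasetManifest, config: SmoteConfig,
                    out_dir: str | Path,
                    minority_classes: tuple[int, ...] = (0, 23),
                    ) -> DatasetManifest:
    """Oversample ``minority_classes`` in the training split up to the
    per-class maximum, writing synthetic PNGs with a ``_smote_<n>`` suffix.

    The test split is returned untouched; majority classes are never
    modified.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    train_counts = manifest.class_counts("train")
    if not train_counts:
        raise ValueError("empty training split")
    target = max(train_counts.values())
    new_records = list(manifest.records)
    for cls in minority_classes:
        n_min = train_counts.get(cls, 0)
        if n_min >= target:
            continue
        if n_min < 2:
            raise ValueError(
                f"class {cls} has {n_min} training samples; need >= 2 "
                "to form neighbourhoods")
        paths = [r.path for r in manifest.records
                 if r.split == "train" and r.label == cls]
        flat, shape = _load_flat(paths)
        k = min(config.K, n_min - 1)
        mset = MinoritySet(flat, cls, K=k)
        eta = config.eta_override
        if eta is None:
            eta = sampling_magnification(target, n_min)
        # never overshoot the majority count; the residual is topped up below
        eta = min(eta, (target - n_min) // n_min)
        cfg = SmoteConfig(K=k, rng_seed=config.rng_seed + cls)
        synth = smote_oversample(mset, cfg, eta=eta) if eta > 0 else \
            np.empty((0, flat.shape[1]))
        # top up the residual so counts match the majority exactly
        shortfall = target - n_min - len(synth)
        if shortfall > 0:
            rng = np.random.default_rng(cfg.rng_seed + 1)
            extras = []
            for _ in range(shortfall):
                i = int(rng.integers(n_min))
                j = int(rng.choice(k_nearest_minority(mset, i)))
                extras.append(synthesize(flat[i], flat[j],
                                         rng.uniform(0.0, 1.0)))
            synth = np.vstack([synth, extras]) if len(synth) else \
                np.asarray(extras)
        for n, vec in enumerate(synth):
            img = np.clip(np.round(vec.reshape(shape)), 0, 255).astype(np.uint8)
            path = out_dir / f"class{cls:02d}_smote_{n:04d}.png"
            Image.fromarray(img, mode="L").save(path)
            new_records.append(ManifestRecord(str(path), cls, "train"))
    return DatasetManifest(new_records)
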