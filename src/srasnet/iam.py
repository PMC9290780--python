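"""Image Adaptive Module: distortion-free size standardisation.

Chromatid crops come in arbitrary sizes, and naive resizing to the
classifier's input size distorts length — a primary class feature.  The
procedure here instead (1) locates the tight bounding box of the nonzero
content, (2) crops to it, (3) rescales *only* when the crop exceeds the
target canvas, preserving aspect ratio, and (4) pastes the result onto an
all-zero square canvas.

Boundary location uses true min/max over nonzero rows and columns, which
is well defined even for objects with internal all-zero rows.  Images must
follow the content-positive / zero-background convention (see
:func:`srasnet.synthetic.load_grayscale` for adapting real scans).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = ["ContentBounds", "IamConfig", "find_content_bounds",
           "crop_to_bounds", "fit_to_canvas", "iam_process"]


class EmptyContentError(ValueError):
    """Raised when an image contains no nonzero pixel."""


@dataclass(frozen=True)
class ContentBounds:
    """Inclusive first/last nonzero row (U/D) and column (L/R) indices."""

    U: int
    D: int
    L: int
    R: int

    def __post_init__(self):
        if not (0 <= self.U <= self.D and 0 <= self.L <= self.R):
            raise ValueError(f"invalid bounds {self}")

    @property
    def height(self) -> int:
        return self.D - self.U + 1

    @property
    def width(self) -> int:
        return self.R - self.L + 1


@dataclass(frozen=True)
class IamConfig:
    canvas_size: int = 224
    placement: str = "center"  # or "top_left"

    def __post_init__(self):
        if self.canvas_size < 1:
            raise ValueError("canvas_size must be >= 1")
        if self.placement not in ("center", "top_left"):
            raise ValueError(f"unknown placement {self.placement!r}")


def find_content_bounds(image: np.ndarray) -> ContentBounds:
    """Tight bounding box of all pixels strictly greater than zero."""
    image = np.asarray(image)
    rows = np.flatnonzero(image.any(axis=1))
    cols = np.flatnonzero(image.any(axis=0))
    if rows.size == 0:
        raise EmptyContentError("image has no nonzero content")
    return ContentBounds(int(rows[0]), int(rows[-1]),
                         int(cols[0]), int(cols[-1]))


def crop_to_bounds(image: np.ndarray, bounds: ContentBounds) -> np.ndarray:
    image = np.asarray(image)
    h, w = image.shape
    if bounds.D >= h or bounds.R >= w:
        raise ValueError(f"bounds {bounds} exceed image shape {image.shape}")
    return image[bounds.U:bounds.D + 1, bounds.L:bounds.R + 1].copy()


def fit_to_canvas(image: np.ndarray, config: IamConfig = IamConfig()) -> np.ndarray:
    """Rescale only if oversized, then paste onto a zero square canvas.

    When ``max(H, W)`` exceeds the canvas, both dims are multiplied by
    ``canvas_size / max(H, W)`` (bilinear, floor-rounded, clamped to
    >= 1 px); otherwise pixels are untouched.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    h, w = image.shape
    c = config.canvas_size
    if max(h, w) > c:
        factor = c / max(h, w)
        nh = max(1, int(h * factor))
        nw = max(1, int(w * factor))
        pil = Image.fromarray(image.astype(np.uint8), mode="L")
        image = np.asarray(pil.resize((nw, nh), Image.BILINEAR))
        # Interpolation can zero out edge rows/columns; re-tighten so the
        # pasted content keeps a tight bounding box (makes the full
        # adaptation idempotent).
        if image.any():
            b = find_content_bounds(image)
            image = image[b.U:b.D + 1, b.L:b.R + 1]
        h, w = image.shape
    canvas = np.zeros((c, c), dtype=image.dtype)
    if config.placement == "center":
        top, left = (c - h) // 2, (c - w) // 2
    else:
        top, left = 0, 0
    canvas[top:top + h, left:left + w] = image
    return canvas


def iam_process(image: np.ndarray, config: IamConfig = IamConfig()) -> np.ndarray:
    """Locate content, crop, and fit to the canvas (the full adaptation)."""
    bounds = find_content_bounds(image)
    return fit_to_canvas(crop_to_bounds(image, bounds), config)
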