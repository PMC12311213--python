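"""Image preparation for the ultrasound pipeline.

B-mode frames are converted to grayscale, the annotated lesion bounding box
is cropped with a small surrounding margin (nearby tissue carries signal),
and the crop is rescaled to a square input while preserving aspect ratio —
the longer side is scaled to ``target_size`` and the shorter side padded
symmetrically. Augmentation (flips, crops, rotation) is seeded and is only
legitimate on the training cohort; the pipeline enforces that guard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

# Rec.709 luminance weights for RGB -> gray
_LUMA = np.array([0.2126, 0.7152, 0.0722])

VALID_AUG_OPS = frozenset({"hflip", "vflip", "crop", "rotate"})


@dataclass(frozen=True)
class PreprocessConfig:
    target_size: int = 224
    margin_pixels: int = 8
    pad_value: float = 0.0
    normalization: str = "unit_interval"  # or "zscore_per_image"

    def __post_init__(self) -> None:
        if self.target_size <= 0:
            raise ValueError("target_size must be positive")
        if self.margin_pixels < 0:
            raise ValueError("margin_pixels must be non-negative")
        if self.normalization not in ("unit_interval", "zscore_per_image"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse a 1- or 3-channel image to a single luminance channel.

    3-channel input uses Rec.709 weights (0.2126 R + 0.7152 G + 0.0722 B);
    single-channel input is returned unchanged.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] == 1:
        return image[:, :, 0]
    if image.ndim == 3 and image.shape[2] == 3:
        return image @ _LUMA
    raise ValueError(f"expected 1 or 3 channels, got shape {image.shape}")


def crop_roi(image: np.ndarray, bbox: tuple[int, int, int, int], margin_pixels: int = 0) -> np.ndarray:
    """Crop the bounding box expanded by ``margin_pixels`` per side, clipped
    to the image; never pads (padding happens in :func:`resize_pad`).

    ``bbox`` is (x_min, y_min, x_max, y_max), 0-based, half-open.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    x0, y0, x1, y1 = bbox
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(f"bbox {bbox} not inside {w}x{h} image")
    m = int(margin_pixels)
    cx0, cy0 = max(0, x0 - m), max(0, y0 - m)
    cx1, cy1 = min(w, x1 + m), min(h, y1 + m)
    crop = image[cy0:cy1, cx0:cx1]
    if crop.size == 0:
        raise ValueError("empty crop")
    return crop


def resize_pad(image: np.ndarray, target_size: int = 224, pad_value: float = 0.0) -> np.ndarray:
    """Scale the longer side to ``target_size`` (bilinear), keep aspect ratio,
    and pad the shorter side symmetrically with ``pad_value``."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    h, w = image.shape
    scale = target_size / max(h, w)
    new_h = max(1, int(round(h * scale)))
    new_w = max(1, int(round(w * scale)))
    # resize via PIL float mode (bilinear); exact for the identity case
    if (new_h, new_w) != (h, w):
        pil = Image.fromarray(image.astype(np.float32), mode="F")
        pil = pil.resize((new_w, new_h), resample=Image.BILINEAR)
        resized = np.asarray(pil, dtype=float)
    else:
        resized = image
    out = np.full((target_size, target_size), float(pad_value))
    top = (target_size - new_h) // 2
    left = (target_size - new_w) // 2
    out[top : top + new_h, left : left + new_w] = resized
    return out


def normalize_image(image: np.ndarray, mode: str = "unit_interval") -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if mode == "unit_interval":
        lo, hi = image.min(), image.max()
        return (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
    if mode == "zscore_per_image":
        sd = image.std()
        return (image - image.mean()) / (sd if sd > 0 else 1.0)
    raise ValueError(f"unknown normalization {mode!r}")


def augment(
    image: np.ndarray,
    seed: int,
    ops: set[str] = frozenset({"hflip", "vflip", "crop", "rotate"}),
    rotate_range: float = 15.0,
    crop_fraction_range: tuple[float, float] = (0.8, 1.0),
) -> np.ndarray:
    """Seeded random augmentation: flips with p=0.5 each, random central-ish
    crop (re-resized to the input shape), rotation with angle uniform in
    ``±rotate_range`` degrees. Output has the input's shape."""
    unknown = set(ops) - VALID_AUG_OPS
    if unknown:
        raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = np.asarray(image, dtype=float)
    h, w = out.shape
    if "hflip" in ops and rng.random() < 0.5:
        out = out[:, ::-1]
    if "vflip" in ops and rng.random() < 0.5:
        out = out[::-1, :]
    if "crop" in ops:
        frac = rng.uniform(*crop_fraction_range)
        ch, cw = max(1, int(round(h * frac))), max(1, int(round(w * frac)))
        top = rng.integers(0, h - ch + 1)
        left = rng.integers(0, w - cw + 1)
        cropped = out[top : top + ch, left : left + cw]
        pil = Image.fromarray(np.ascontiguousarray(cropped, dtype=np.float32), mode="F")
        out = np.asarray(pil.resize((w, h), resample=Image.BILINEAR), dtype=float)
    if "rotate" in ops:
        angle = rng.uniform(-rotate_range, rotate_range)
        if abs(angle) > 1e-12:
            pil = Image.fromarray(np.ascontiguousarray(out, dtype=np.float32), mode="F")
            out = np.asarray(pil.rotate(angle, resample=Image.BILINEAR), dtype=float)
    return np.ascontiguousarray(out)


def preprocess_image(
    image: np.ndarray,
    bbox: tuple[int, int, int, int],
    config: PreprocessConfig = PreprocessConfig(),
) -> np.ndarray:
    """Full deterministic chain: grayscale -> ROI crop + margin -> resize/pad
    -> intensity normalization. Returns a target_size x target_size array."""
    gray = to_grayscale(image)
    crop = crop_roi(gray, bbox, config.margin_pixels)
    square = resize_pad(crop, config.target_size, config.pad_value)
    return normalize_image(square, config.normalization)


def load_png(path) -> np.ndarray:
    """Read a PNG into a float array in [0, 1] (grayscale or RGB)."""
    with Image.open(path) as im:
        arr = np.asarray(im, dtype=float)
    return arr / 255.0
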