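"""Colour parameters: channel statistics, grayscale conversion, binarization.

Twelve of the seventeen parameters come from this module: per-channel means
and medians (R_MEAN..B_MEDIAN), grayscale mean/median (GS_MEAN, GS_MEDIAN),
and the white percentage of the binarized grayscale image at the four
thresholds 0.05, 0.10, 0.15, 0.20 (WH_PERCENT1..4).
"""

from __future__ import annotations

import numpy as np

from .io import RgbImage

#: Binarization thresholds used in pipeline runs, on the normalised [0, 1] scale.
BINARIZATION_THRESHOLDS: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20)

# Luminance weights of the grayscale conversion (ITU-R 601 luma).
_GRAY_WEIGHTS = (0.2989, 0.5870, 0.1140)


def _pixels(img: RgbImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, RgbImage) else np.asarray(img)


def to_grayscale(img: RgbImage | np.ndarray) -> np.ndarray:
    """Convert a 24-bit RGB image to an 8-bit grayscale image.

    Brightness = 0.2989*R + 0.5870*G + 0.1140*B, rounded half away from
    zero to the nearest integer and clamped to [0, 255].
    """
    rgb = _pixels(img).astype(np.float64)
    gs = (
        _GRAY_WEIGHTS[0] * rgb[..., 0]
        + _GRAY_WEIGHTS[1] * rgb[..., 1]
        + _GRAY_WEIGHTS[2] * rgb[..., 2]
    )
    # values are non-negative, so half-up == half-away-from-zero
    return np.clip(np.floor(gs + 0.5), 0, 255).astype(np.uint8)


def channel_stats(img: RgbImage | np.ndarray) -> dict[str, float]:
    """Mean and median brightness of the R, G and B channels.

    Medians average the two middle order statistics when the pixel count is
    even (the standard definition).
    """
    rgb = _pixels(img)
    out: dict[str, float] = {}
    for k, name in enumerate("RGB"):
        chan = rgb[..., k].astype(np.float64)
        out[f"{name}_MEAN"] = float(chan.mean())
        out[f"{name}_MEDIAN"] = float(np.median(chan))
    return out


def grayscale_stats(gs: np.ndarray) -> dict[str, float]:
    """Mean and median brightness of an 8-bit grayscale image."""
    gs = np.asarray(gs, dtype=np.float64)
    return {"GS_MEAN": float(gs.mean()), "GS_MEDIAN": float(np.median(gs))}


def binarize(gs: np.ndarray, threshold: float) -> np.ndarray:
    """Binarize a grayscale image at a threshold on the normalised scale.

    A pixel is white (1) iff ``pixel / 255 > threshold`` (strict
    comparison). ``threshold`` must lie strictly inside (0, 1).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    gs = np.asarray(gs)
    return (gs.astype(np.float64) > threshold * 255.0).astype(np.uint8)


def white_percentage(binary: np.ndarray) -> float:
    """Percentage of white (1) pixels in a binary image, in [0, 100]."""
    binary = np.asarray(binary)
    return float(100.0 * np.count_nonzero(binary) / binary.size)


def color_features(img: RgbImage | np.ndarray, thresholds=BINARIZATION_THRESHOLDS) -> dict[str, float]:
    """The 12 colour parameters of one image, keyed by parameter name."""
    gs = to_grayscale(img)
    out = channel_stats(img)
    out.update(grayscale_stats(gs))
    for idx, t in enumerate(thresholds, start=1):
        out[f"WH_PERCENT{idx}"] = white_percentage(binarize(gs, t))
    return out
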