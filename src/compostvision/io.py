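"""Image and table input/output.

Images are decoded to ``uint8`` H x W x 3 arrays (row-major, origin at the
top-left, rows indexed downward — this convention fixes the meaning of the
GLCM direction offsets). Grayscale-on-disk inputs are replicated across the
three channels, alpha channels are dropped, and higher bit depths are
linearly rescaled to 8 bits so that fixtures of any depth are usable.

Feature tables are plain CSV: ``experiment_id,source_id`` followed by the 17
parameter columns in :data:`PARAMETER_ORDER`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd

#: The 17 colour and texture parameters, in canonical column order.
PARAMETER_ORDER: tuple[str, ...] = (
    "R_MEAN",
    "G_MEAN",
    "B_MEAN",
    "R_MEDIAN",
    "G_MEDIAN",
    "B_MEDIAN",
    "GS_MEAN",
    "GS_MEDIAN",
    "WH_PERCENT1",
    "WH_PERCENT2",
    "WH_PERCENT3",
    "WH_PERCENT4",
    "ENTROPY",
    "CONTRAST",
    "CORRELATION",
    "ENERGY",
    "HOMOGENEITY",
)

#: Valid group labels for a composting experiment.
GROUP_LABELS = ("favorable", "unfavorable")


@dataclass
class RgbImage:
    """A decoded 24-bit RGB sample image plus its provenance labels.

    Attributes
    ----------
    pixels : numpy.ndarray
        ``uint8`` array of shape (H, W, 3); channels are R, G, B.
    source_id : str
        Identifier of the individual photograph (file stem).
    experiment_id : str
        Identifier of the composting experiment the sample came from
        (e.g. the chamber name).
    """

    pixels: np.ndarray
    source_id: str = ""
    experiment_id: str = ""

    def __post_init__(self) -> None:
        validate_rgb(self.pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


def validate_rgb(pixels: np.ndarray) -> np.ndarray:
    """Check an array is a valid H x W x 3 uint8 image with H, W >= 2."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 array, got shape {pixels.shape}")
    if pixels.shape[0] < 2 or pixels.shape[1] < 2:
        raise ValueError(
            "image must be at least 2 x 2 pixels (texture analysis needs a "
            f"neighbour pair in every direction), got {pixels.shape[:2]}"
        )
    if pixels.dtype != np.uint8:
        raise ValueError(f"expected uint8 pixels, got dtype {pixels.dtype}")
    return pixels


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    """Rescale integer images of any depth to 8 bits."""
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return (arr // 257).astype(np.uint8)  # 65535 -> 255 exactly
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        scaled = (arr.astype(np.float64) - info.min) / (info.max - info.min) * 255.0
        return np.floor(scaled + 0.5).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.floating):
        # float images are assumed normalised to [0, 1]
        return np.floor(np.clip(arr, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    raise ValueError(f"unsupported image dtype {arr.dtype}")


def read_image(path: str | os.PathLike, experiment_id: str = "") -> RgbImage:
    """Read a JPEG/PNG/TIFF sample image into an :class:`RgbImage`.

    Grayscale inputs are replicated across R, G, B; an alpha channel is
    dropped; 16-bit inputs are rescaled to [0, 255] by integer division by
    257. Raises ``IOError`` for unreadable files and ``ValueError`` for
    images smaller than 2 x 2.
    """
    path = os.fspath(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoding failures vary by backend
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise IOError(f"file {path!r} does not decode to a 2-D image")
    arr = _to_uint8(arr)
    stem = os.path.splitext(os.path.basename(path))[0]
    return RgbImage(pixels=arr, source_id=stem, experiment_id=experiment_id)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

_ID_COLUMNS = ["experiment_id", "source_id"]


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate column layout and uniqueness of a feature table."""
    expected = _ID_COLUMNS + list(PARAMETER_ORDER)
    missing = [c for c in expected if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    if len(table) == 0:
        raise ValueError("feature table is empty")
    dup = table.duplicated(subset=_ID_COLUMNS)
    if dup.any():
        pairs = table.loc[dup, _ID_COLUMNS].to_records(index=False).tolist()
        raise ValueError(f"duplicate (experiment_id, source_id) pairs: {pairs[:5]}")
    return table[expected]


def write_feature_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a feature table to CSV with >= 10 significant digits."""
    table = validate_feature_table(table)
    table.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature-table CSV written by :func:`write_feature_table`."""
    table = pd.read_csv(path, dtype={"experiment_id": str, "source_id": str})
    return validate_feature_table(table)


def read_group_assignment(path: str | os.PathLike) -> dict[str, str]:
    """Read an ``experiment_id,label`` CSV into a mapping.

    Labels must be ``favorable`` or ``unfavorable``.
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("experiment_id", "label"):
        if col not in df.columns:
            raise ValueError(f"groups file {os.fspath(path)!r} lacks column {col!r}")
    groups: dict[str, str] = {}
    for row_num, (exp, label) in enumerate(zip(df["experiment_id"], df["label"]), start=2):
        if label not in GROUP_LABELS:
            raise ValueError(
                f"groups file row {row_num}: label {label!r} is not one of {GROUP_LABELS}"
            )
        if exp in groups:
            raise ValueError(f"groups file row {row_num}: duplicate experiment {exp!r}")
        groups[exp] = label
    present = set(groups.values())
    for needed in GROUP_LABELS:
        if needed not in present:
            raise ValueError(f"groups file defines no {needed!r} experiment")
    return groups


def write_group_assignment(groups: dict[str, str], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"experiment_id": list(groups), "label": [groups[k] for k in groups]}
    ).to_csv(path, index=False, lineterminator="\n")
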