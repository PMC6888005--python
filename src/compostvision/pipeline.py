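"""Library-level orchestration: extract features, compare groups.

``extract_features`` computes the full 17-parameter vector for one image;
``extract_directory`` walks a study tree (one sub-directory per composting
experiment) into a feature table; ``compare_tables`` joins a feature table
with a group assignment into a :class:`~compostvision.groupstats.GroupComparison`.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .color import color_features
from .color import to_grayscale
from .config import RunConfig
from .groupstats import GroupComparison, summarize_groups
from .io import PARAMETER_ORDER, RgbImage, read_image, validate_feature_table
from .texture import texture_vector

logger = logging.getLogger("compostvision")

_IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}


def extract_features(img: RgbImage | np.ndarray, config: RunConfig | None = None) -> dict[str, float]:
    """All 17 colour and texture parameters of one image, in canonical order."""
    config = config or RunConfig()
    gs = to_grayscale(img)
    values = color_features(img, thresholds=config.thresholds)
    values.update(
        texture_vector(gs, levels=config.glcm_levels, quantization=config.glcm_quantization)
    )
    return {name: values[name] for name in PARAMETER_ORDER}


def extract_directory(image_root: str | os.PathLike, config: RunConfig | None = None) -> pd.DataFrame:
    """Extract a feature table from a directory tree of sample images.

    The immediate parent directory of each image is its experiment id
    (one composting chamber = one directory). Corrupt or undecodable files
    are logged and skipped; rows are sorted by (experiment_id, source_id)
    so output is independent of filesystem order. Raises if no image can
    be decoded.
    """
    config = config or RunConfig()
    image_root = os.fspath(image_root)
    if not os.path.isdir(image_root):
        raise IOError(f"image root {image_root!r} is not a directory")
    rows = []
    n_skipped = 0
    for exp_id in sorted(os.listdir(image_root)):
        exp_dir = os.path.join(image_root, exp_id)
        if not os.path.isdir(exp_dir):
            continue
        for fname in sorted(os.listdir(exp_dir)):
            if os.path.splitext(fname)[1].lower() not in _IMAGE_EXTENSIONS:
                continue
            path = os.path.join(exp_dir, fname)
            try:
                img = read_image(path, experiment_id=exp_id)
            except (IOError, ValueError) as exc:
                logger.warning("skipping %s: %s", path, exc)
                n_skipped += 1
                continue
            row = {"experiment_id": exp_id, "source_id": img.source_id}
            row.update(extract_features(img, config))
            rows.append(row)
    if not rows:
        raise IOError(f"no decodable images found under {image_root!r}")
    logger.info("extracted %d images (%d skipped)", len(rows), n_skipped)
    table = pd.DataFrame(rows).sort_values(["experiment_id", "source_id"]).reset_index(drop=True)
    return validate_feature_table(table)


def compare_tables(
    features: pd.DataFrame,
    groups: dict[str, str],
    config: RunConfig | None = None,
) -> GroupComparison:
    """Group comparison of a feature table, carrying the resolved config."""
    config = config or RunConfig()
    comparison = summarize_groups(features, groups, alpha=config.alpha)
    comparison.config = config.to_dict()
    return comparison
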