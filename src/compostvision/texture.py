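"""GLCM texture statistics on 8-bit grayscale images.

The grayscale image is quantized to 8 brightness classes over the fixed
range [0, 255] (equal-width bins, not per-image min-max stretching — the
whole point of the features is comparability across images of differing
brightness; min-max is available as an option for sensitivity checks).
Symmetric gray-level co-occurrence matrices are accumulated for a 1-pixel
neighbourhood in four directions (0, 45, 90, 135 degrees), each neighbour
pair counted in both orders. CONTRAST, CORRELATION, ENERGY and HOMOGENEITY
are computed per direction and then averaged over the four directions;
ENTROPY is the Shannon entropy (bits) of the 256-bin brightness histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _shannon_entropy

#: Direction name -> (row offset, column offset) of the 1-pixel neighbour.
#: Rows increase downward, so 45 degrees points up-and-right.
DIRECTIONS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclass(frozen=True)
class Glcm:
    """A normalised symmetric co-occurrence matrix for one direction.

    ``p[i-1, j-1]`` is the probability of gray levels (i, j) co-occurring,
    with levels indexed 1..L as in the defining formulas; ``raw_counts``
    holds the symmetric pair counts before normalisation.
    """

    p: np.ndarray
    raw_counts: np.ndarray
    direction: int

    @property
    def levels(self) -> int:
        return self.p.shape[0]


@dataclass(frozen=True)
class GlcmMoments:
    """Marginal means and standard deviations of a GLCM."""

    mu_i: float
    mu_j: float
    sigma_i: float
    sigma_j: float


def quantize(gs: np.ndarray, levels: int = 8, mode: str = "fixed_range") -> np.ndarray:
    """Quantize an 8-bit grayscale image to ``levels`` brightness classes.

    ``fixed_range`` (default): level = floor(pixel * levels / 256) + 1,
    i.e. equal-width bins over [0, 255]; pixel 255 maps to the top level.
    ``min_max``: equal-width bins over the image's own [min, max] range.
    Returns an integer grid with values in 1..levels.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    gs = np.asarray(gs)
    if mode == "fixed_range":
        q = (gs.astype(np.int64) * levels) // 256 + 1
    elif mode == "min_max":
        lo = int(gs.min())
        hi = int(gs.max())
        width = (hi - lo + 1) / levels
        q = np.minimum((gs.astype(np.float64) - lo) / width, levels - 1).astype(np.int64) + 1
    else:
        raise ValueError(f"unknown quantization mode {mode!r}")
    return q


def build_glcm(q: np.ndarray, direction: int, levels: int | None = None) -> Glcm:
    """Build the symmetric GLCM of a quantized grid for one direction.

    For every pixel with an in-bounds 1-pixel neighbour at the direction's
    offset, the level pair (a, b) increments both ``raw_counts[a, b]`` and
    ``raw_counts[b, a]``; probabilities are the counts normalised to sum 1.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}, got {direction}")
    q = np.asarray(q, dtype=np.int64)
    if q.ndim != 2:
        raise ValueError(f"expected a 2-D quantized grid, got shape {q.shape}")
    if levels is None:
        levels = max(8, int(q.max()))
    dr, dc = DIRECTIONS[direction]
    h, w = q.shape
    # slices selecting all in-bounds (pixel, neighbour) pairs at once
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    if a.size == 0:
        raise ValueError(
            f"grid of shape {q.shape} has no neighbour pair in direction {direction}"
        )
    flat = (a.ravel() - 1) * levels + (b.ravel() - 1)
    counts = np.bincount(flat, minlength=levels * levels).reshape(levels, levels)
    counts = counts + counts.T  # symmetric accumulation
    total = counts.sum()
    return Glcm(p=counts / total, raw_counts=counts, direction=direction)


def glcm_moments(g: Glcm) -> GlcmMoments:
    """Marginal means and standard deviations of a normalised GLCM."""
    levels = g.levels
    i = np.arange(1, levels + 1)
    pi = g.p.sum(axis=1)  # row marginal
    pj = g.p.sum(axis=0)  # column marginal
    mu_i = float(i @ pi)
    mu_j = float(i @ pj)
    sigma_i = float(np.sqrt((i - mu_i) ** 2 @ pi))
    sigma_j = float(np.sqrt((i - mu_j) ** 2 @ pj))
    return GlcmMoments(mu_i=mu_i, mu_j=mu_j, sigma_i=sigma_i, sigma_j=sigma_j)


def _index_grids(levels: int) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(1, levels + 1)
    return np.meshgrid(i, i, indexing="ij")


def glcm_contrast(g: Glcm) -> float:
    """Sum of (i - j)^2 p(i, j); 0 for a diagonal matrix, at most (L-1)^2."""
    ii, jj = _index_grids(g.levels)
    return float(((ii - jj) ** 2 * g.p).sum())


def glcm_correlation(g: Glcm) -> float:
    """GLCM correlation in [-1, 1]; NaN when a marginal deviation is zero.

    A single-level (constant) region has sigma_i = sigma_j = 0 and its
    correlation is undefined; the undefined case is returned as NaN rather
    than silently coerced to 0 or 1.
    """
    m = glcm_moments(g)
    denom = m.sigma_i * m.sigma_j
    if denom == 0.0:
        return float("nan")
    ii, jj = _index_grids(g.levels)
    cov = ((ii - m.mu_i) * (jj - m.mu_j) * g.p).sum()
    return float(cov / denom)


def glcm_energy(g: Glcm) -> float:
    """Sum of squared probabilities (angular second moment), in (0, 1]."""
    return float((g.p**2).sum())


def glcm_homogeneity(g: Glcm) -> float:
    """Sum of p(i, j) / (1 + |i - j|), in (0, 1].

    The absolute value in the denominator is the standard (inverse
    difference) definition; a signed difference would be non-computable for
    symmetric matrices (zero denominator at j = i + 1).
    """
    ii, jj = _index_grids(g.levels)
    return float((g.p / (1.0 + np.abs(ii - jj))).sum())


def gray_entropy(gs: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin brightness histogram, in [0, 8].

    Bin proportions are the fraction of pixels at each brightness 0..255,
    with 0 * log2(0) taken as 0.
    """
    gs = np.asarray(gs)
    counts = np.bincount(gs.ravel().astype(np.int64), minlength=256)
    return float(_shannon_entropy(counts, base=2))


def texture_vector(
    gs: np.ndarray,
    levels: int = 8,
    quantization: str = "fixed_range",
) -> dict[str, float]:
    """The five texture parameters of one grayscale image.

    CONTRAST, CORRELATION, ENERGY and HOMOGENEITY are computed for each of
    the four direction GLCMs individually and then arithmetically averaged
    (per-direction-then-average, not pooling of matrices). Directions where
    CORRELATION is undefined are skipped in its average; if it is undefined
    in all four directions the result is NaN.
    """
    gs = np.asarray(gs)
    if gs.ndim != 2 or gs.shape[0] < 2 or gs.shape[1] < 2:
        raise ValueError(f"grayscale image must be at least 2 x 2, got shape {gs.shape}")
    q = quantize(gs, levels=levels, mode=quantization)
    contrast, energy, homogeneity, correlation = [], [], [], []
    for direction in DIRECTIONS:
        g = build_glcm(q, direction, levels=levels)
        contrast.append(glcm_contrast(g))
        energy.append(glcm_energy(g))
        homogeneity.append(glcm_homogeneity(g))
        corr = glcm_correlation(g)
        if not np.isnan(corr):
            correlation.append(corr)
    return {
        "ENTROPY": gray_entropy(gs),
        "CONTRAST": float(np.mean(contrast)),
        "CORRELATION": float(np.mean(correlation)) if correlation else float("nan"),
        "ENERGY": float(np.mean(energy)),
        "HOMOGENEITY": float(np.mean(homogeneity)),
    }
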