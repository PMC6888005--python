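"""GLCM construction and texture statistics against independent oracles."""

import numpy as np
import pytest

import compostvision as cv
from compostvision.texture import DIRECTIONS, glcm_moments

# ---------------------------------------------------------------------------
# independent brute-force oracles (double loops, written before the
# vectorized implementation)
# ---------------------------------------------------------------------------


def glcm_counts_oracle(q, direction, levels=8):
    dr, dc = DIRECTIONS[direction]
    h, w = q.shape
    counts = np.zeros((levels, levels), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[q[r, c] - 1, q[r2, c2] - 1] += 1
                counts[q[r2, c2] - 1, q[r, c] - 1] += 1
    return counts


def stats_oracle(p):
    L = p.shape[0]
    mu_i = sum((i + 1) * p[i, j] for i in range(L) for j in range(L))
    mu_j = sum((j + 1) * p[i, j] for i in range(L) for j in range(L))
    var_i = sum((i + 1 - mu_i) ** 2 * p[i, j] for i in range(L) for j in range(L))
    var_j = sum((j + 1 - mu_j) ** 2 * p[i, j] for i in range(L) for j in range(L))
    contrast = sum((i - j) ** 2 * p[i, j] for i in range(L) for j in range(L))
    energy = sum(p[i, j] ** 2 for i in range(L) for j in range(L))
    homog = sum(p[i, j] / (1 + abs(i - j)) for i in range(L) for j in range(L))
    denom = np.sqrt(var_i) * np.sqrt(var_j)
    if denom == 0:
        corr = float("nan")
    else:
        corr = (
            sum((i + 1 - mu_i) * (j + 1 - mu_j) * p[i, j] for i in range(L) for j in range(L))
            / denom
        )
    return contrast, corr, energy, homog


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "pixel, level", [(0, 1), (31, 1), (32, 2), (127, 4), (128, 5), (254, 8), (255, 8)]
)
def test_quantize_fixed_range_bin_edges(pixel, level):
    q = cv.quantize(np.full((2, 2), pixel, np.uint8))
    assert (q == level).all()


def test_quantize_validation_and_constant():
    with pytest.raises(ValueError):
        cv.quantize(np.zeros((2, 2), np.uint8), levels=1)
    assert len(np.unique(cv.quantize(np.full((3, 3), 77, np.uint8)))) == 1


def test_quantize_min_max_stretches_per_image():
    gs = np.linspace(10, 50, 36).astype(np.uint8).reshape(6, 6)
    q_fixed = cv.quantize(gs, mode="fixed_range")
    q_mm = cv.quantize(gs, mode="min_max")
    assert q_fixed.max() <= 2  # values 10..50 occupy the two darkest fixed bins
    assert q_mm.min() == 1 and q_mm.max() == 8  # min-max uses the full level range
    assert (cv.quantize(np.full((3, 3), 9, np.uint8), mode="min_max") == 1).all()


# ---------------------------------------------------------------------------
# GLCM construction
# ---------------------------------------------------------------------------


def test_build_glcm_two_row_example():
    q = np.array([[1, 1], [8, 8]])
    g = cv.build_glcm(q, 0)
    expected = np.zeros((8, 8))
    expected[0, 0] = expected[7, 7] = 0.5
    np.testing.assert_allclose(g.p, expected)
    assert g.raw_counts.sum() == 4  # two horizontal pairs, doubled


def test_build_glcm_degenerate_grid_errors():
    with pytest.raises(ValueError):
        cv.build_glcm(np.array([[1]]), 0)
    with pytest.raises(ValueError):
        cv.build_glcm(np.array([[1, 2]]), 90)  # single row has no vertical pair
    with pytest.raises(ValueError):
        cv.build_glcm(np.array([[1, 2], [3, 4]]), 30)  # not a supported direction


def test_glcm_matches_bruteforce_and_skimage_on_random_grids():
    """Counts, normalisation, symmetry and pair totals on seeded random grids."""
    from skimage.feature import graycomatrix

    rng = np.random.default_rng(11)
    for _ in range(30):
        h, w = rng.integers(2, 13, size=2)
        gs = rng.integers(0, 256, size=(h, w), dtype=np.uint8)
        q = cv.quantize(gs)
        for direction in DIRECTIONS:
            g = cv.build_glcm(q, direction)
            oracle = glcm_counts_oracle(q, direction)
            np.testing.assert_array_equal(g.raw_counts, oracle)
            np.testing.assert_array_equal(g.raw_counts, g.raw_counts.T)
            assert abs(g.p.sum() - 1.0) < 1e-12
            # raw total = 2 x number of in-bounds pairs
            dr, dc = DIRECTIONS[direction]
            n_pairs = (h - abs(dr)) * (w - abs(dc))
            assert g.raw_counts.sum() == 2 * n_pairs
        # independent library cross-check; skimage measures angles with rows
        # increasing downward, so its pi/4 is our 135-degree offset and vice
        # versa (symmetric matrices make the sign of the offset irrelevant)
        sk = graycomatrix(
            (q - 1).astype(np.uint8),
            distances=[1],
            angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
            levels=8,
            symmetric=True,
        )
        for a_idx, direction in enumerate((0, 135, 90, 45)):
            np.testing.assert_array_equal(
                cv.build_glcm(q, direction).raw_counts, sk[:, :, 0, a_idx]
            )


def test_glcm_statistics_match_oracle_on_random_grids():
    rng = np.random.default_rng(5)
    for _ in range(30):
        h, w = rng.integers(2, 13, size=2)
        q = cv.quantize(rng.integers(0, 256, size=(h, w), dtype=np.uint8))
        for direction in DIRECTIONS:
            g = cv.build_glcm(q, direction)
            contrast, corr, energy, homog = stats_oracle(g.p)
            assert cv.glcm_contrast(g) == pytest.approx(contrast, abs=1e-12)
            assert cv.glcm_energy(g) == pytest.approx(energy, abs=1e-12)
            assert cv.glcm_homogeneity(g) == pytest.approx(homog, abs=1e-12)
            got = cv.glcm_correlation(g)
            if np.isnan(corr):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(corr, abs=1e-12)
            # range assertions
            assert 0.0 <= cv.glcm_contrast(g) <= 49.0
            assert 0.0 < cv.glcm_energy(g) <= 1.0
            assert 0.0 < cv.glcm_homogeneity(g) <= 1.0
            if not np.isnan(got):
                assert -1.0 - 1e-12 <= got <= 1.0 + 1e-12


def test_checkerboard_analytic_values():
    idx = np.indices((6, 6)).sum(axis=0) % 2
    gs = (idx * 255).astype(np.uint8)
    g = cv.build_glcm(cv.quantize(gs), 0)
    assert cv.glcm_contrast(g) == pytest.approx(49.0, abs=1e-12)
    assert cv.glcm_energy(g) == pytest.approx(0.5, abs=1e-12)
    assert cv.glcm_homogeneity(g) == pytest.approx(0.125, abs=1e-12)
    assert cv.glcm_correlation(g) == pytest.approx(-1.0, abs=1e-12)


def test_constant_and_perfectly_correlated_limits():
    const = np.full((5, 5), 80, np.uint8)
    g = cv.build_glcm(cv.quantize(const), 45)
    assert cv.glcm_contrast(g) == 0.0
    assert cv.glcm_energy(g) == 1.0
    assert cv.glcm_homogeneity(g) == 1.0
    assert np.isnan(cv.glcm_correlation(g))

    # rows of constant brightness: all horizontal pairs sit on the diagonal
    rows = np.repeat(np.array([[0], [100], [200]], np.uint8), 4, axis=1)
    g = cv.build_glcm(cv.quantize(rows), 0)
    assert cv.glcm_correlation(g) == pytest.approx(1.0, abs=1e-12)

    uniform = cv.Glcm(p=np.full((8, 8), 1 / 64), raw_counts=np.ones((8, 8), int), direction=0)
    assert cv.glcm_energy(uniform) == pytest.approx(1 / 64, abs=1e-15)


def test_moments_symmetric_glcm():
    rng = np.random.default_rng(2)
    q = cv.quantize(rng.integers(0, 256, size=(7, 9), dtype=np.uint8))
    for direction in DIRECTIONS:
        m = glcm_moments(cv.build_glcm(q, direction))
        assert 1.0 <= m.mu_i <= 8.0
        assert m.mu_i == pytest.approx(m.mu_j, abs=1e-12)
        assert m.sigma_i == pytest.approx(m.sigma_j, abs=1e-12)


# ---------------------------------------------------------------------------
# entropy and the averaged texture vector
# ---------------------------------------------------------------------------


def test_gray_entropy_limits():
    assert cv.gray_entropy(np.full((4, 4), 9, np.uint8)) == 0.0
    halves = np.concatenate([np.zeros((2, 4), np.uint8), np.full((2, 4), 200, np.uint8)])
    assert cv.gray_entropy(halves) == pytest.approx(1.0, abs=1e-12)
    all_vals = np.repeat(np.arange(256, dtype=np.uint8), 4).reshape(32, 32)
    assert cv.gray_entropy(all_vals) == pytest.approx(8.0, abs=1e-12)


def test_texture_vector_composes_per_direction_then_averages():
    rng = np.random.default_rng(17)
    gs = rng.integers(0, 256, size=(10, 12), dtype=np.uint8)
    vec = cv.texture_vector(gs)
    q = cv.quantize(gs)
    per_dir = {
        name: [] for name in ("CONTRAST", "CORRELATION", "ENERGY", "HOMOGENEITY")
    }
    for direction in DIRECTIONS:
        g = cv.build_glcm(q, direction)
        per_dir["CONTRAST"].append(cv.glcm_contrast(g))
        per_dir["CORRELATION"].append(cv.glcm_correlation(g))
        per_dir["ENERGY"].append(cv.glcm_energy(g))
        per_dir["HOMOGENEITY"].append(cv.glcm_homogeneity(g))
    assert vec["ENTROPY"] == cv.gray_entropy(gs)
    for name, vals in per_dir.items():
        assert vec[name] == pytest.approx(np.mean(vals), abs=1e-12)
    # averaging scalars per direction is not the same as pooling matrices
    pooled = sum(cv.build_glcm(q, d).raw_counts for d in DIRECTIONS)
    pooled_energy = ((pooled / pooled.sum()) ** 2).sum()
    assert vec["ENERGY"] != pytest.approx(pooled_energy, abs=1e-6)


def test_texture_vector_constant_image_limits():
    vec = cv.texture_vector(np.full((4, 4), 33, np.uint8))
    assert vec["ENTROPY"] == 0.0
    assert vec["CONTRAST"] == 0.0
    assert np.isnan(vec["CORRELATION"])
    assert vec["ENERGY"] == 1.0
    assert vec["HOMOGENEITY"] == 1.0


def test_rotating_image_permutes_directions_and_preserves_average():
    rng = np.random.default_rng(23)
    gs = rng.integers(0, 256, size=(9, 13), dtype=np.uint8)
    rot = np.rot90(gs)
    q, q_rot = cv.quantize(gs), cv.quantize(rot)
    pairing = {0: 90, 90: 0, 45: 135, 135: 45}
    for d, d_rot in pairing.items():
        np.testing.assert_array_equal(
            cv.build_glcm(q, d).raw_counts, cv.build_glcm(q_rot, d_rot).raw_counts
        )
    vec, vec_rot = cv.texture_vector(gs), cv.texture_vector(rot)
    for name in ("CONTRAST", "CORRELATION", "ENERGY", "HOMOGENEITY"):
        assert vec[name] == pytest.approx(vec_rot[name], abs=1e-12)
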