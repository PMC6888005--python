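"""Seeded synthetic compost-sample images for the two composting classes.

Real photographs of the composted material are not publicly deposited, so
this module generates images with the statistical structure the analysis
assumes: a dark, spatially correlated matrix (smoothed Gaussian noise,
channels coupled through a shared luminance field) overlaid with bright,
elongated straw-like streaks whose density differs by class. Default
channel means are the published per-class group averages; streak and noise
defaults were calibrated analytically (censored-normal tail probabilities
plus Boolean-model streak coverage) so that the white-percentage group
means land near the published values.

The generator is exactly mean-calibrated: ``channel_means`` is the expected
mean of the *final composite* image. The base level is offset for the
expected streak coverage ``1 - exp(-density * E[length] * E[width] / 1e4)``
(exact for Poisson-placed streaks wrapped toroidally, since a uniformly
translated shape on a torus covers pixel centres with probability equal to
its area fraction) and for truncation at brightness 0.
"""

from __future__ import annotations

import math
import os
from dataclasses import asdict, dataclass

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.stats import norm

from .io import RgbImage, write_group_assignment


@dataclass(frozen=True)
class ClassSpec:
    """Generating parameters of one image class.

    channel_means/channel_sds are the target per-channel mean and pixel
    standard deviation (8-bit scale) of the composite image;
    smoothing_scale is the Gaussian kernel sigma (pixels) controlling
    spatial autocorrelation; streak_density is the expected number of
    straw streaks per 10^4 pixels; streak geometry ranges are inclusive
    pixel ranges; channel_correlation couples the R/G/B noise fields
    through a shared luminance field.
    """

    label: str
    channel_means: tuple[float, float, float]
    channel_sds: tuple[float, float, float]
    smoothing_scale: float = 3.0
    streak_density: float = 0.0
    streak_brightness: tuple[float, float, float] = (150.0, 135.0, 90.0)
    streak_length_range: tuple[int, int] = (20, 60)
    streak_width_range: tuple[int, int] = (2, 5)
    channel_correlation: float = 0.85
    streak_noise_sd: float = 6.0

    def __post_init__(self) -> None:
        for m, s in zip(self.channel_means, self.channel_sds):
            if s < 0:
                raise ValueError("channel_sds must be non-negative")
            if m + 3 * s > 255:
                raise ValueError(
                    f"channel mean {m} + 3 sd {s} exceeds 255; clamping would bias"
                )
        if self.streak_density < 0:
            raise ValueError("streak_density must be non-negative")
        if not 0 <= self.channel_correlation <= 1:
            raise ValueError("channel_correlation must be in [0, 1]")
        for lo, hi in (self.streak_length_range, self.streak_width_range):
            if lo < 1 or hi < lo:
                raise ValueError("streak ranges must be positive and ordered")

    @property
    def expected_streak_coverage(self) -> float:
        """Expected fraction of pixels covered by at least one streak."""
        mean_area = (
            (self.streak_length_range[0] + self.streak_length_range[1])
            / 2.0
            * (self.streak_width_range[0] + self.streak_width_range[1])
            / 2.0
        )
        return 1.0 - math.exp(-self.streak_density * mean_area / 1e4)


#: Default class specifications. Channel means are the published per-class
#: group averages; SDs, streak density and geometry come from the one-time
#: analytic calibration described in the module docstring.
FAVORABLE = ClassSpec(
    label="favorable",
    channel_means=(24.86, 19.62, 15.43),
    channel_sds=(12.0, 9.0, 7.0),
    streak_density=2.1,
)

UNFAVORABLE = ClassSpec(
    label="unfavorable",
    channel_means=(42.26, 30.39, 20.99),
    channel_sds=(14.0, 11.0, 8.0),
    streak_density=5.7,
)


def _uncensored_level(target: float, sd: float) -> float:
    """Pre-clamp Gaussian mean whose zero-censored expectation is ``target``.

    Solves m * Phi(m/sd) + sd * phi(m/sd) = target for m; the upper clamp at
    255 is ignored (negligible for dark-matrix levels).
    """
    if sd == 0 or target > 8 * sd:
        return target

    def censored_mean(m: float) -> float:
        a = m / sd
        return m * norm.cdf(a) + sd * norm.pdf(a)

    lo = target - 6 * sd - 1.0
    return float(brentq(lambda m: censored_mean(m) - target, lo, target + 1e-9))


def _smooth_field(rng: np.random.Generator, height: int, width: int, scale: float) -> np.ndarray:
    """Standardised (sample mean 0, sd 1) smoothed Gaussian noise field."""
    z = rng.standard_normal((height, width))
    if scale > 0:
        z = gaussian_filter(z, sigma=scale, mode="reflect")
    z = z - z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def _streak_mask_indices(
    rng: np.random.Generator, spec: ClassSpec, height: int, width: int
) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of all pixels covered by the sampled streaks.

    Streak rectangles have uniformly random continuous centre, orientation
    in [0, pi), integer length and width from the spec ranges, and wrap
    around the image edges (toroidal placement keeps the expected covered
    area exactly length * width regardless of position).
    """
    lam = spec.streak_density * height * width / 1e4
    n_streaks = int(rng.poisson(lam))
    rows, cols = [], []
    lmin, lmax = spec.streak_length_range
    wmin, wmax = spec.streak_width_range
    for _ in range(n_streaks):
        cy = rng.uniform(0, height)
        cx = rng.uniform(0, width)
        theta = rng.uniform(0, math.pi)
        length = int(rng.integers(lmin, lmax + 1))
        wid = int(rng.integers(wmin, wmax + 1))
        half_diag = (length + wid) / 2.0 + 1.0
        r = np.arange(math.floor(cy - half_diag), math.ceil(cy + half_diag) + 1)
        c = np.arange(math.floor(cx - half_diag), math.ceil(cx + half_diag) + 1)
        rr, cc = np.meshgrid(r, c, indexing="ij")
        dy = rr - cy
        dx = cc - cx
        along = dx * math.cos(theta) + dy * math.sin(theta)
        across = -dx * math.sin(theta) + dy * math.cos(theta)
        inside = (np.abs(along) <= length / 2.0) & (np.abs(across) <= wid / 2.0)
        rows.append(np.mod(rr[inside], height))
        cols.append(np.mod(cc[inside], width))
    if not rows:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    return (
        np.concatenate(rows).astype(np.intp),
        np.concatenate(cols).astype(np.intp),
    )


def generate_image(
    spec: ClassSpec, height: int, width: int, seed: int | np.random.SeedSequence
) -> RgbImage:
    """Generate one synthetic sample image.

    The composite is (1) a spatially correlated Gaussian matrix per channel
    (shared luminance field weighted by ``channel_correlation``), level-
    offset so the censored, streak-covered composite has expected channel
    means equal to ``spec.channel_means``; (2) Poisson-placed bright streak
    rectangles painted at ``streak_brightness`` plus zero-mean luminance
    noise; (3) clamping to [0, 255] and rounding. Identical (spec,
    dimensions, seed) gives bit-identical output.
    """
    if height < 16 or width < 16:
        raise ValueError(f"image dimensions must be >= 16, got {height} x {width}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    p_cov = spec.expected_streak_coverage
    rho = spec.channel_correlation
    common = _smooth_field(rng, height, width, spec.smoothing_scale)
    img = np.empty((height, width, 3), dtype=np.float64)
    for k in range(3):
        own = _smooth_field(rng, height, width, spec.smoothing_scale)
        z = rho * common + math.sqrt(1.0 - rho * rho) * own
        z = z - z.mean()
        zsd = z.std()
        if zsd > 0:
            z = z / zsd
        base_target = (spec.channel_means[k] - p_cov * spec.streak_brightness[k]) / (
            1.0 - p_cov
        )
        level = _uncensored_level(base_target, spec.channel_sds[k])
        img[:, :, k] = level + spec.channel_sds[k] * z

    rows, cols = _streak_mask_indices(rng, spec, height, width)
    if rows.size:
        lum_noise = rng.normal(0.0, spec.streak_noise_sd, size=rows.size)
        for k in range(3):
            img[rows, cols, k] = spec.streak_brightness[k] + lum_noise

    pixels = np.floor(np.clip(img, 0.0, 255.0) + 0.5).astype(np.uint8)
    return RgbImage(pixels=pixels, source_id=f"synthetic_{spec.label}")


def study_seed(master_seed: int, experiment_index: int, image_index: int) -> np.random.SeedSequence:
    """Splittable per-image seed: SeedSequence keyed by the study position."""
    return np.random.SeedSequence([int(master_seed), experiment_index, image_index])


def iter_study_images(
    fav_spec: ClassSpec = FAVORABLE,
    unfav_spec: ClassSpec = UNFAVORABLE,
    images_per_experiment: int = 32,
    fav_experiments: int = 3,
    unfav_experiments: int = 7,
    seed: int = 0,
    height: int = 648,
    width: int = 968,
):
    """Yield ``(experiment_id, source_id, RgbImage)`` for a full study.

    Experiments are named ``fav_01..`` / ``unf_01..``; sub-seeds derive from
    the master seed and the (experiment, image) position, so any subset is
    reproducible independently.
    """
    if images_per_experiment < 1 or fav_experiments < 1 or unfav_experiments < 1:
        raise ValueError("experiment and image counts must be >= 1")
    plan = [(f"fav_{i + 1:02d}", fav_spec) for i in range(fav_experiments)]
    plan += [(f"unf_{i + 1:02d}", unfav_spec) for i in range(unfav_experiments)]
    for e_idx, (exp_id, spec) in enumerate(plan):
        for i_idx in range(images_per_experiment):
            img = generate_image(spec, height, width, study_seed(seed, e_idx, i_idx))
            source_id = f"sample_{i_idx:03d}"
            yield exp_id, source_id, replace_ids(img, exp_id, source_id)


def replace_ids(img: RgbImage, experiment_id: str, source_id: str) -> RgbImage:
    return RgbImage(pixels=img.pixels, source_id=source_id, experiment_id=experiment_id)


def study_group_assignment(fav_experiments: int = 3, unfav_experiments: int = 7) -> dict[str, str]:
    groups = {f"fav_{i + 1:02d}": "favorable" for i in range(fav_experiments)}
    groups.update({f"unf_{i + 1:02d}": "unfavorable" for i in range(unfav_experiments)})
    return groups


def _spec_dict(spec: ClassSpec) -> dict:
    """ClassSpec as plain YAML-serialisable types (tuples become lists)."""
    return {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(spec).items()}


def generate_study(
    out_dir: str | os.PathLike,
    fav_spec: ClassSpec = FAVORABLE,
    unfav_spec: ClassSpec = UNFAVORABLE,
    images_per_experiment: int = 32,
    fav_experiments: int = 3,
    unfav_experiments: int = 7,
    seed: int = 0,
    height: int = 648,
    width: int = 968,
) -> dict[str, str]:
    """Write a full synthetic study to disk and return its group assignment.

    Creates one PNG directory per experiment under ``out_dir`` plus
    ``groups.csv`` and ``generator.yaml`` (the resolved generating
    parameters). The same master seed always produces an identical tree.
    """
    import imageio.v3 as iio

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    for exp_id, source_id, img in iter_study_images(
        fav_spec,
        unfav_spec,
        images_per_experiment,
        fav_experiments,
        unfav_experiments,
        seed,
        height,
        width,
    ):
        exp_dir = os.path.join(out_dir, exp_id)
        os.makedirs(exp_dir, exist_ok=True)
        iio.imwrite(os.path.join(exp_dir, f"{source_id}.png"), img.pixels)
    groups = study_group_assignment(fav_experiments, unfav_experiments)
    write_group_assignment(groups, os.path.join(out_dir, "groups.csv"))
    config = {
        "seed": int(seed),
        "height": height,
        "width": width,
        "images_per_experiment": images_per_experiment,
        "favorable_spec": _spec_dict(fav_spec),
        "unfavorable_spec": _spec_dict(unfav_spec),
    }
    with open(os.path.join(out_dir, "generator.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return groups
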