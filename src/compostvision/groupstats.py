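"""Group-level comparison of favorable vs unfavorable composting conditions.

Per-image feature vectors are aggregated into per-parameter group means and
sample standard deviations (the image is the unit of analysis), differences
are tested with the two-sided Mann-Whitney U test, and the absolute
percentage difference of the unfavorable group relative to the favorable
group is summarised by threshold counts (how many of the 17 parameters
differ by more than 10%, 50%, 100%).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .io import GROUP_LABELS, PARAMETER_ORDER, validate_feature_table

#: Pooled-sample-size limit below or at which the exact U distribution is
#: enumerated; above it the tie- and continuity-corrected normal
#: approximation is used.
EXACT_LIMIT = 20

DEFAULT_THRESHOLDS = (10.0, 50.0, 100.0)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero (display convention for percentages)."""
    x = float(x)
    if math.isnan(x):
        return float("nan")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct_diff(mean_fav: float, mean_unfav: float) -> float:
    """Absolute percentage difference relative to the favorable mean.

    ``100 * |mean_unfav - mean_fav| / mean_fav``; NaN when the favorable
    mean is zero (the difference is then not expressible as a percentage).
    """
    if mean_fav == 0 or math.isnan(mean_fav) or math.isnan(mean_unfav):
        return float("nan")
    return 100.0 * abs(mean_unfav - mean_fav) / abs(mean_fav)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _u_statistics(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    nx, ny = len(x), len(y)
    ranks = rankdata(np.concatenate([x, y]))  # mid-ranks for ties
    ux = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    uy = nx * ny - ux
    return ux, uy


def _exact_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """P(min(Ux, Uy) <= observed) over all label assignments (exact, ties OK)."""
    nx, ny = len(x), len(y)
    n = nx + ny
    ranks = rankdata(np.concatenate([x, y]))
    offset = nx * (nx + 1) / 2.0
    combs = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), nx)),
        dtype=np.intp,
    ).reshape(-1, nx)
    ux = ranks[combs].sum(axis=1) - offset
    u_min = np.minimum(ux, nx * ny - ux)
    return float(np.mean(u_min <= u_obs + 1e-9))


def _asymptotic_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    nx, ny = len(x), len(y)
    n = nx + ny
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all pooled values identical
        return 1.0
    mu = nx * ny / 2.0
    z = (u_obs - mu + 0.5) / math.sqrt(sigma2)  # continuity correction
    return float(min(1.0, 2.0 * norm.cdf(z)))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U = min(Ux, Uy) from mid-rank assignment. For
    pooled sample sizes up to :data:`EXACT_LIMIT` the p-value is exact: the
    probability, over all label assignments of the pooled values, that the
    permuted min-U is at most the observed one (this handles ties and
    reduces to the classical two-sided exact p for untied data). For larger
    samples the normal approximation with tie correction and continuity
    correction is used.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ux, uy = _u_statistics(x, y)
    u = min(ux, uy)
    if x.size + y.size <= EXACT_LIMIT:
        p = _exact_p(x, y, u)
    else:
        p = _asymptotic_p(x, y, u)
    return float(u), p


# ---------------------------------------------------------------------------
# group summary
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """Per-parameter group statistics of a favorable/unfavorable comparison.

    ``table`` is indexed by parameter name (in canonical order) with columns
    ``mean_fav, sd_fav, mean_unfav, sd_unfav, p_value, pct_diff``.
    """

    table: pd.DataFrame
    n_fav: int
    n_unfav: int
    alpha: float = 0.05
    config: dict = field(default_factory=dict)

    @property
    def parameters(self) -> list[str]:
        return list(self.table.index)

    def threshold_counts(self, thresholds: Iterable[float] = DEFAULT_THRESHOLDS) -> list[int]:
        return threshold_counts(self, thresholds)

    def significant(self) -> pd.Series:
        """Boolean per parameter: p-value below the significance level."""
        return self.table["p_value"] < self.alpha

    def summary(self) -> str:
        """Plain-text table of means, SDs, p-values and percentage differences."""
        lines = [
            f"Group comparison: favorable n={self.n_fav}, unfavorable n={self.n_unfav}, "
            f"alpha={self.alpha}",
            "",
            f"{'Parameter':<13}{'Fav mean':>10}{'Fav SD':>8}{'Unf mean':>10}"
            f"{'Unf SD':>8}{'p-value':>9}{'diff %':>7}",
        ]
        for name, row in self.table.iterrows():
            p = row["p_value"]
            p_str = "<0.001" if p < 0.001 else f"{p:.3f}"
            d = row["pct_diff"]
            d_str = "-" if math.isnan(d) else f"{round_half_up(d):.0f}"
            lines.append(
                f"{name:<13}{row['mean_fav']:>10.2f}{row['sd_fav']:>8.2f}"
                f"{row['mean_unfav']:>10.2f}{row['sd_unfav']:>8.2f}{p_str:>9}{d_str:>7}"
            )
        counts = self.threshold_counts()
        lines.append("")
        lines.append(
            "Parameters with |difference| > 10% / 50% / 100%: "
            f"{counts[0]} / {counts[1]} / {counts[2]}"
        )
        return "\n".join(lines)

    def to_report_dict(self) -> dict:
        return render_report(self)

    def to_json(self, path=None, **kwargs) -> str:
        doc = json.dumps(self.to_report_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(doc + "\n")
        return doc

    def plot_pct_diff(self, ax=None):
        """Bar chart of absolute percentage differences, largest first."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        vals = self.table["pct_diff"].sort_values(ascending=False)
        ax.bar(vals.index, vals.values)
        ax.set_ylabel("absolute difference (%)")
        ax.tick_params(axis="x", rotation=90)
        return ax


def summarize_groups(
    table: pd.DataFrame,
    groups: Mapping[str, str],
    alpha: float = 0.05,
    parameters: Sequence[str] = PARAMETER_ORDER,
) -> GroupComparison:
    """Aggregate a feature table into a favorable/unfavorable comparison.

    Means and sample standard deviations (n-1 denominator) are taken over
    all images in each group; every experiment in the table must appear in
    ``groups`` and each group must contribute at least 2 images.
    """
    table = validate_feature_table(table)
    unknown = sorted(set(table["experiment_id"]) - set(groups))
    if unknown:
        raise ValueError(f"experiments without a group label: {unknown}")
    bad = sorted(set(groups.values()) - set(GROUP_LABELS))
    if bad:
        raise ValueError(f"unknown group labels: {bad}")
    labels = table["experiment_id"].map(groups)
    fav = table[labels == "favorable"]
    unfav = table[labels == "unfavorable"]
    for name, grp in (("favorable", fav), ("unfavorable", unfav)):
        if len(grp) < 2:
            raise ValueError(f"group {name!r} has {len(grp)} images; need >= 2")
    rows = {}
    for param in parameters:
        xf = fav[param].to_numpy(dtype=np.float64)
        xu = unfav[param].to_numpy(dtype=np.float64)
        mean_fav, mean_unfav = float(xf.mean()), float(xu.mean())
        _, p = mann_whitney_u(xf, xu)
        rows[param] = {
            "mean_fav": mean_fav,
            "sd_fav": float(xf.std(ddof=1)),
            "mean_unfav": mean_unfav,
            "sd_unfav": float(xu.std(ddof=1)),
            "p_value": p,
            "pct_diff": pct_diff(mean_fav, mean_unfav),
        }
    frame = pd.DataFrame.from_dict(rows, orient="index").loc[list(parameters)]
    return GroupComparison(table=frame, n_fav=len(fav), n_unfav=len(unfav), alpha=alpha)


def threshold_counts(
    comparison: GroupComparison, thresholds: Iterable[float] = DEFAULT_THRESHOLDS
) -> list[int]:
    """Number of parameters whose percentage difference exceeds each threshold."""
    diffs = comparison.table["pct_diff"].to_numpy(dtype=np.float64)
    return [int(np.nansum(diffs > t)) for t in thresholds]


def render_report(comparison: GroupComparison) -> dict:
    """Machine-readable report: full-precision and display-rounded values.

    Display rounding follows the publication convention: means and SDs to 2
    decimals, percentage differences to the nearest integer (half up).
    """
    if len(comparison.table) == 0:
        raise ValueError("comparison covers no parameters")
    params = {}
    for name, row in comparison.table.iterrows():
        d = row["pct_diff"]
        params[name] = {
            "mean_fav": row["mean_fav"],
            "sd_fav": row["sd_fav"],
            "mean_unfav": row["mean_unfav"],
            "sd_unfav": row["sd_unfav"],
            "p_value": row["p_value"],
            "pct_diff": None if math.isnan(d) else d,
            "display": {
                "mean_fav": round_half_up(row["mean_fav"], 2),
                "mean_unfav": round_half_up(row["mean_unfav"], 2),
                "sd_fav": round_half_up(row["sd_fav"], 2),
                "sd_unfav": round_half_up(row["sd_unfav"], 2),
                "pct_diff": None if math.isnan(d) else int(round_half_up(d)),
            },
        }
    counts = comparison.threshold_counts()
    return {
        "n_fav": comparison.n_fav,
        "n_unfav": comparison.n_unfav,
        "alpha": comparison.alpha,
        "parameters": params,
        "threshold_counts": {
            "10%": counts[0],
            "50%": counts[1],
            "100%": counts[2],
        },
        "config": comparison.config,
    }
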