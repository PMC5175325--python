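"""Cross-index association: R-squared and the empty-corner diagnostic.

Two indices are compared on the countries they share through (i) the
coefficient of determination between posterior-mean scores and (ii) a
corner-occupancy count operationalising the visual "empty upper-left
triangle" reading of a scatter plot — the number of countries that score
low on one index (below its x-quantile) yet high on the other (above its
y-quantile).  An empty corner is the observable footprint of a
necessary-condition relationship between the two dimensions of regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def r_squared(x_scores: np.ndarray, y_scores: np.ndarray) -> float:
    """Squared Pearson correlation of paired scores."""
    x = np.asarray(x_scores, float)
    y = np.asarray(y_scores, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x_scores and y_scores must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 paired scores, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("x_scores are constant; R^2 undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def corner_occupancy(
    x_scores: np.ndarray,
    y_scores: np.ndarray,
    x_quantile: float = 0.25,
    y_quantile: float = 0.75,
) -> int:
    """Countries strictly below the x-quantile of x and above the y-quantile of y.

    Zero occupancy of this low-x/high-y rectangle is evidence that high x is
    necessary for high y.  Strict inequalities against linearly interpolated
    sample quantiles keep the count invariant under strictly monotone
    transforms of either axis.
    """
    if not (0.0 < x_quantile < 1.0 and 0.0 < y_quantile < 1.0):
        raise ValueError(f"quantiles must lie in (0, 1), got {x_quantile}, {y_quantile}")
    x = np.asarray(x_scores, float)
    y = np.asarray(y_scores, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x_scores and y_scores must be 1-d arrays of equal length")
    xt = np.quantile(x, x_quantile)
    yt = np.quantile(y, y_quantile)
    return int(np.sum((x < xt) & (y > yt)))


@dataclass
class ComparisonReport:
    """Paired score table with association and corner statistics."""

    table: pd.DataFrame  # columns: country_id, score_x, score_y
    r2: float
    corner_count: int
    x_quantile: float
    y_quantile: float
    excluded: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_countries(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        df = self.table.copy()
        df["r2"] = self.r2
        df["corner_count"] = self.corner_count
        df["x_quantile"] = self.x_quantile
        df["y_quantile"] = self.y_quantile
        df["excluded"] = ";".join(self.excluded)
        df.to_csv(path, index=False, float_format="%.10g")


def compare_indices(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    exclusions: tuple[str, ...] = (),
    x_quantile: float = 0.25,
    y_quantile: float = 0.75,
) -> ComparisonReport:
    """Compare two country-score tables (as produced by ``summarize``).

    Only countries present in both tables, minus user-supplied exclusions,
    enter the comparison; at least 3 must remain.
    """
    a = scores_a.set_index("country_id")["score_mean"]
    b = scores_b.set_index("country_id")["score_mean"]
    common = [c for c in a.index if c in set(b.index) and c not in set(exclusions)]
    if len(common) < 3:
        raise ValueError(
            f"need at least 3 countries shared by both indices after exclusions, "
            f"got {len(common)}"
        )
    x = a.loc[common].to_numpy()
    y = b.loc[common].to_numpy()
    table = pd.DataFrame({"country_id": common, "score_x": x, "score_y": y})
    return ComparisonReport(
        table=table,
        r2=r_squared(x, y),
        corner_count=corner_occupancy(x, y, x_quantile, y_quantile),
        x_quantile=x_quantile,
        y_quantile=y_quantile,
        excluded=tuple(exclusions),
    )


def scatter_plot(report: ComparisonReport, path, x_label: str = "index A",
                 y_label: str = "index B") -> None:
    """Write a score scatter with the corner rectangle marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = report.table["score_x"].to_numpy()
    y = report.table["score_y"].to_numpy()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=12)
    ax.axvline(np.quantile(x, report.x_quantile), ls="--", lw=0.8, color="grey")
    ax.axhline(np.quantile(y, report.y_quantile), ls="--", lw=0.8, color="grey")
    ax.set_xlabel(x_label)
    ax.set_ylabel(y_label)
    ax.set_title(f"$R^2$ = {report.r2:.2f}, corner count = {report.corner_count}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
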