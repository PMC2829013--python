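"""Distribution diagnostics for normalisation stages.

Boxplot statistics per array at each pipeline stage (the classic
M-value-versus-array panels used to judge normalisation), MA-plot data
for any array pair, and per-array standard deviation / skewness
summaries.  Everything is produced as numbers (TSV-friendly tables);
image rendering is a thin optional layer on top so tests and users can
work with the statistics directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as _stats

ArrayValues = Union[pd.Series, Sequence[float], np.ndarray]


@dataclass
class BoxplotStats:
    """Tukey boxplot statistics for one array.

    Whiskers sit at the most extreme data points within 1.5 IQR of the
    quartiles; ``outliers`` are exactly the points beyond them,
    reported as (feature_id, value) pairs.
    """

    array_id: str
    median: float
    q1: float
    q3: float
    lower_whisker: float
    upper_whisker: float
    outliers: list[tuple[str, float]]


@dataclass
class DistributionSummary:
    """Per-array spread and asymmetry: sample s.d. and skewness g1."""

    array_id: str
    sd: float
    skewness: float


def _clean(values: ArrayValues, array_id: str) -> pd.Series:
    s = pd.Series(values)
    s = s.dropna()
    if s.empty:
        raise ValueError(f"{array_id}: no non-missing values")
    return s.astype(float)


def boxplot_stats_single(values: ArrayValues, array_id: str = "array") -> BoxplotStats:
    """Boxplot statistics for one array's values (NaN-aware)."""
    s = _clean(values, array_id)
    v = s.to_numpy()
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    lower, upper = float(inside.min()), float(inside.max())
    out_mask = (v < lo_fence) | (v > hi_fence)
    outliers = [(str(i), float(x))
                for i, x in zip(s.index[out_mask], v[out_mask])]
    return BoxplotStats(array_id=array_id, median=float(med),
                        q1=float(q1), q3=float(q3),
                        lower_whisker=lower, upper_whisker=upper,
                        outliers=outliers)


def boxplot_stats(per_array: Mapping[str, ArrayValues] | pd.DataFrame) -> list[BoxplotStats]:
    """Boxplot statistics per array (columns of a matrix or dict values)."""
    if isinstance(per_array, pd.DataFrame):
        per_array = {str(c): per_array[c] for c in per_array.columns}
    return [boxplot_stats_single(v, array_id=k) for k, v in per_array.items()]


def boxplot_table(per_array: Mapping[str, ArrayValues] | pd.DataFrame,
                  stage: str = "") -> pd.DataFrame:
    """Boxplot statistics as a tidy table (one row per array)."""
    rows = []
    for bs in boxplot_stats(per_array):
        rows.append({
            "stage": stage, "array_id": bs.array_id, "median": bs.median,
            "q1": bs.q1, "q3": bs.q3,
            "lower_whisker": bs.lower_whisker,
            "upper_whisker": bs.upper_whisker,
            "n_outliers": len(bs.outliers),
        })
    return pd.DataFrame(rows)


def ma_plot_data(L_a: pd.Series, L_b: pd.Series) -> pd.DataFrame:
    """(A, M) pairs over the shared features of two array vectors.

    M = L_a - L_b and A = (L_a + L_b)/2; because L = log2(R/G), these
    equal log2{(R_a/G_a)/(R_b/G_b)} and log2 sqrt{(R_a/G_a)(R_b/G_b)}
    respectively — identical to the quantities the pairwise loess fit
    consumes, so pre/post normalisation MA-plots come from the same
    machinery.
    """
    shared = L_a.index.intersection(L_b.index).sort_values()
    if shared.empty:
        raise ValueError(
            f"no shared features between {L_a.name!r} and {L_b.name!r}"
        )
    a = L_a.loc[shared].astype(float)
    b = L_b.loc[shared].astype(float)
    return pd.DataFrame({"A": (a + b) / 2.0, "M": a - b}, index=shared)


def distribution_stats_single(values: ArrayValues,
                              array_id: str = "array") -> DistributionSummary:
    """Sample s.d. (n-1 denominator) and moment skewness g1."""
    s = _clean(values, array_id)
    if len(s) < 3:
        raise ValueError(f"{array_id}: need >= 3 values for distribution "
                         f"summary, got {len(s)}")
    v = s.to_numpy()
    return DistributionSummary(
        array_id=array_id,
        sd=float(np.std(v, ddof=1)),
        skewness=float(_stats.skew(v, bias=True)),
    )


def distribution_stats(per_array: Mapping[str, ArrayValues] | pd.DataFrame) -> list[DistributionSummary]:
    if isinstance(per_array, pd.DataFrame):
        per_array = {str(c): per_array[c] for c in per_array.columns}
    return [distribution_stats_single(v, array_id=k)
            for k, v in per_array.items()]


def distribution_table(per_array: Mapping[str, ArrayValues] | pd.DataFrame,
                       stage: str = "") -> pd.DataFrame:
    return pd.DataFrame([
        {"stage": stage, "array_id": d.array_id, "sd": d.sd,
         "skewness": d.skewness}
        for d in distribution_stats(per_array)
    ])


def plot_stage_boxplots(stages: Mapping[str, pd.DataFrame], path: str) -> None:
    """Render M-value vs array boxplot panels, one per pipeline stage."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(stages)
    fig, axes = plt.subplots(n, 1, figsize=(8, 2.6 * n), squeeze=False)
    for ax, (label, matrix) in zip(axes.ravel(), stages.items()):
        data = [matrix[c].dropna().to_numpy() for c in matrix.columns]
        ax.boxplot(data, flierprops={"markersize": 2})
        ax.axhline(0.0, color="grey", lw=0.6)
        ax.set_title(label)
        ax.set_ylabel("M")
        ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ma(ma: pd.DataFrame, path: str, title: str = "") -> None:
    """Render an MA scatter plot from a :func:`ma_plot_data` table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ma["A"], ma["M"], s=3, alpha=0.4)
    ax.axhline(0.0, color="red", lw=0.8)
    ax.set_xlabel("A")
    ax.set_ylabel("M")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
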