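"""Hue-band stress kinetics.

The stress indicator is built from normalized per-degree hue histograms:
group mean histograms with per-degree 95% confidence intervals, trapezoidal
area under the curve over the yellow ([0, 60] deg) and green ([61, 120] deg)
bands, the per-day AUC time series per responder group, difference
histograms between treatments, and per-day two-group comparisons of the
per-plant band AUCs (Welch's t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

YELLOW_BAND = (0, 60)
GREEN_BAND = (61, 120)

HUE_COLS = [f"hue_{d:03d}" for d in range(360)]


@dataclass
class MeanHistogram:
    """Per-degree mean hue fraction with a t-based 95% CI half-width."""

    mean: np.ndarray
    ci_halfwidth: np.ndarray
    n: int


def mean_histogram_with_ci(histograms: np.ndarray,
                           confidence: float = 0.95) -> MeanHistogram:
    """Average a stack of normalized histograms per degree.

    ``histograms`` is (replicates x 360).  The CI uses the t distribution
    on the replicate dimension (replicate counts here are small, 6-9).
    """
    h = np.atleast_2d(np.asarray(histograms, dtype=float))
    n = h.shape[0]
    if n < 2:
        raise ValueError("need >= 2 histograms for a mean with CI")
    mean = h.mean(axis=0)
    sd = h.std(axis=0, ddof=1)
    tq = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    return MeanHistogram(mean=mean, ci_halfwidth=tq * sd / np.sqrt(n), n=n)


def hist_auc(values, lo_deg: int, hi_deg: int) -> float:
    """Trapezoidal area under a per-degree histogram between two degrees.

    Integrates on the integer-degree grid with unit spacing, endpoints
    inclusive: sum of (f[d] + f[d+1])/2 for d = lo..hi-1.  A constant band
    of height c over [0, 60] integrates to 60 c.
    """
    v = np.asarray(values, dtype=float)
    v = v if v.ndim else v[None]
    if not (0 <= lo_deg < hi_deg <= v.shape[-1] - 1):
        raise ValueError("need 0 <= lo < hi within the histogram support")
    return float(np.trapezoid(v[lo_deg:hi_deg + 1]))


def band_aucs(values) -> tuple[float, float]:
    """Yellow- and green-band AUCs of one normalized histogram."""
    return (hist_auc(values, *YELLOW_BAND), hist_auc(values, *GREEN_BAND))


def _normalized_hist_matrix(hues: pd.DataFrame) -> np.ndarray:
    """Rows of the hue table as mask-fraction histograms.

    Count rows are divided by their own mask-pixel total; rows that already
    sum to <= 1 are assumed normalized and passed through.
    """
    h = hues[HUE_COLS].to_numpy(dtype=float)
    totals = h.sum(axis=1)
    scale = np.where(totals > 1.0, totals, 1.0)
    return h / scale[:, None]


def per_plant_aucs(hues: pd.DataFrame) -> pd.DataFrame:
    """Yellow/green AUC per hue-table row (one plant on one day)."""
    h = _normalized_hist_matrix(hues)
    out = hues.drop(columns=HUE_COLS).copy()
    lo, hi = YELLOW_BAND
    out["yellow_auc"] = np.trapezoid(h[:, lo:hi + 1], axis=1)
    lo, hi = GREEN_BAND
    out["green_auc"] = np.trapezoid(h[:, lo:hi + 1], axis=1)
    return out


def auc_time_series(hues: pd.DataFrame, group_col: str = "treatment") -> pd.DataFrame:
    """Per-group, per-day mean and SE of the per-plant yellow/green AUCs.

    Returns a tidy frame (group, day, yellow_auc, yellow_se, green_auc,
    green_se, n).  SE is over plants within the group-day cell.
    """
    aucs = per_plant_aucs(hues)
    rows = []
    for (g, day), sub in aucs.groupby([group_col, "day"], observed=True):
        n = len(sub)
        rows.append({
            group_col: g, "day": day, "n": n,
            "yellow_auc": sub["yellow_auc"].mean(),
            "yellow_se": sub["yellow_auc"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "green_auc": sub["green_auc"].mean(),
            "green_se": sub["green_auc"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def difference_histogram(mean_a: MeanHistogram | np.ndarray,
                         mean_b: MeanHistogram | np.ndarray) -> np.ndarray:
    """Per-degree difference a - b of two mean histograms (signed)."""
    a = mean_a.mean if isinstance(mean_a, MeanHistogram) else np.asarray(mean_a)
    b = mean_b.mean if isinstance(mean_b, MeanHistogram) else np.asarray(mean_b)
    return a - b


def compare_auc_groups(aucs1: pd.DataFrame, aucs2: pd.DataFrame,
                       band: str = "yellow_auc") -> pd.Series:
    """Per-day Welch two-sample t test between two groups' per-plant AUCs.

    Inputs are per-plant AUC frames (from :func:`per_plant_aucs`) with a
    ``day`` column.  Days with fewer than 3 plants in either group are
    skipped.  Returns day -> p-value.
    """
    out = {}
    g1 = aucs1.groupby("day")[band]
    g2 = aucs2.groupby("day")[band]
    for day in sorted(set(g1.groups) & set(g2.groups)):
        a, b = g1.get_group(day), g2.get_group(day)
        if len(a) < 3 or len(b) < 3:
            continue
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            out[day] = 1.0 if a.mean() == b.mean() else 0.0
            continue
        out[day] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return pd.Series(out, name="p_value").rename_axis("day")
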