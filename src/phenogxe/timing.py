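"""Early/late responder classification and genotype growth rankings.

For every genotype and day, a one-way ANOVA compares plant area between two
nitrogen treatments; the raw p-values are Benjamini-Hochberg corrected
globally across the whole genotype x day matrix and -log10 transformed.
Genotypes are then clustered on their q-value vectors (Canberra distance,
Ward's minimum-variance linkage) and the k=2 cut is labelled early/late by
mean onset day (first day with q below threshold).  Separately, genotypes
are ranked by end-of-experiment size and by growth rate (regression slope
of area on day).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import canberra as _scipy_canberra, squareform
from statsmodels.stats.multitest import multipletests


@dataclass
class QMatrix:
    """Genotype x day treatment-comparison significance matrix."""

    p: pd.DataFrame            # raw ANOVA p-values
    q: pd.DataFrame            # global BH q-values
    neglog10_q: pd.DataFrame   # -log10(q), the heatmap scale

    @property
    def genotypes(self) -> list:
        return list(self.p.index)


@dataclass
class Dendrogram:
    """Agglomerative clustering result (scipy linkage encoding)."""

    merges: np.ndarray         # (n-1, 4) linkage matrix
    leaf_order: list           # labels in dendrogram leaf order
    labels: list = field(default_factory=list)


@dataclass
class ResponderLabels:
    labels: dict               # genotype -> "early" | "late"
    onset_day: dict            # genotype -> first significant day (or None)
    clusters: dict             # genotype -> raw cluster id (1 or 2)


def one_way_anova_F(groups) -> tuple[float, float]:
    """Classic one-way ANOVA from the between/within sum-of-squares
    decomposition.

    Returns ``(F, p)`` with p from the F(k-1, N-k) distribution.  Zero
    within-group variance with unequal means is the infinite-evidence
    limit: returns ``(inf, 0.0)``.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(arrs)
    grand = all_vals.mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df1 = len(arrs) - 1
    df2 = len(all_vals) - len(arrs)
    if ssw == 0.0:
        return (float("inf"), 0.0) if ssb > 0 else (0.0, 1.0)
    f = (ssb / df1) / (ssw / df2)
    return float(f), float(stats.f.sf(f, df1, df2))


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvals, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def qvalue_matrix(traits: pd.DataFrame, trait: str = "area",
                  treatment_pair=("100/100", "10/10"),
                  min_reps: int = 2) -> QMatrix:
    """Daily per-genotype treatment comparison with global FDR correction.

    Each (genotype, day) cell is a one-way ANOVA of ``trait`` between the
    two treatments; BH runs once over every cell of the matrix.  Cells
    without ``min_reps`` plants in both treatments are NaN and excluded
    from the correction.
    """
    sub = traits[traits["treatment"].isin(treatment_pair)]
    genotypes = sorted(sub["genotype"].unique())
    days = sorted(sub["day"].unique())
    p = pd.DataFrame(np.nan, index=genotypes, columns=days)
    for (g, day), cell in sub.groupby(["genotype", "day"], observed=True):
        groups = [cell.loc[cell["treatment"] == t, trait].to_numpy()
                  for t in treatment_pair]
        if any(len(x) < min_reps for x in groups):
            continue
        p.loc[g, day] = one_way_anova_F(groups)[1]
    q = pd.DataFrame(bh_qvalues(p.to_numpy()).reshape(p.shape),
                     index=p.index, columns=p.columns)
    with np.errstate(divide="ignore"):
        nl = -np.log10(q)
    return QMatrix(p=p, q=q, neglog10_q=nl)


def canberra_distance(u, v) -> float:
    """Canberra distance: sum of |u_i - v_i| / (|u_i| + |v_i|), with 0/0
    terms contributing zero."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    return float(_scipy_canberra(u, v))


def canberra_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise Canberra distance matrix over rows."""
    x = np.asarray(vectors, dtype=float)
    n = len(x)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = canberra_distance(x[i], x[j])
    return d


def ward_dendrogram(distance_matrix: np.ndarray, labels=None) -> Dendrogram:
    """Ward's minimum-variance agglomeration on a precomputed dissimilarity
    matrix (Lance-Williams recurrence on the provided distances)."""
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if labels is None:
        labels = list(range(len(d)))
    merges = linkage(squareform(d, checks=False), method="ward")
    order = [labels[i] for i in leaves_list(merges)]
    return Dendrogram(merges=merges, leaf_order=order, labels=list(labels))


def onset_days(qmat: QMatrix, q_threshold: float = 0.05) -> dict:
    """First day each genotype's treatment comparison reaches q < threshold
    (None if it never does)."""
    out = {}
    for g in qmat.genotypes:
        sig = qmat.q.loc[g] < q_threshold
        out[g] = int(sig.idxmax()) if sig.any() else None
    return out


def split_early_late(dendrogram: Dendrogram, qmat: QMatrix,
                     q_threshold: float = 0.05, k: int = 2) -> ResponderLabels:
    """Cut the q-value dendrogram at k=2 and name the clusters.

    The cluster whose genotypes reach significance sooner on average (never-
    significant genotypes count as one past the last day) is "early".  If
    the mean onsets tie, the cluster holding the first dendrogram leaf is
    "early" (documented tie-break).
    """
    assign = fcluster(dendrogram.merges, t=k, criterion="maxclust")
    clusters = dict(zip(dendrogram.labels, assign))
    onset = onset_days(qmat, q_threshold)
    last_day = max(qmat.p.columns) + 1
    means = {}
    for c in sorted(set(assign)):
        genos = [g for g in dendrogram.labels if clusters[g] == c]
        means[c] = float(np.mean([onset[g] if onset[g] is not None else last_day
                                  for g in genos]))
    ranked = sorted(means, key=lambda c: (means[c],
                                          0 if c == clusters[dendrogram.leaf_order[0]]
                                          else 1))
    name = {ranked[0]: "early"}
    for c in ranked[1:]:
        name[c] = "late"
    labels = {g: name[clusters[g]] for g in dendrogram.labels}
    return ResponderLabels(labels=labels, onset_day=onset, clusters=clusters)


def classify_responders(traits: pd.DataFrame, trait: str = "area",
                        treatment_pair=("100/100", "10/10"),
                        q_threshold: float = 0.05) -> tuple[ResponderLabels, QMatrix, Dendrogram]:
    """End-to-end responder pipeline: daily ANOVA -> global BH -> -log10 q
    -> Canberra -> Ward -> k=2 early/late labels."""
    qmat = qvalue_matrix(traits, trait=trait, treatment_pair=treatment_pair)
    vecs = np.nan_to_num(qmat.neglog10_q.to_numpy(), posinf=300.0)
    dend = ward_dendrogram(canberra_matrix(vecs), labels=qmat.genotypes)
    return split_early_late(dend, qmat, q_threshold=q_threshold), qmat, dend


def growth_rate(traits: pd.DataFrame, window: tuple[int, int] = (10, 22),
                trait: str = "area", confidence: float = 0.95) -> pd.DataFrame:
    """Average daily growth (least-squares slope of area on day) per genotype.

    The slope is fitted per plant over the day window, then averaged over a
    genotype's replicates with a t-based CI.  Robust to days dropped by
    outlier filtering, and identical to the mean daily change for complete
    series.
    """
    sub = traits[(traits["day"] >= window[0]) & (traits["day"] <= window[1])]
    slopes = []
    for (g, pid), plant in sub.groupby(["genotype", "plant_id"], observed=True):
        if plant["day"].nunique() < 2:
            continue
        b = np.polyfit(plant["day"].to_numpy(dtype=float),
                       plant[trait].to_numpy(dtype=float), 1)[0]
        slopes.append((g, pid, b))
    sl = pd.DataFrame(slopes, columns=["genotype", "plant_id", "slope"])
    rows = []
    for g, grp in sl.groupby("genotype"):
        n = len(grp)
        m = grp["slope"].mean()
        if n > 1:
            half = (stats.t.ppf(0.5 + confidence / 2, n - 1)
                    * grp["slope"].std(ddof=1) / np.sqrt(n))
        else:
            half = np.nan
        rows.append({"genotype": g, "rate": m, "ci_low": m - half,
                     "ci_high": m + half, "n": n})
    return pd.DataFrame(rows).set_index("genotype")


def end_size_outperformers(traits: pd.DataFrame, day: int = 26,
                           treatment: str = "10/10", trait: str = "area",
                           q_star: float = 0.01) -> pd.DataFrame:
    """Rank genotypes by end-of-experiment size within one treatment.

    Each genotype's replicates are Welch-tested against the pooled
    replicates of all other genotypes; BH across genotypes; a star marks
    q < ``q_star`` (either direction).
    """
    sub = traits[(traits["day"] == day) & (traits["treatment"] == treatment)]
    genotypes = sorted(sub["genotype"].unique())
    if len(genotypes) < 2:
        raise ValueError("need >= 2 genotypes to compare end sizes")
    rows = []
    for g in genotypes:
        own = sub.loc[sub["genotype"] == g, trait].to_numpy()
        rest = sub.loc[sub["genotype"] != g, trait].to_numpy()
        pval = float(stats.ttest_ind(own, rest, equal_var=False).pvalue)
        rows.append({"genotype": g, "mean": own.mean(),
                     "effect": own.mean() - rest.mean(), "p": pval})
    out = pd.DataFrame(rows).set_index("genotype")
    out["q"] = bh_qvalues(out["p"].to_numpy())
    out["star"] = out["q"] < q_star
    return out.sort_values("mean", ascending=False)
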