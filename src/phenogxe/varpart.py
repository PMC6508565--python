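"""Variance attribution: mixed-model Wald ANOVA, type-III variance
partitioning of the ionome, and PCA with group confidence ellipses.

The area time course is modelled as a Gaussian linear mixed model with six
fixed effects — genotype (G), treatment (E) and their interactions with
each other and with time (GxE, GxT, ExT, GxExT) — and a per-plant random
intercept and slope over day (repeated measures).  Each fixed effect gets a
Wald chi-square adjusted for all other terms (type III).  Ionomic responses
are partitioned into genotype / treatment / interaction / residual
fractions of total type-III sum of squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.decomposition import PCA

#: fixed-effect terms tested, in patsy syntax, keyed by short name
FIXED_EFFECTS = {
    "G": "C(genotype, Sum)",
    "E": "C(treatment, Sum)",
    "GxE": "C(genotype, Sum):C(treatment, Sum)",
    "GxT": "C(genotype, Sum):day_c",
    "ExT": "C(treatment, Sum):day_c",
    "GxExT": "C(genotype, Sum):C(treatment, Sum):day_c",
}


@dataclass
class EffectTest:
    effect: str
    chi2: float
    df: int
    p: float


@dataclass
class WaldResult:
    effects: list[EffectTest]
    converged: bool
    used_fallback: bool   # True when the fixed-effects-only OLS fallback was used

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"effect": e.effect, "chi2": e.chi2,
                              "df": e.df, "p": e.p} for e in self.effects]
                            ).set_index("effect")


@dataclass
class VariancePartition:
    response: str
    fractions: dict[str, float]   # genotype / treatment / interaction / residual
    sum_squares: dict[str, float] = field(default_factory=dict)


@dataclass
class PcaResult:
    scores: np.ndarray
    loadings: np.ndarray          # variables x components, orthonormal columns
    explained_pct: np.ndarray
    ellipses: dict                # group -> dict(center, width, height, angle_deg)
    dropped_columns: list = field(default_factory=list)


def _wald_formula(response: str) -> str:
    return f"{response} ~ day_c + " + " + ".join(FIXED_EFFECTS.values())


def mixed_model_wald(traits: pd.DataFrame, response: str = "area",
                     transform: str = "log") -> WaldResult:
    """Wald chi-square tests of the six G/E/time fixed effects under a
    random-intercept-and-slope repeated-measures model.

    ``transform="log"`` (default) models log area — growth noise is
    multiplicative, so the Gaussian model holds on the log scale.  Day is
    centred so intercept-related terms stay well scaled.  If the mixed
    model fails to converge, an OLS fixed-effects-only fit supplies the
    Wald tests and the result is flagged ``used_fallback``.
    """
    df = traits.copy()
    for col in ("genotype", "treatment"):
        if df[col].nunique() < 2:
            raise ValueError(f"need >= 2 levels of {col}")
    y = df[response].astype(float)
    if transform == "log":
        if (y <= 0).any():
            raise ValueError("log transform requires positive responses")
        df["_y"] = np.log(y)
    else:
        df["_y"] = y
    if df["_y"].var() == 0:
        raise ValueError("response has zero variance")
    df["day_c"] = df["day"] - df["day"].mean()
    formula = _wald_formula("_y")

    converged, used_fallback = False, False
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, df, groups=df["plant_id"],
                                re_formula="~day_c")
            fit = model.fit(method="lbfgs", maxiter=200)
            converged = bool(fit.converged)
            # a singular / boundary random-effects covariance means the
            # repeated measures show no extra correlation; the asymptotic
            # chi-square is unreliable there, so use the exact fixed-effects
            # F test instead
            cov_re = np.asarray(fit.cov_re)
            boundary = (np.linalg.eigvalsh(cov_re).min()
                        < 1e-4 * float(fit.scale))
        except Exception:
            fit, boundary = None, True
        if fit is None or not converged or boundary:
            used_fallback = True
            fit = smf.ols(formula, df).fit()
    effects = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wt = fit.wald_test_terms(skip_single=False)
    table = wt.table
    df_col = next(c for c in table.columns if c.replace(" ", "_") == "df_constraint")
    # between-within (containment) denominator df for the mixed fit:
    # genotype/treatment contrasts are between-plant comparisons, so their
    # Wald statistics are referred to an F with plants-minus-cells df rather
    # than the asymptotic chi-square (anticonservative at these panel sizes)
    n_plants = df["plant_id"].nunique()
    n_cells = df.groupby(["genotype", "treatment"], observed=True).ngroups
    n_fixed = len(np.ravel(fit.fe_params if hasattr(fit, "fe_params")
                           else fit.params))
    between_ddf = max(n_plants - n_cells, 1)
    within_ddf = max(len(df) - n_plants - (n_fixed - n_cells), 1)
    for name, term in FIXED_EFFECTS.items():
        row = table.loc[term]
        stat = float(np.ravel(row.iloc[0])[0])
        dfree = int(row[df_col])
        if used_fallback:
            # OLS wald_test_terms reports F; report the chi-square-scale
            # statistic but keep the exact finite-sample F p-value
            chi2 = stat * dfree
            p = float(stats.f.sf(stat, dfree, float(row["df_denom"])))
        else:
            chi2 = stat
            ddf = within_ddf if "day_c" in term else between_ddf
            p = float(stats.f.sf(chi2 / dfree, dfree, ddf))
        effects.append(EffectTest(effect=name, chi2=chi2, df=dfree, p=p))
    return WaldResult(effects=effects, converged=converged,
                      used_fallback=used_fallback)


def type3_anova(values: pd.DataFrame, response: str, typ: int = 3) -> pd.DataFrame:
    """Two-factor genotype x treatment ANOVA table (type III by default,
    sum-to-zero contrasts)."""
    formula = (f"{response} ~ C(genotype, Sum) + C(treatment, Sum) "
               "+ C(genotype, Sum):C(treatment, Sum)")
    fit = smf.ols(formula, values).fit()
    return sm.stats.anova_lm(fit, typ=typ)


def type3_variance_partition(ionome: pd.DataFrame, element: str,
                             value_col: str = "ppm") -> VariancePartition:
    """Fraction of an element's total variance attributable to genotype,
    treatment, their interaction and residual (partial eta-squared against
    total SS; on balanced designs identical to the sequential partition)."""
    sub = ionome[ionome["element"] == element].copy()
    if sub.empty:
        raise ValueError(f"element {element!r} not in table")
    counts = sub.groupby(["genotype", "treatment"], observed=True).size()
    if (counts < 2).any():
        raise ValueError("need >= 2 replicates per genotype x treatment cell")
    table = type3_anova(sub, value_col)
    ss = {
        "genotype": float(table.loc["C(genotype, Sum)", "sum_sq"]),
        "treatment": float(table.loc["C(treatment, Sum)", "sum_sq"]),
        "interaction": float(table.loc["C(genotype, Sum):C(treatment, Sum)", "sum_sq"]),
        "residual": float(table.loc["Residual", "sum_sq"]),
    }
    total = sum(ss.values())
    fractions = {k: v / total for k, v in ss.items()}
    return VariancePartition(response=element, fractions=fractions, sum_squares=ss)


def partition_all_elements(ionome: pd.DataFrame,
                           value_col: str = "ppm") -> pd.DataFrame:
    """Per-element variance partition table (rows = elements)."""
    rows = []
    for el in sorted(ionome["element"].unique()):
        part = type3_variance_partition(ionome, el, value_col)
        rows.append({"element": el, **part.fractions})
    return pd.DataFrame(rows).set_index("element")


def confidence_ellipse(points: np.ndarray, confidence: float = 0.95) -> dict:
    """95% normal-theory ellipse of 2-D points: covariance eigen-axes scaled
    by the chi-square(2) quantile."""
    pts = np.asarray(points, dtype=float)
    center = pts.mean(axis=0)
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    r = np.sqrt(stats.chi2.ppf(confidence, df=2))
    return {
        "center": center,
        "width": 2 * r * np.sqrt(max(evals[0], 0.0)),
        "height": 2 * r * np.sqrt(max(evals[1], 0.0)),
        "angle_deg": float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0]))),
    }


def pca_with_ellipses(matrix, group_labels=None, scale: bool = True,
                      n_components: int | None = None) -> PcaResult:
    """Centered (optionally unit-variance) PCA with per-group 95% score
    ellipses on the first two components.

    Constant columns carry no information and are dropped with a warning.
    Shape features and elements are scaled to unit variance (heterogeneous
    units); hue-fraction bins should use ``scale=False`` (shared unit).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] <= 2:
        raise ValueError("need a 2-D matrix with more than 2 samples")
    sd = x.std(axis=0)
    dropped = list(np.nonzero(sd == 0)[0])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant column(s)",
                      stacklevel=2)
        x = x[:, sd > 0]
        sd = sd[sd > 0]
    x = x - x.mean(axis=0)
    if scale:
        x = x / sd
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x)
    ellipses = {}
    if group_labels is not None and scores.shape[1] >= 2:
        groups = pd.Series(list(group_labels))
        for g in groups.unique():
            pts = scores[(groups == g).to_numpy(), :2]
            if len(pts) >= 3:
                ellipses[g] = confidence_ellipse(pts)
    return PcaResult(scores=scores, loadings=pca.components_.T,
                     explained_pct=pca.explained_variance_ratio_ * 100.0,
                     ellipses=ellipses, dropped_columns=dropped)
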