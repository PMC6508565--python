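"""Influence-based record filtering and robust replicate screening.

Image records are screened with Cook's distance on a cell-means linear
model whose cells are the genotype x treatment x day combinations (the
three-way interaction as the only effect).  A record is an outlier when its
influence exceeds four times the mean influence.  Ionomic replicates are
screened per genotype x treatment x element with a raw (unscaled) MAD rule
at cutoff 6.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class InfluenceResult:
    distances: pd.Series      # Cook's D per record (NaN for singleton cells)
    mean_influence: float     # mean over non-singleton records
    threshold: float          # 4 x mean influence (threshold_factor x)
    flags: pd.Series          # True where D > threshold
    singleton: pd.Series      # True where the record is alone in its cell


@dataclass
class MadResult:
    scores: pd.Series         # |x - median| / MAD within the replicate group
    threshold: float
    flags: pd.Series


def cooks_distance(design_cells, response) -> tuple[pd.Series, pd.Series]:
    """Cook's distance under a cell-means model.

    ``design_cells`` assigns each record to a factor-combination cell (any
    hashable label, e.g. (genotype, treatment, day) tuples); the model fits
    one mean per cell, so leverage is ``h = 1/n_cell`` and

        D_i = r_i^2 h / (p s^2 (1 - h)^2),

    with p the number of cells and s^2 the residual mean square.  This is
    algebraically identical to the leave-one-out definition: the scaled sum
    of squared shifts in fitted values when record i is dropped.  Records in
    singleton cells have undefined influence (their removal deletes the
    cell) and get NaN.

    Returns ``(D, singleton_flags)`` as Series aligned with the input.
    """
    y = pd.Series(np.asarray(response, dtype=float))
    cells = pd.Series(list(design_cells), index=y.index)
    if len(y) != len(cells):
        raise ValueError("design_cells and response length mismatch")
    grp = y.groupby(cells)
    n_cell = grp.transform("size")
    if (n_cell < 2).all():
        raise ValueError("need at least one cell with >= 2 records")
    resid = y - grp.transform("mean")
    p = cells.nunique()
    dof = len(y) - p
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = float((resid**2).sum()) / dof
    h = 1.0 / n_cell
    with np.errstate(divide="ignore", invalid="ignore"):
        d = resid**2 * h / (p * s2 * (1.0 - h) ** 2)
    singleton = n_cell == 1
    d[singleton] = np.nan
    if s2 == 0.0:
        d[~singleton] = 0.0
    return d, singleton


def flag_influence_outliers(traits: pd.DataFrame, response: str = "area",
                            factors=("genotype", "treatment", "day"),
                            threshold_factor: float = 4.0,
                            log_transform: bool = True):
    """Remove records whose Cook's distance exceeds ``threshold_factor``
    times the mean influence.

    The response is log-transformed by default: plant growth noise is
    multiplicative, so residual spread on the raw scale grows with plant
    size and late-day records would dominate the pooled variance.  The mean
    influence is taken over all non-singleton records pooled together.

    Returns ``(filtered table, InfluenceResult, removal_fraction)``.
    """
    y = traits[response].astype(float)
    if log_transform:
        if (y <= 0).any():
            raise ValueError("log transform requires positive responses")
        y = np.log(y)
    cells = list(zip(*(traits[f] for f in factors)))
    d, singleton = cooks_distance(cells, y.to_numpy())
    d.index = traits.index
    singleton.index = traits.index
    mean_d = float(d[~singleton].mean())
    threshold = threshold_factor * mean_d
    flags = (d > threshold).fillna(False)
    result = InfluenceResult(distances=d, mean_influence=mean_d,
                             threshold=threshold, flags=flags,
                             singleton=singleton)
    removal_fraction = float(flags.mean())
    return traits.loc[~flags].copy(), result, removal_fraction


def mad_flags(values, cutoff: float = 6.2) -> MadResult:
    """Flag replicate measurements by the unscaled MAD rule.

    Score is ``|x - median| / MAD`` with ``MAD = median(|x - median|)`` (no
    1.4826 consistency factor); values scoring above ``cutoff`` are flagged.
    Degenerate case MAD = 0: any value differing from the median is flagged
    (its score is infinite); identical replicates yield no flags.
    """
    x = pd.Series(np.asarray(values, dtype=float))
    if len(x) < 3:
        raise ValueError("need >= 3 replicates for MAD screening")
    med = float(x.median())
    mad = float((x - med).abs().median())
    if mad == 0.0:
        scores = pd.Series(np.where(x == med, 0.0, np.inf), index=x.index)
    else:
        scores = (x - med).abs() / mad
    return MadResult(scores=scores, threshold=cutoff, flags=scores > cutoff)


def mad_filter_ionome(ionome: pd.DataFrame, cutoff: float = 6.2,
                      value_col: str = "ppm"):
    """Apply the MAD rule within every genotype x treatment x element group.

    Groups with fewer than 3 replicates are left unflagged.  Returns the
    filtered table and the flag Series aligned with the input.
    """
    flags = pd.Series(False, index=ionome.index)
    for _, idx in ionome.groupby(["genotype", "treatment", "element"],
                                 observed=True).groups.items():
        if len(idx) < 3:
            continue
        res = mad_flags(ionome.loc[idx, value_col])
        flags.loc[idx] = res.flags.to_numpy()
    return ionome.loc[~flags].copy(), flags
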