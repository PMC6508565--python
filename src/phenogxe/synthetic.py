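"""Synthetic nitrogen-deprivation experiments with known ground truth.

Emulates a controlled-environment phenotyping study: a panel of genotypes
grown under three nitrogen treatments ("100/100", "50/10", "10/10"),
imaged daily from day 8 to day 26.  Plant area follows a per-genotype
logistic growth curve; low-nitrogen treatments are scaled down
multiplicatively starting at a genotype-specific *onset day* — the
ground-truth early/late responder label.  Color is a two-peak hue mixture
(yellow mode near 45 deg, green mode near 100 deg) whose yellow weight rises
and falls with stress, peaking mid-experiment.  The leaf ionome is drawn
from an additive genotype + treatment + interaction model with configured
variance fractions.

Everything is seeded and reproducible; the generator returns the hidden
truth (outlier flags, responder labels, variance fractions) alongside the
data so each downstream analysis stage can be validated offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREATMENTS = ("100/100", "50/10", "10/10")

#: elements measured in the emulated leaf ionome, with typical dry-weight ppm
ELEMENT_TYPICAL_PPM = {
    "B": 30.0, "Na": 300.0, "Mg": 4000.0, "Al": 50.0, "P": 3000.0,
    "S": 2000.0, "K": 25000.0, "Ca": 5000.0, "Mn": 60.0, "Fe": 120.0,
    "Co": 0.2, "Ni": 1.5, "Cu": 8.0, "Zn": 40.0, "As": 0.1,
    "Se": 0.5, "Rb": 15.0, "Mo": 1.0, "Cd": 0.3,
}


@dataclass
class GenotypeParams:
    """Logistic growth parameters for one genotype.

    asymptote : final plant area in px
    rate      : logistic growth rate per day
    inflection: day of fastest growth
    onset_day : day on which low-N treatments start to diverge from control
    """

    asymptote: float
    rate: float
    inflection: float
    onset_day: int

    def __post_init__(self) -> None:
        if self.asymptote <= 0 or self.rate <= 0:
            raise ValueError("asymptote and rate must be positive")


@dataclass
class ExperimentConfig:
    """Design and effect sizes of a synthetic experiment.

    Defaults reproduce the emulated study's layout: 30 genotypes, three
    nitrogen treatments with 9/9/6 replicates, daily imaging on days 8-26.
    ``treatment_effect`` is the asymptotic multiplicative area penalty per
    treatment once a genotype's onset day has passed (reached gradually
    over ``ramp_days``).  ``cv`` is the coefficient of variation of the
    multiplicative lognormal growth noise.
    """

    n_genotypes: int = 30
    treatments: tuple[str, ...] = TREATMENTS
    reps_per_treatment: tuple[int, ...] = (9, 9, 6)
    day_start: int = 8
    day_end: int = 26
    treatment_effect: dict[str, float] = field(
        default_factory=lambda: {"100/100": 1.0, "50/10": 0.65, "10/10": 0.45}
    )
    ramp_days: float = 5.0
    cv: float = 0.2
    # early onsets are drawn from early_onset_range, late from late_onset_range;
    # the first half of the panel (rounded up) is early
    early_onset_range: tuple[int, int] = (10, 12)
    late_onset_range: tuple[int, int] = (20, 22)
    # hue mixture: yellow weight = base + amp[treatment] * gaussian bump in day
    yellow_base: float = 0.10
    yellow_amp: dict[str, float] = field(
        default_factory=lambda: {"100/100": 0.10, "50/10": 0.28, "10/10": 0.38}
    )
    yellow_peak_day: float = 13.0
    yellow_peak_width: float = 3.0
    # ionome variance fractions (genotype, treatment, interaction); the
    # remainder is residual.  Per-element overrides via element_fractions.
    default_fractions: tuple[float, float, float] = (0.25, 0.25, 0.10)
    element_fractions: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            # genotype-dominated elements
            "Mo": (0.55, 0.15, 0.05),
            "Cd": (0.50, 0.15, 0.05),
            "Co": (0.45, 0.15, 0.05),
            # treatment-dominated elements
            "P": (0.10, 0.55, 0.10),
            "K": (0.10, 0.45, 0.10),
        }
    )
    ionome_cv: float = 0.25
    ionome_reps: int = 6
    outlier_rate: float = 0.0
    outlier_magnitude: float = 5.0
    seed: int = 0

    @property
    def days(self) -> np.ndarray:
        return np.arange(self.day_start, self.day_end + 1)

    def validate(self) -> None:
        if len(self.reps_per_treatment) != len(self.treatments):
            raise ValueError("reps_per_treatment must match treatments")
        if any(r < 2 for r in self.reps_per_treatment):
            raise ValueError("need at least 2 replicates per treatment")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must be in [0, 1)")
        for name, rng in (("early", self.early_onset_range),
                          ("late", self.late_onset_range)):
            if not (self.day_start <= rng[0] <= rng[1] <= self.day_end):
                raise ValueError(f"{name}_onset_range outside day range")
        for el, fr in {**{"_default": self.default_fractions},
                       **self.element_fractions}.items():
            if any(f < 0 or f > 1 for f in fr) or sum(fr) > 1:
                raise ValueError(f"invalid variance fractions for {el}")
        if not 0 <= self.yellow_base <= 1:
            raise ValueError("yellow_base must be in [0, 1]")

    def fractions_for(self, element: str) -> tuple[float, float, float]:
        return self.element_fractions.get(element, self.default_fractions)


@dataclass
class GroundTruth:
    """Hidden truth behind one generated experiment."""

    outlier_flags: pd.Series            # aligned 1:1 with the trait table index
    responder_labels: dict[str, str]    # genotype -> "early" | "late"
    onset_days: dict[str, int]          # genotype -> true divergence day
    variance_fractions: dict[str, tuple[float, float, float]]  # element -> (G, E, GxE)
    genotype_params: dict[str, GenotypeParams] = field(default_factory=dict)


def growth_curve(params: GenotypeParams, treatment_effect: float,
                 day, ramp_days: float = 5.0) -> np.ndarray:
    """Expected plant area (px) on `day` under a given treatment penalty.

    Logistic growth ``A / (1 + exp(-r (day - t0)))``.  Before the
    genotype's onset day all treatments coincide; from the onset day the
    curve is scaled by ``treatment_effect ** min(1, (day - onset)/ramp)``,
    i.e. the penalty is phased in geometrically over ``ramp_days`` so the
    divergence grows after onset rather than jumping.
    """
    if treatment_effect <= 0:
        raise ValueError("treatment_effect must be positive")
    day = np.asarray(day, dtype=float)
    base = params.asymptote / (1.0 + np.exp(-params.rate * (day - params.inflection)))
    since_onset = np.clip(day - params.onset_day, 0.0, None)
    frac = np.clip(since_onset / ramp_days, 0.0, 1.0) if ramp_days > 0 else (
        (since_onset > 0).astype(float))
    return base * treatment_effect ** frac


def default_genotype_params(config: ExperimentConfig) -> dict[str, GenotypeParams]:
    """Draw per-genotype growth parameters and onset days from the config seed.

    The first half of the panel (rounded up) gets early onsets, the rest
    late — this ordering is the ground-truth responder partition.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    names = [f"G{i:02d}" for i in range(config.n_genotypes)]
    n_early = (config.n_genotypes + 1) // 2
    params = {}
    for i, g in enumerate(names):
        lo, hi = (config.early_onset_range if i < n_early
                  else config.late_onset_range)
        params[g] = GenotypeParams(
            asymptote=float(rng.lognormal(np.log(40_000.0), 0.25)),
            rate=float(rng.uniform(0.30, 0.45)),
            inflection=float(rng.uniform(16.0, 20.0)),
            onset_day=int(rng.integers(lo, hi + 1)),
        )
    return params


def inject_outliers(traits: pd.DataFrame, rate: float, magnitude: float,
                    seed: int, column: str = "area"):
    """Corrupt a random fraction of records by multiplying or dividing `column`.

    Returns the corrupted copy and a boolean flag Series aligned with it.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    flags = pd.Series(rng.random(len(traits)) < rate, index=traits.index)
    out = traits.copy()
    if flags.any():
        direction = rng.random(int(flags.sum())) < 0.5
        factor = np.where(direction, magnitude, 1.0 / magnitude)
        out.loc[flags, column] = out.loc[flags, column].to_numpy() * factor
    return out, flags


def _yellow_fraction(config: ExperimentConfig, treatment: str, day,
                     genotype_shift: float = 0.0) -> np.ndarray:
    """Yellow-band hue mass for a treatment on a day: baseline plus a
    stress bump centred on the peak day, larger under low nitrogen."""
    day = np.asarray(day, dtype=float)
    bump = np.exp(-0.5 * ((day - config.yellow_peak_day) / config.yellow_peak_width) ** 2)
    yf = config.yellow_base + (config.yellow_amp[treatment] + genotype_shift) * bump
    return np.clip(yf, 0.0, 1.0)


# hue-mixture component parameters (degrees): yellow mode ~45, green mode ~100;
# kept clear of the 60-degree band boundary so band masses are unambiguous
_YELLOW_MODE, _GREEN_MODE, _HUE_SD = 45.0, 100.0, 6.0


def hue_mixture_pmf(yellow_fraction: float) -> np.ndarray:
    """Per-degree probability vector (360 bins) of the two-peak hue mixture."""
    deg = np.arange(360, dtype=float)
    yellow = np.exp(-0.5 * ((deg - _YELLOW_MODE) / _HUE_SD) ** 2)
    yellow[61:] = 0.0
    green = np.exp(-0.5 * ((deg - _GREEN_MODE) / _HUE_SD) ** 2)
    green[:61] = 0.0
    green[121:] = 0.0
    yellow /= yellow.sum()
    green /= green.sum()
    return yellow_fraction * yellow + (1.0 - yellow_fraction) * green


def generate_experiment(config: ExperimentConfig,
                        genotype_params: dict[str, GenotypeParams] | None = None,
                        with_histograms: bool = True,
                        with_ionome: bool = True):
    """Simulate a full experiment.

    Returns ``(traits, hues, ionome, truth)``:

    traits : long-format DataFrame (plant_id, genotype, treatment, rep, day,
             area, ...); area = growth_curve x lognormal(cv) noise, with
             outliers injected at ``config.outlier_rate``.
    hues   : per plant-day hue histogram counts, columns hue_000..hue_359
             (None when with_histograms=False).
    ionome : long DataFrame (sample_id, genotype, treatment, rep,
             element, ppm) (None when with_ionome=False).
    truth  : :class:`GroundTruth`.
    """
    config.validate()
    if genotype_params is None:
        genotype_params = default_genotype_params(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    days = config.days

    nd = len(days)
    pid_col, geno_col, trt_col, rep_col, mu_col = [], [], [], [], []
    for g, gp in genotype_params.items():
        for trt, reps in zip(config.treatments, config.reps_per_treatment):
            mu = growth_curve(gp, config.treatment_effect[trt], days,
                              config.ramp_days)
            for r in range(reps):
                pid_col.append(f"{g}.{trt.replace('/', '-')}.r{r}")
                geno_col.append(g)
                trt_col.append(trt)
                rep_col.append(r)
                mu_col.append(mu)
    n_plants = len(pid_col)
    mu_all = np.concatenate(mu_col)
    noise = rng.lognormal(mean=0.0, sigma=config.cv, size=n_plants * nd)
    traits = pd.DataFrame({
        "plant_id": np.repeat(pid_col, nd),
        "genotype": np.repeat(geno_col, nd),
        "treatment": np.repeat(trt_col, nd),
        "rep": np.repeat(rep_col, nd),
        "day": np.tile(days, n_plants),
        "area": mu_all * noise,
    })
    # companion shape traits derived from area (isometric-ish scaling with
    # their own small noise) so shape PCA has >1 informative dimension
    lin = np.sqrt(traits["area"].to_numpy())
    m = len(traits)
    traits["height"] = lin * 2.2 * rng.lognormal(0.0, 0.05, m)
    traits["width"] = lin * 1.6 * rng.lognormal(0.0, 0.05, m)
    traits["perimeter"] = lin * 9.0 * rng.lognormal(0.0, 0.08, m)
    traits["hull_area"] = traits["area"] * rng.uniform(1.3, 1.8, m)
    traits["solidity"] = traits["area"] / traits["hull_area"]

    if config.outlier_rate > 0:
        out_seed = int(rng.integers(0, 2**31 - 1))
        traits, flags = inject_outliers(traits, config.outlier_rate,
                                        config.outlier_magnitude, out_seed)
    else:
        flags = pd.Series(False, index=traits.index)

    hues = None
    if with_histograms:
        hues = _generate_hue_table(config, traits, genotype_params, rng)

    ionome = None
    truth_fracs: dict[str, tuple[float, float, float]] = {}
    if with_ionome:
        ionome, truth_fracs = generate_ionome(config, list(genotype_params), rng)

    midpoint = (config.day_start + config.day_end) / 2.0
    labels = {g: ("early" if gp.onset_day < midpoint else "late")
              for g, gp in genotype_params.items()}
    truth = GroundTruth(
        outlier_flags=flags,
        responder_labels=labels,
        onset_days={g: gp.onset_day for g, gp in genotype_params.items()},
        variance_fractions=truth_fracs,
        genotype_params=genotype_params,
    )
    return traits, hues, ionome, truth


def _generate_hue_table(config, traits, genotype_params, rng):
    """Multinomial hue-histogram counts per plant-day from the two-peak mixture."""
    geno_shift = {g: float(s) for g, s in zip(
        genotype_params, rng.normal(0.0, 0.02, len(genotype_params)))}
    pmf_cache: dict[float, np.ndarray] = {}
    recs = np.empty((len(traits), 360), dtype=np.int64)
    n_px = np.maximum(traits["area"].round().astype(int).to_numpy(), 50)
    yfs = np.empty(len(traits))
    for i, (g, trt, day) in enumerate(zip(traits["genotype"], traits["treatment"],
                                          traits["day"])):
        yfs[i] = _yellow_fraction(config, trt, day, geno_shift[g])
    # quantize yellow fractions so the pmf cache stays small
    yfs = np.round(yfs, 3)
    for i in range(len(traits)):
        pmf = pmf_cache.get(yfs[i])
        if pmf is None:
            pmf = hue_mixture_pmf(yfs[i])
            pmf_cache[yfs[i]] = pmf
        recs[i] = rng.multinomial(n_px[i], pmf)
    hues = pd.DataFrame(recs, columns=[f"hue_{d:03d}" for d in range(360)])
    for col in ("plant_id", "genotype", "treatment", "day"):
        hues.insert(0, col, traits[col].to_numpy())
    hues = hues[["plant_id", "genotype", "treatment", "day"]
                + [f"hue_{d:03d}" for d in range(360)]]
    return hues


def generate_ionome(config: ExperimentConfig, genotypes: list[str], rng=None):
    """Leaf-ionome table from an additive G + E + GxE + residual model.

    Effect vectors are drawn, centred and rescaled so their *empirical*
    variance equals the configured fraction of the total variance exactly;
    the residual carries the remainder.  With enough replicates a type-III
    partition therefore recovers the configured fractions.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    n_g, n_t, n_r = len(genotypes), len(config.treatments), config.ionome_reps
    rows = []
    fracs_out = {}
    for el, mu in ELEMENT_TYPICAL_PPM.items():
        f_g, f_t, f_gt = config.fractions_for(el)
        f_res = 1.0 - (f_g + f_t + f_gt)
        sd_tot = config.ionome_cv * mu
        g_eff = _scaled_effect(rng.normal(size=n_g), f_g * sd_tot**2)
        t_eff = _scaled_effect(rng.normal(size=n_t), f_t * sd_tot**2)
        gt = rng.normal(size=(n_g, n_t))
        gt -= gt.mean(axis=0, keepdims=True)
        gt -= gt.mean(axis=1, keepdims=True)
        v = gt.var()
        gt = gt * np.sqrt(f_gt * sd_tot**2 / v) if v > 0 else gt * 0.0
        resid = rng.normal(size=(n_g, n_t, n_r))
        # orthogonalize against the cell means and rescale so every
        # configured fraction is realized exactly in the sample
        resid -= resid.mean(axis=2, keepdims=True)
        rv = resid.var()
        resid = resid * np.sqrt(f_res * sd_tot**2 / rv) if rv > 0 else resid * 0.0
        vals = (mu + g_eff[:, None, None] + t_eff[None, :, None]
                + gt[:, :, None] + resid)
        for i, g in enumerate(genotypes):
            for j, trt in enumerate(config.treatments):
                for r in range(n_r):
                    rows.append((f"{g}.{trt.replace('/', '-')}.s{r}", g, trt, r,
                                 el, vals[i, j, r]))
        fracs_out[el] = (f_g, f_t, f_gt)
    ionome = pd.DataFrame(rows, columns=["sample_id", "genotype", "treatment",
                                         "rep", "element", "ppm"])
    return ionome, fracs_out


def _scaled_effect(x: np.ndarray, target_var: float) -> np.ndarray:
    x = x - x.mean()
    v = x.var()
    if v == 0 or target_var == 0:
        return np.zeros_like(x)
    return x * np.sqrt(target_var / v)


# ---------------------------------------------------------------------------
# image rendering

#: fixed background color (RGB uint8), hue ~220 deg — far outside the 0-120
#: plant band, so a threshold segmenter recovers the mask exactly
BACKGROUND_RGB = (46, 87, 169)


def render_plant_image(area_px: int, yellow_fraction: float,
                       canvas_size: tuple[int, int] = (256, 256),
                       seed: int = 0):
    """Render a synthetic plant: one connected blob of ``area_px`` pixels on a
    uniform blue background.

    Foreground hues are drawn from the two-peak yellow/green mixture so that
    the fraction of pixels in the [0, 60] degree band matches
    ``yellow_fraction`` to within rounding.  Returns ``(rgb uint8 image, bool
    mask)``.
    """
    from skimage.color import hsv2rgb

    h, w = canvas_size
    if area_px > h * w:
        raise ValueError(f"area {area_px} exceeds canvas {h * w} px")
    if not 0 <= yellow_fraction <= 1:
        raise ValueError("yellow_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = np.zeros((h, w), dtype=bool)
    if area_px > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        # mild anisotropy for a leaf-like blob; take the area_px closest
        # pixels by elliptical distance -> exact pixel count, connected
        d2 = ((yy - cy) / 1.3) ** 2 + (xx - cx) ** 2
        order = np.argsort(d2, axis=None, kind="stable")[:area_px]
        mask.flat[order] = True

    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = BACKGROUND_RGB
    if area_px > 0:
        n_yellow = int(round(yellow_fraction * area_px))
        hues = np.empty(area_px)
        hues[:n_yellow] = np.clip(rng.normal(_YELLOW_MODE, _HUE_SD, n_yellow), 2, 58)
        hues[n_yellow:] = np.clip(rng.normal(_GREEN_MODE, _HUE_SD, area_px - n_yellow),
                                  62, 118)
        rng.shuffle(hues)
        hsv = np.stack([hues / 360.0,
                        rng.uniform(0.6, 0.9, area_px),
                        rng.uniform(0.5, 0.9, area_px)], axis=1)
        rgb = (hsv2rgb(hsv[None, :, :])[0] * 255.0).round().astype(np.uint8)
        img[mask] = rgb
    return img, mask
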