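# Methods

`phenogxe` implements a temporal genotype-by-environment (G×E) analysis of
plant abiotic-stress phenotyping data: image-derived shape and color traits
measured daily for a genotype panel under contrasting nitrogen treatments,
followed by influence-based quality control, a color-band stress index,
early/late responder classification, and variance attribution for the leaf
ionome. Because the platform-scale raw data (tens of thousands of images)
are not desk-reproducible, the package ships a first-class synthetic
experiment generator with known ground truth; every analysis stage is
validated against that truth.

## The emulated experiment

The generator mimics a controlled-environment study: `n_genotypes` (default
30) sorghum-like genotypes under three nitrogen treatments labelled
`100/100`, `50/10`, `10/10` (full ammonium/nitrate down to 10%/10%), with
9/9/6 replicate plants respectively, imaged daily from day 8 to day 26.

**Growth.** Plant area (px) follows a per-genotype logistic curve
A/(1 + e^{−r(t − t₀)}) with asymptote A ~ lognormal(ln 40 000, 0.25),
rate r ~ U(0.30, 0.45) /day and inflection t₀ ~ U(16, 20). Each low-N
treatment carries a multiplicative penalty (defaults 0.65 for `50/10`,
0.45 for `10/10`) that is phased in geometrically over `ramp_days`
(default 5) starting at the genotype's *onset day* — so treatments
coincide before onset and diverge progressively after it. Onset days are
drawn from (10, 12) for the early half of the panel and (20, 22) for the
late half; "early" is defined as onset before the day-range midpoint.
Record noise is multiplicative lognormal with CV 0.2 (areas are positive
and spread grows with size, matching the fan-shaped replicate spread of
real growth data). Records are independent given the curve; the generator
does not model within-plant autocorrelation, diurnal movement, camera
zoom, or occlusion — so passing tests certify the statistical machinery,
not robustness to those imaging artifacts.

**Color.** Each plant-day histogram is a multinomial draw (one trial per
mask pixel) from a two-peak hue mixture: a yellow mode at 45° and a green
mode at 100° (σ = 6°, truncated away from the 60° band boundary). The
yellow mixing weight is a baseline 0.10 plus a Gaussian-in-time stress
bump centred on day 13 (σ = 3 days) whose amplitude grows as nitrogen
drops (0.10 / 0.28 / 0.38), plus a small per-genotype offset. This encodes
the observed kinetics — stress-induced yellowing that peaks mid-experiment
and is strongest under severe deprivation — without modelling leaf-level
spatial structure.

**Ionome.** For 19 leaf elements with realistic ppm magnitudes, values are
drawn from an additive model μ + g_i + t_j + (gt)_{ij} + ε with configured
variance fractions per element (e.g. Mo/Cd/Co genotype-dominated, P/K
treatment-dominated). Effect vectors are centred and rescaled, and the
residual is orthogonalized against the cell means, so the configured
fractions are realized *exactly* in each sample; recovery tests therefore
measure the estimator, not generator sampling noise.

**Outliers.** A configurable fraction of trait records is multiplied or
divided (50/50) by `outlier_magnitude`; flags are returned as ground truth.

**Rendered images.** `render_plant_image` paints a connected elliptical
blob with an exact pixel count on a uniform blue background (hue ≈ 220°,
far outside the 0–120° plant band), with foreground hues drawn from the
same two-peak mixture. The background is chosen so the threshold
segmenter recovers the mask exactly, isolating analysis testing from
segmentation quality.

## Image parameterization

Sixteen shape descriptors are computed per mask: area, hull area,
solidity, perimeter, width, height, longest axis, center of mass (x, y),
hull vertex count, and the moment-equivalent ellipse (center, major/minor
axis, angle, eccentricity). Conventions that pin down reproducible values:

- raster coordinates, origin top-left, 0-based pixel centers;
- `hull_area` counts the pixels of the filled convex hull
  (`skimage.morphology.convex_hull_image`), so `solidity = area/hull_area`
  is always in (0, 1] and a filled square scores exactly 1.0;
  `hull_vertices` and `longest_axis` (max pairwise vertex distance) come
  from the convex hull of pixel centers;
- perimeter is the crack-following boundary length (count of exposed unit
  pixel edges, holes included): deterministic and exactly invariant under
  90° rotation, unlike weighted pixel-count approximations;
- hue is canonically in degrees (0–360). 8-bit color-channel encodings
  (0–255, with hue stored as H/2) are never used as a bin scale;
- pixels with zero saturation or value have undefined hue: they are
  excluded from the bins but retained in the normalization denominator, so
  a normalized histogram sums to the defined-hue fraction of the mask.

## Quality control

**Image records.** Cook's distance on a cell-means linear model whose
cells are the genotype × treatment × day combinations (the three-way
interaction as the only effect). With leverage h = 1/n_cell the closed
form D_i = r_i²h / (p s² (1−h)²) is algebraically identical to the
leave-one-out fitted-shift definition, which the tests verify by
brute-force refitting. Records with influence above 4× the mean influence
(pooled over all non-singleton records) are removed. The filter runs on
log(area) by default: the growth noise is multiplicative, so raw-scale
residual variance scales with plant size and a pooled raw-scale s² would
drown early-day outliers under late-day noise; on the log scale the rule
is also exactly scale-invariant. `log_transform=False` restores the raw
response. At the default study conditions the filter removes ≈5% of
records, with sensitivity ≈1 against magnitude-5 corruption and a
false-flag rate well under 1%.

**Ionomic replicates.** Within each genotype × treatment × element group,
a measurement is excluded when |x − median| / MAD > 6.2, with
MAD = median(|x − median|) *unscaled* (no 1.4826 consistency constant —
the cutoff is calibrated for the raw statistic). Degenerate MAD = 0:
values different from the median are flagged (infinite score); identical
replicates pass. Whether the published cutoff was meant for a differently
standardized score is ambiguous; the statistic here is the raw MAD score
and the cutoff is exposed as a parameter.

## Color kinetics

Per-degree mean histograms with t-based 95% CIs are computed over
replicates (replicate counts are 6–9, so normal quantiles would be
anticonservative). Band areas use the trapezoidal rule on the integer
degree grid, endpoints inclusive: yellow = [0°, 60°], green = [61°, 120°].
The band pair deliberately omits the [60°, 61°] sliver — the published
ranges are kept verbatim rather than tidied; both bands are configurable.
Per-day group comparisons use Welch's t on per-plant band AUCs (groups of
unequal size and variance); SE bands in the AUC time series are over
plants, not over genotype means (the alternative is one `groupby` away).

## Responder classification

For each genotype and day, a one-way ANOVA (classic between/within SS
decomposition) compares area between `100/100` and `10/10`. The raw
p-values are Benjamini–Hochberg corrected **globally** across the whole
genotype × day matrix (not per row; configurable), stored alongside
−log10(q) (base-10, the conventional heatmap scale). Genotype q-vectors
are clustered with the Canberra distance — sensitive to differences in the
many near-zero q entries that distinguish response timing — under Ward's
minimum-variance linkage applied to the provided dissimilarities
(Lance–Williams recurrence). The k = 2 cut is labelled by mean onset day
(first day with q < 0.05; never-significant genotypes count one past the
last day); ties go to the cluster containing the first dendrogram leaf.
The onset threshold 0.05 and k are parameters. Under the default
conditions (onset separation ≥ 6 days) label recovery is ≈100% over
repeated experiments.

Growth rate is the per-plant least-squares slope of area on day over days
10–22, averaged over replicates with a t CI — identical to the mean daily
change for complete series but robust to days dropped by QC. End-size
ranking Welch-tests each genotype's day-26 replicates against the pooled
rest within a treatment, with BH across genotypes and a star at q < 0.01.

## Variance attribution

**Area.** A Gaussian linear mixed model on log area (same rationale as the
QC transform) with fixed effects G, E, G×E, G×T, E×T, G×E×T (T = day,
continuous and centred; the day main effect is included for hierarchy) and
a per-plant random intercept and slope over day. Each fixed effect gets a
Wald chi-square adjusted for all other terms (type III). Two small-sample
safeguards: (i) between-plant effects (G, E, G×E) are referred to an F
with containment (between-within) denominator degrees of freedom — plants
minus genotype×treatment cells — since the asymptotic chi-square is
anticonservative at panel sizes of tens of plants; (ii) when the fit does
not converge or the random-effects covariance estimate is singular (its
smallest eigenvalue below 10⁻⁴ of the residual variance — i.e. the data
show no extra within-plant correlation), the model falls back to the
fixed-effects-only OLS with exact F p-values, flagged `used_fallback` in
the result. The Wald statistic here is the standard quadratic form in the
estimated coefficients, not a refitting procedure. Simulations at a
4-genotype design hold the E-test size at 0.05 ± 0.02 and reach power
≈1.0 at p < 0.01 against a 0.45× treatment penalty.

**Ionome.** Per element, a two-factor genotype × treatment OLS with
sum-to-zero contrasts; type III SS for each term divided by the total SS
gives the variance fraction (partial η² against total — the "percent
variance explained" scale; on balanced designs this equals the sequential
type I partition, which the tests assert). Values below detection are used
as reported; no imputation.

**PCA.** Centered PCA via scikit-learn; unit-variance scaling for shape
features and elements (heterogeneous units), center-only for hue-fraction
bins (shared unit). Constant columns (e.g. the all-zero hue bins beyond
120°) are dropped with a warning before decomposition. Group 95%
confidence ellipses come from the 2-D score covariance scaled by the
χ²(2 df) 0.95 quantile.

## Numerical and design notes

- All generators take explicit integer seeds (`numpy.random.default_rng`
  with derived `SeedSequence`s); identical configurations produce
  byte-identical tables and hash-identical pipeline manifests.
- Simulation-based checks use reduced designs chosen to exercise the
  models at realistic effect sizes: responder-recovery runs use the full
  30-genotype layout; Wald error-rate simulations use 4 genotypes ×
  3 treatments × 4 replicates × 5 alternate days; null-FDR simulations use
  6 genotypes × 5 days.
- Empty masks raise `"no plant"`; masks with < 3 pixels return NaN for
  hull/ellipse fields; singleton QC cells get NaN influence and are
  excluded from the mean; zero within-group variance in the ANOVA returns
  the F → ∞, p → 0 limit explicitly.
- Known limitations: the segmenter assumes a uniform known background (no
  shadows or soil); the mixed model treats day as linear in its
  interactions; MAD screening needs ≥ 3 replicates; the generator's
  independence of records across days understates the serial correlation
  of real growth curves, which would widen real-data onset estimates.
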