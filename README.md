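# phenogxe

Temporal genotype-by-environment (G×E) analysis of plant abiotic-stress
responses from high-throughput phenotyping data.

When a diverse panel of genotypes is grown under contrasting nutrient
treatments and imaged daily, the interesting biology is not just *whether*
genotypes differ but *when* and *how fast* they respond. `phenogxe` is a
library plus CLI for that question, built around four analyses:

- **Trait extraction** — 16 shape descriptors (area, hull area, solidity,
  perimeter, width, height, longest axis, center of mass, hull vertices,
  moment-equivalent ellipse) and 360-bin per-degree hue histograms from an
  RGB image and its foreground mask.
- **Influence-based QC** — Cook's distance D_i = r_i²h / (p s²(1−h)²) on a
  genotype × treatment × day cell-means model; records above 4× the mean
  influence are removed. Ionomic replicates are screened with the unscaled
  MAD rule |x − median|/MAD > 6.2.
- **Color-stress kinetics** — normalized hue histograms averaged per group
  with 95% CIs, trapezoidal area under the yellow ([0°, 60°]) and green
  ([61°, 120°]) bands, AUC time series, treatment difference histograms,
  and per-day Welch tests.
- **Responder timing and variance attribution** — per-day one-way ANOVA of
  area between high and low nitrogen per genotype, global Benjamini–
  Hochberg FDR, −log10(q) heatmap vectors clustered with Canberra distance
  and Ward linkage, k = 2 cut into early/late responders; a mixed-model
  Wald ANOVA of area (fixed G, E, G×E, G×T, E×T, G×E×T; random per-plant
  intercept and slope over day); and per-element type III variance
  partitioning of the leaf ionome with PCA confidence ellipses.

Platform-scale raw data are rarely shareable, so the package includes a
synthetic experiment generator (logistic growth with treatment- and
genotype-dependent divergence onset, two-peak yellow/green hue mixtures,
an additive-effects ionome, injected outliers) that produces traits,
histograms, ionome tables, rendered PNG images — and the hidden ground
truth, so every stage is testable offline. See `docs/methods.md` for the
models and defaults.

## Worked example

```python
import numpy as np
from phenogxe import synthetic as syn, qc, timing, color

cfg = syn.ExperimentConfig(n_genotypes=8, reps_per_treatment=(6, 6, 4), seed=42)
traits, hues, ionome, truth = syn.generate_experiment(cfg)

filtered, influence, removed = qc.flag_influence_outliers(traits)
print(f"records: {len(traits)}, removed by influence filter: {100*removed:.2f}%")

labels, qmat, dend = timing.classify_responders(filtered)
agree = np.mean([labels.labels[g] == truth.responder_labels[g] for g in labels.labels])
print(f"responders: {sorted(g for g, l in labels.labels.items() if l == 'early')} early")
print(f"label agreement with ground truth: {100*agree:.0f}%")

series = color.auc_time_series(hues)
low = series[series.treatment == "10/10"]
peak = low.loc[low.yellow_auc.idxmax()]
print(f"yellow AUC peaks on day {int(peak.day)} at {peak.yellow_auc:.3f} (10/10 group)")
```

prints

```
records: 2432, removed by influence filter: 4.40%
responders: ['G00', 'G01', 'G02', 'G03'] early
label agreement with ground truth: 100%
yellow AUC peaks on day 13 at 0.486 (10/10 group)
```

A few percent of records exceed the 4×-mean influence threshold (the
filter's background removal rate on clean data); the dendrogram cut
recovers the generator's early/late onset partition exactly; and the
yellow band mass in the severe-deprivation group peaks mid-experiment on
day 13, the configured stress peak — the quantitative signature of
transient yellowing under nitrogen starvation.

The same stages are available as a CLI:

```bash
phenogxe simulate --out run/ --seed 1
phenogxe qc run/traits.csv --out run/filtered.csv --report run/qc.json
phenogxe timing run/filtered.csv --out run/qmatrix.csv --labels run/labels.csv
phenogxe color run/hues.csv --out run/auc.csv --diff run/diff.csv
phenogxe variance run/ionome.csv --per-element --out run/partitions.csv
phenogxe run --out run_all/ --seed 1      # full pipeline + manifest
```

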