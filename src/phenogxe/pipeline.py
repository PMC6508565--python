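"""End-to-end runner: simulate -> extract -> qc -> color -> timing -> variance.

Each stage reads and writes plain text tables under one output directory
and the run finishes with a JSON manifest recording seeds, row counts,
filtering decisions and content hashes, so identical configurations
produce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import color, features, io, qc, synthetic, timing, varpart

log = logging.getLogger("phenogxe")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (defaults follow the study's
    settings: 4x-mean influence cutoff, MAD cutoff 6.2, q < 0.05 onset,
    yellow [0,60] / green [61,120] bands, global BH, k = 2)."""

    outdir: str = "phenogxe_run"
    seed: int = 0
    experiment: synthetic.ExperimentConfig = field(
        default_factory=synthetic.ExperimentConfig)
    stages: tuple[str, ...] = ("simulate", "extract", "qc", "color",
                               "timing", "variance")
    n_render_images: int = 3        # images rendered + re-extracted per run
    influence_factor: float = 4.0
    mad_cutoff: float = 6.2
    q_threshold: float = 0.05
    treatment_pair: tuple[str, str] = ("100/100", "10/10")
    traits_path: str | None = None  # start from an existing table instead
    hues_path: str | None = None
    ionome_path: str | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns (and writes) the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    config.experiment.seed = config.seed

    traits = hues = ionome = None
    if "simulate" in config.stages:
        traits, hues, ionome, truth = synthetic.generate_experiment(config.experiment)
        io.write_trait_table(traits, out / "traits.csv")
        io.write_hue_table(hues, out / "hues.csv")
        io.write_ionome_table(ionome, out / "ionome.csv")
        (out / "ground_truth.json").write_text(json.dumps({
            "responder_labels": truth.responder_labels,
            "onset_days": truth.onset_days,
            "n_outliers": int(truth.outlier_flags.sum()),
        }, indent=2))
        manifest["stages"]["simulate"] = {
            "n_trait_records": len(traits),
            "n_outliers_injected": int(truth.outlier_flags.sum()),
        }
        log.info("simulate: %d trait records", len(traits))
    else:
        if config.traits_path is None:
            raise FileNotFoundError(
                "stage 'simulate' disabled and no traits_path given; "
                "the qc/timing stages need a trait table")
        traits = io.read_trait_table(config.traits_path)
        if config.hues_path:
            hues = io.read_hue_table(config.hues_path)
        if config.ionome_path:
            ionome = io.read_ionome_table(config.ionome_path)

    if "extract" in config.stages:
        rows = []
        rng = np.random.default_rng(config.seed)
        for i in range(config.n_render_images):
            area = int(rng.integers(2_000, 8_000))
            yf = float(rng.uniform(0.1, 0.5))
            img, mask = synthetic.render_plant_image(area, yf, seed=config.seed + i)
            io.write_image(out / f"plant_{i}.png", img)
            io.write_mask(out / f"plant_{i}_mask.png", mask)
            seg = features.segment_plant(img)
            rows.append(features.extract_shape_features(seg).as_dict())
        pd.DataFrame(rows).to_csv(out / "extracted_shapes.csv", index=False)
        manifest["stages"]["extract"] = {"n_images": config.n_render_images}

    if "qc" in config.stages:
        filtered, influence, removed = qc.flag_influence_outliers(
            traits, threshold_factor=config.influence_factor)
        io.write_trait_table(filtered, out / "traits_filtered.csv")
        manifest["stages"]["qc"] = {
            "n_removed": int(influence.flags.sum()),
            "removal_pct": round(100.0 * removed, 3),
        }
        log.info("qc: removed %.2f%% of records", 100 * removed)
        traits = filtered
        if ionome is not None:
            ionome_f, mflags = qc.mad_filter_ionome(ionome, cutoff=config.mad_cutoff)
            io.write_ionome_table(ionome_f, out / "ionome_filtered.csv")
            manifest["stages"]["qc"]["n_ionome_flags"] = int(mflags.sum())
            ionome = ionome_f

    labels = None
    if "timing" in config.stages:
        labels, qmat, dend = timing.classify_responders(
            traits, treatment_pair=config.treatment_pair,
            q_threshold=config.q_threshold)
        qmat.q.to_csv(out / "qmatrix.csv")
        pd.Series(labels.labels, name="label").rename_axis("genotype") \
            .to_csv(out / "responder_labels.csv")
        (out / "dendrogram.json").write_text(json.dumps({
            "merges": dend.merges.tolist(), "leaf_order": list(dend.leaf_order),
        }))
        rates = timing.growth_rate(traits)
        rates.to_csv(out / "growth_rates.csv")
        end = timing.end_size_outperformers(
            traits, day=int(traits["day"].max()))
        end.to_csv(out / "end_sizes.csv")
        manifest["stages"]["timing"] = {
            "n_early": sum(v == "early" for v in labels.labels.values()),
            "n_late": sum(v == "late" for v in labels.labels.values()),
        }

    if "color" in config.stages and hues is not None:
        if labels is not None:
            grp = hues.copy()
            grp["responder"] = grp["genotype"].map(labels.labels)
            grp["group"] = grp["responder"] + "|" + grp["treatment"]
            series = color.auc_time_series(grp, group_col="group")
        else:
            series = color.auc_time_series(hues, group_col="treatment")
        series.to_csv(out / "auc_series.csv", index=False)
        pair = config.treatment_pair
        diffs = {}
        for day, sub in hues.groupby("day"):
            mats = {t: color._normalized_hist_matrix(sub[sub["treatment"] == t])
                    for t in pair}
            if any(len(m) < 2 for m in mats.values()):
                continue
            diffs[int(day)] = color.difference_histogram(
                color.mean_histogram_with_ci(mats[pair[0]]),
                color.mean_histogram_with_ci(mats[pair[1]]))
        pd.DataFrame(diffs).T.rename_axis("day").to_csv(out / "diff_histograms.csv")
        manifest["stages"]["color"] = {"n_series_rows": len(series)}

    if "variance" in config.stages:
        wald = varpart.mixed_model_wald(traits)
        wald.as_frame().to_csv(out / "wald_area.csv")
        manifest["stages"]["variance"] = {
            "wald_fallback": wald.used_fallback,
        }
        if ionome is not None:
            parts = varpart.partition_all_elements(ionome)
            parts.to_csv(out / "variance_partitions.csv")
            wide = ionome.pivot_table(index="sample_id", columns="element",
                                      values="ppm")
            wide = wide.dropna()  # samples losing an element to MAD filtering
            meta = ionome.drop_duplicates("sample_id").set_index("sample_id")
            pca = varpart.pca_with_ellipses(wide.to_numpy(),
                                            meta.loc[wide.index, "treatment"])
            manifest["stages"]["variance"]["ionome_pc1_pct"] = round(
                float(pca.explained_pct[0]), 2)

    for p in sorted(out.iterdir()):
        if p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
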