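"""End-to-end orchestration of the analysis stages.

metrics per viewing distance -> missing-value row filter -> Pearson
decorrelation -> parallel analysis -> varimax EFA (+ bootstrap loading CIs)
-> defence classification -> one distributional Student model per factor ->
convergence diagnostics -> pairwise contrasts. Every stage's output is
persisted as CSV/JSON and a manifest records the configuration, seeds and
drop counts so a run is fully reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .defence import classify_table
from .factors import (ExploratoryFactorAnalysis, bootstrap_loadings,
                      correlation_filter, drop_invalid, parallel_analysis)
from .io import read_image, write_metric_table
from .metrics import METRIC_REGISTRY, full_qcpa
from .phylo import PhyloDistributionalStudent, phylo_correlation
from .vision import VisualSystem

logger = logging.getLogger(__name__)

MINOR_LOADING = 0.4  # loadings below this magnitude are reported as minor


@dataclass
class RunConfig:
    """Pipeline defaults; the visual-model constants are the study's printed values."""

    abundances: tuple = (1.0, 2.0, 2.0, 2.0)
    noise: float = 0.05
    acuity_cpd: float = 3.0
    chrom_threshold: float = 2.0
    lum_threshold: float = 4.0
    ranked_falloff: int = 3
    ranked_radius: int = 5
    ranked_repetitions: int = 5
    distances_mm: tuple = (20.0, 100.0)
    r_max: float = 0.6
    parallel_n_random: int = 10000
    n_bootstrap: int = 1000
    mcmc_chains: int = 4
    mcmc_post_warmup: int = 8000
    mcmc_walkers: int = 100
    mcmc_warmup_steps: int = 3000
    mcmc_thin: int = 120
    seed: int = 0

    def visual_system(self) -> VisualSystem:
        return VisualSystem(self.abundances, self.noise, self.acuity_cpd,
                            self.chrom_threshold, self.lum_threshold)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in asdict(self).items()}, fh)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for k in ("abundances", "distances_mm"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def compute_metrics(images, config: RunConfig):
    """Run the full QCPA stack on every image at every viewing distance."""
    vs = config.visual_system()
    vectors = []
    for img in images:
        for dist in config.distances_mm:
            vectors.append(full_qcpa(img, vs, dist,
                                     config.ranked_falloff,
                                     config.ranked_radius,
                                     config.ranked_repetitions))
    return vectors


def run_pipeline(config: RunConfig, images, species_map, assay_df, tree,
                 out_dir, n_factors=None) -> dict:
    """Execute all stages on in-memory inputs and persist artefacts.

    images: list of ConeCatchImage; species_map: image id -> species;
    assay_df: raw assay table; tree: dendropy.Tree or Newick string.
    Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed, "stages": []}
    config.to_yaml(out / "config.yaml")

    # stage 1: metrics
    vectors = compute_metrics(images, config)
    metrics = write_metric_table(vectors, species_map, out / "metrics.csv")
    manifest["stages"].append({"stage": "metrics", "n_rows": len(metrics)})

    # stage 2: missing-value filter + decorrelation
    kept, report = drop_invalid(metrics)
    filtered, kept_cols = correlation_filter(kept, r_max=config.r_max)
    filtered.to_csv(out / "metrics_filtered.csv", index=False)
    manifest["stages"].append({"stage": "filter", "n_dropped": report["n_removed"],
                               "dropped_ids": report["removed_ids"],
                               "n_metrics_kept": len(kept_cols),
                               "metrics_kept": kept_cols})

    # stage 3: factor retention + EFA + bootstrap
    X = filtered[kept_cols]
    if n_factors is None:
        n_factors = max(parallel_analysis(X.to_numpy(), config.parallel_n_random,
                                          seed=config.seed), 1)
    model = ExploratoryFactorAnalysis(n_factors=n_factors).fit(X)
    lo, hi, skipped = bootstrap_loadings(X, n_factors, config.n_bootstrap,
                                         seed=config.seed, reference=model)
    loadings = []
    for i, m in enumerate(kept_cols):
        for j in range(n_factors):
            loadings.append({"metric": m, "factor": j + 1,
                             "loading": model.loadings_[i, j],
                             "ci_lo": lo[i, j], "ci_hi": hi[i, j],
                             "minor": abs(model.loadings_[i, j]) < MINOR_LOADING})
    pd.DataFrame(loadings).to_csv(out / "loadings.csv", index=False)
    scores = model.transform(X)
    sc = filtered[["id", "species", "distance_mm"]].copy()
    for j in range(n_factors):
        sc[f"factor{j + 1}"] = scores[:, j]
    sc.to_csv(out / "scores.csv", index=False)
    manifest["stages"].append({
        "stage": "efa", "n_factors": int(n_factors),
        "explained_variance": [float(v) for v in model.explained_variance_ratio_],
        "bootstrap_skipped": skipped})

    # stage 4: defence classes
    classes = classify_table(assay_df)
    classes.to_csv(out / "defence_classes.csv", index=False)
    manifest["stages"].append({"stage": "classify",
                               "classes": classes["defence"].value_counts().to_dict()})

    # stage 5: distributional models (one per factor)
    species_order = sorted(set(sc["species"]))
    A, species_order = phylo_correlation(tree, species_order)
    cls_map = dict(zip(classes["species"], classes["defence"]))
    contrasts_all, diag_all = [], []
    draws_per_chain = config.mcmc_post_warmup // config.mcmc_chains
    root = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(n_factors)]
    for j in range(n_factors):
        data = sc.rename(columns={f"factor{j + 1}": "score"})[
            ["score", "species", "distance_mm"]].copy()
        data["defence"] = data["species"].map(cls_map)
        fit = PhyloDistributionalStudent(
            chains=config.mcmc_chains, draws_per_chain=draws_per_chain,
            n_walkers=config.mcmc_walkers, warmup_steps=config.mcmc_warmup_steps,
            thin=config.mcmc_thin, random_state=seeds[j],
        ).fit(data, A=A, species_order=species_order)
        ct = fit.contrasts()
        ct.insert(0, "factor", j + 1)
        contrasts_all.append(ct)
        dg = fit.diagnostics()
        dg.insert(0, "factor", j + 1)
        diag_all.append(dg)
        cs = fit.cell_summary()
        cs.insert(0, "factor", j + 1)
        cs.to_csv(out / f"cells_factor{j + 1}.csv", index=False)
    pd.concat(contrasts_all).to_csv(out / "contrasts.csv", index=False)
    diag = pd.concat(diag_all)
    diag.to_csv(out / "diagnostics.csv", index=False)
    manifest["stages"].append({
        "stage": "fit",
        "seeds": seeds,
        "all_pass": bool(diag["pass"].all()),
        "max_rhat": float(diag["rhat"].max())})
    manifest["stages"].append({"stage": "contrasts",
                               "n_rows": int(sum(len(c) for c in contrasts_all))})

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_images(image_dir, samples_csv):
    """Load a directory of TIFF/PNG images described by a samples table
    (columns: id, species, px_per_mm)."""
    samples = pd.read_csv(samples_csv)
    images, species_map = [], {}
    for r in samples.itertuples():
        img = read_image(Path(image_dir) / f"{r.id}.tif", r.px_per_mm, r.id)
        images.append(img)
        species_map[r.id] = r.species
    return images, species_map


def report(out_dir) -> str:
    """Plain-text summary regenerated from a completed run's artefacts."""
    out = Path(out_dir)
    for f in ("manifest.json", "loadings.csv", "contrasts.csv", "diagnostics.csv"):
        if not (out / f).exists():
            raise FileNotFoundError(f"missing artefact {f} in {out}")
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    loadings = pd.read_csv(out / "loadings.csv")
    contrasts = pd.read_csv(out / "contrasts.csv")
    diag = pd.read_csv(out / "diagnostics.csv")
    lines = [f"qcpattern run (version {manifest['version']}, seed {manifest['seed']})"]
    for st in manifest["stages"]:
        lines.append(f"  stage {st['stage']}: " +
                     ", ".join(f"{k}={v}" for k, v in st.items()
                               if k not in ("stage", "dropped_ids", "metrics_kept")))
    lines.append("major loadings (|loading| >= %.1f):" % MINOR_LOADING)
    major = loadings[~loadings["minor"]]
    for r in major.itertuples():
        lines.append(f"  factor {r.factor}: {r.metric} = {r.loading:+.2f} "
                     f"[{r.ci_lo:+.2f}, {r.ci_hi:+.2f}]")
    lines.append("convergence: max R-hat %.4f, all pass: %s"
                 % (diag["rhat"].max(), bool(diag["pass"].all())))
    lines.append("mean contrasts with 95%% CI excluding 0: %d / %d"
                 % (((contrasts.kind == "mean")
                     & ((contrasts.ci_lo > 0) | (contrasts.ci_hi < 0))).sum(),
                    (contrasts.kind == "mean").sum()))
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text
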