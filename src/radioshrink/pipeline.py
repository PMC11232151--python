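"""End-to-end pipeline: simulate -> preprocess -> extract -> train ->
predict -> stratify -> survival -> genomics, with a reproducibility
manifest of per-stage artifact digests.

The global seed is expanded per stage through named substreams so every
stage is independently reproducible and insensitive to which other stages
run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import genomics as genomics_mod
from . import survival as survival_mod
from .cohort import CohortConfig, generate_cohort, patient_images
from .features import DiscretizationSpec, extract_all, vectors_to_frame, wide_feature_table
from .imaging import PreprocessConfig, SegmentationFailure, preprocess_pair, resample_isotropic, VolumeImage
from .multitask import (ForestHyperparams, collinearity_filter, evaluate_auc,
                        fit_multitask_forest, joint_importance, predict,
                        select_common_subset, split_development)

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess_extract", "train", "predict", "stratify",
          "survive", "genomics")


def _strict_update(obj, overrides: dict, context: str):
    known = {f.name for f in dataclasses.fields(obj)}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    for k, v in overrides.items():
        setattr(obj, k, tuple(v) if isinstance(getattr(obj, k), tuple) else v)
    obj.__post_init__() if hasattr(obj, "__post_init__") else None
    return obj


@dataclass
class ModelConfig:
    r_threshold: float = 0.9
    train_fraction: float = 0.66
    k_grid: tuple[int, ...] = (4, 8, 12, 17, 24)
    n_trees: int = 100
    max_depth: int = 6
    min_leaf: int = 3
    selection_n_trees: int = 25

    def __post_init__(self):
        self.k_grid = tuple(int(k) for k in self.k_grid)


@dataclass
class GenomicsConfig:
    min_expressed_fraction: float = 0.20
    top_variance_n: int = 2000
    alpha: float = 0.05
    n_gene_sets: int = 20

    def __post_init__(self):
        pass


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "pipeline_out"
    stages: tuple[str, ...] = STAGES
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    discretization: DiscretizationSpec = field(default_factory=DiscretizationSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    genomics: GenomicsConfig = field(default_factory=GenomicsConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        cfg = cls()
        nested = {"cohort": CohortConfig, "preprocess": PreprocessConfig,
                  "discretization": DiscretizationSpec, "model": ModelConfig,
                  "genomics": GenomicsConfig}
        for key, klass in nested.items():
            if key in raw:
                sub = raw.pop(key)
                if key == "discretization":
                    setattr(cfg, key, DiscretizationSpec(**sub))
                else:
                    _strict_update(getattr(cfg, key), sub, key)
        top_known = {"seed", "out_dir", "stages"}
        unknown = set(raw) - top_known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        for k in top_known & set(raw):
            setattr(cfg, k, tuple(raw[k]) if k == "stages" else raw[k])
        bad = set(cfg.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def canonical(self) -> str:
        """Canonical JSON of the scientific configuration; the output
        location does not change what is computed, so it is excluded."""
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if isinstance(obj, np.integer):
                return int(obj)
            return obj
        payload = enc(self)
        payload.pop("out_dir", None)
        return json.dumps(payload, sort_keys=True)


def demo_config(out_dir: str = "pipeline_out", seed: int = 0) -> PipelineConfig:
    """The reference demonstration configuration: 120 patients with small
    volumes on a 1.5 mm working grid, a reduced k-grid and a light selection
    forest so the full chain runs end to end on one CPU in a few minutes."""
    return PipelineConfig.from_dict({
        "seed": seed,
        "out_dir": out_dir,
        "cohort": {"n_patients": 120},
        "preprocess": {"target_spacing_mm": 1.5},
        "model": {"k_grid": [4, 8, 12, 17], "n_trees": 100,
                  "selection_n_trees": 15},
        "genomics": {"top_variance_n": 2000},
    })


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31 - 1)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)  # stage -> {status, digests, seconds}
    versions: dict = field(default_factory=dict)

    def digests(self) -> dict:
        return {s: info.get("digests", {}) for s, info in self.stages.items()}

    def to_json(self) -> str:
        return json.dumps({"config_hash": self.config_hash, "seed": self.seed,
                           "stages": self.stages, "versions": self.versions},
                          indent=2, sort_keys=True)


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Run all enabled stages, writing artifacts and the manifest under
    ``cfg.out_dir``. Re-running with the same config reproduces every
    digest bit-identically."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.cohort.seed = cfg.seed
    import numpy, scipy, pandas, skimage, lifelines  # noqa: versions for the manifest
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg.canonical().encode()).hexdigest(),
        seed=cfg.seed,
        versions={"numpy": numpy.__version__, "scipy": scipy.__version__,
                  "pandas": pandas.__version__, "scikit-image": skimage.__version__,
                  "lifelines": lifelines.__version__},
    )

    state: dict = {}

    def record(stage: str, paths: list[Path], t0: float) -> None:
        manifest.stages[stage] = {
            "status": "completed",
            "digests": {p.name: _digest_file(p) for p in sorted(paths)},
            "seconds": round(time.time() - t0, 3),
        }

    for stage in STAGES:
        if stage not in cfg.stages:
            manifest.stages[stage] = {"status": "skipped"}
            continue
        t0 = time.time()
        try:
            paths = _STAGE_FUNCS[stage](cfg, state, out)
        except Exception:
            manifest.stages[stage] = {"status": "failed",
                                      "seconds": round(time.time() - t0, 3)}
            (out / "manifest.json").write_text(manifest.to_json())
            raise
        record(stage, paths, t0)

    # timings vary run to run; digests are the reproducibility contract
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: PipelineConfig, state: dict, out: Path) -> list[Path]:
    cohort = generate_cohort(cfg.cohort)
    state["cohort"] = cohort
    cohort_mod.write_cohort(cohort, out)
    return [out / "manifest.csv", out / "expression.tsv", out / "ground_truth.json"]


def _load_cohort(cfg: PipelineConfig, state: dict):
    if "cohort" not in state:
        state["cohort"] = generate_cohort(cfg.cohort)
    return state["cohort"]


def _stage_preprocess_extract(cfg: PipelineConfig, state: dict, out: Path) -> list[Path]:
    cohort = _load_cohort(cfg, state)
    frames = []
    n_fallback = 0
    for pid in cohort.manifest.index:
        images = patient_images(cohort, pid)
        for tp_key, tp_name in (("pre", "pre"), ("early", "earlyNAC")):
            bundle = images[tp_key]
            true_mask = VolumeImage(bundle["mask"].astype(float),
                                    cfg.cohort.voxel_spacing_mm)
            mask_r = resample_isotropic(true_mask, cfg.preprocess.target_spacing_mm,
                                        is_mask=True).values.astype(bool)
            box = _bounding_box(mask_r, pad=6)
            try:
                triplet, masks = preprocess_pair(bundle["s0"], bundle["sm"],
                                                 cfg.preprocess, init_box=box)
            except SegmentationFailure:
                n_fallback += 1
                triplet, masks = preprocess_pair(bundle["s0"], bundle["sm"],
                                                 cfg.preprocess,
                                                 tumor_mask=mask_r)
            frames.append(vectors_to_frame(
                extract_all(triplet, masks, pid, tp_name, cfg.discretization)))
    long = pd.concat(frames, ignore_index=True)
    if n_fallback:
        log.warning("FCM segmentation fell back to the reference mask for "
                    "%d timepoints", n_fallback)
    long.to_csv(out / "features.csv", index=False)
    state["features_long"] = long
    return [out / "features.csv"]


def _bounding_box(mask: np.ndarray, pad: int) -> tuple[slice, slice, slice]:
    idx = np.argwhere(mask)
    if len(idx) == 0:
        return tuple(slice(0, s) for s in mask.shape)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _stage_train(cfg: PipelineConfig, state: dict, out: Path) -> list[Path]:
    cohort = state["cohort"]
    wide = wide_feature_table(state["features_long"])
    wide = wide.loc[cohort.manifest.index]
    labels = cohort.manifest[["cs", "pcr"]]
    seed = _stage_seed(cfg.seed, "train")

    train_idx, val_idx = split_development(wide, labels,
                                           frac=cfg.model.train_fraction, seed=seed)
    X_train = wide.iloc[train_idx]
    y_train = labels.iloc[train_idx]
    # impute before the correlation screen so constant/NaN columns are handled
    X_imp = X_train.fillna(X_train.median()).fillna(0.0)
    filtered, removal_log = collinearity_filter(X_imp, cfg.model.r_threshold)

    hp = ForestHyperparams(n_trees=cfg.model.n_trees, max_depth=cfg.model.max_depth,
                           min_leaf=cfg.model.min_leaf)
    ranking_model = fit_multitask_forest(filtered, y_train, hp, seed=seed)
    ranking = joint_importance(ranking_model)
    sel_hp = ForestHyperparams(n_trees=cfg.model.selection_n_trees,
                               max_depth=cfg.model.max_depth,
                               min_leaf=cfg.model.min_leaf)
    selection = select_common_subset(filtered, y_train, ranking,
                                     k_grid=cfg.model.k_grid, seed=seed,
                                     hyperparams=sel_hp)
    final = fit_multitask_forest(filtered[selection.chosen_features], y_train,
                                 hp, seed=seed)
    state.update(model=final, selection=selection, wide=wide, labels=labels,
                 train_idx=train_idx, val_idx=val_idx)

    (out / "model.json").write_text(final.to_json())
    selection.loocv_curve.to_csv(out / "selection_curve.csv", index=False)
    pd.DataFrame(removal_log).to_csv(out / "collinearity_log.csv", index=False)
    pd.Series(selection.chosen_features, name="feature").to_csv(
        out / "signature.csv", index=False)
    return [out / "model.json", out / "selection_curve.csv",
            out / "collinearity_log.csv", out / "signature.csv"]


def _stage_predict(cfg: PipelineConfig, state: dict, out: Path) -> list[Path]:
    scores = predict(state["model"], state["wide"][state["selection"].chosen_features])
    scores.index.name = "patient_id"
    state["scores"] = scores
    labels = state["labels"]
    val = state["val_idx"]
    seed = _stage_seed(cfg.seed, "predict")
    rows = []
    for task in scores.columns:
        rep = evaluate_auc(scores.iloc[val][task], labels.iloc[val][task],
                           n_boot=500, seed=seed)
        rows.append({"task": task, "auc": rep.auc, "ci_low": rep.ci_low,
                     "ci_high": rep.ci_high, "sensitivity": rep.sensitivity,
                     "specificity": rep.specificity, "precision": rep.precision,
                     "f1": rep.f1})
    pd.DataFrame(rows).to_csv(out / "validation_metrics.csv", index=False)
    scores.to_csv(out / "scores.csv")
    return [out / "scores.csv", out / "validation_metrics.csv"]


def _stage_stratify(cfg: PipelineConfig, state: dict, out: Path) -> list[Path]:
    cohort = state["cohort"]
    scores = state["scores"]
    surv = cohort.manifest.rename(columns={"os_months": "time", "os_event": "event"})
    cut_cs = survival_mod.optimal_cutoff_logrank(scores["cs"], surv)
    cut_pcr = survival_mod.optimal_cutoff_logrank(scores["pcr"], surv)
    thresholds = survival_mod.StratificationThresholds(
        cs_threshold=cut_cs["threshold"], pcr_threshold=cut_pcr["threshold"])
    groups = survival_mod.stratify(scores, thresholds)
    state["groups"] = groups
    state["thresholds"] = thresholds
    frame = groups.to_frame()
    frame["p_cs"] = scores["cs"]
    frame["p_pcr"] = scores["pcr"]
    frame.index.name = "patient_id"
    frame.to_csv(out / "stratification.csv")
    (out / "thresholds.json").write_text(json.dumps(
        {"cs_threshold": thresholds.cs_threshold,
         "pcr_threshold": thresholds.pcr_threshold,
         "cs_cutoff_p": cut_cs["p_value"], "pcr_cutoff_p": cut_pcr["p_value"]},
        indent=2))
    return [out / "stratification.csv", out / "thresholds.json"]


def _stage_survive(cfg: PipelineConfig, state: dict, out: Path) -> list[Path]:
    cohort = state["cohort"]
    groups = state["groups"]
    paths = []
    covariates = ["age", "pr", "her2", "diameter_mm"]
    summary_rows = []
    for endpoint, tc, ec in (("os", "os_months", "os_event"),
                             ("rfs", "rfs_months", "rfs_event")):
        records = cohort.manifest.rename(columns={tc: "time", ec: "event"})
        records = survival_mod.censor_at(records, cfg.cohort.admin_censor_months)
        res = survival_mod.three_group_analysis(groups, records)
        km_frames = []
        for g, km in res["km"].items():
            km = km.copy()
            km.insert(0, "group", g)
            km_frames.append(km)
        pd.concat(km_frames, ignore_index=True).to_csv(
            out / f"km_{endpoint}.csv", index=False)
        res["pairwise"].to_csv(out / f"pairwise_logrank_{endpoint}.csv", index=False)
        records = records.assign(
            predicted_cs=(groups >= 2).astype(int),
            predicted_pcr=(groups == 3).astype(int))
        for exposure in ("predicted_cs", "predicted_pcr"):
            cox = survival_mod.cox_fit(records, covariates, exposure)
            summary_rows.append({
                "endpoint": endpoint, "exposure": exposure, "hr": cox.hr,
                "ci_low": cox.ci_low, "ci_high": cox.ci_high,
                "wald_p": cox.wald_p, "lr_p": cox.lr_p,
                "overall_logrank_p": res["overall"]["p_value"],
            })
        paths += [out / f"km_{endpoint}.csv", out / f"pairwise_logrank_{endpoint}.csv"]
    pd.DataFrame(summary_rows).to_csv(out / "cox_summary.csv", index=False)
    paths.append(out / "cox_summary.csv")
    return paths


def _stage_genomics(cfg: PipelineConfig, state: dict, out: Path) -> list[Path]:
    cohort = state["cohort"]
    groups = state.get("groups")
    if groups is None:  # genomics can run against the true groups alone
        groups = pd.Series(cohort.truth.group, index=cohort.manifest.index)
    gcfg = genomics_mod.GeneFilterConfig(
        min_expressed_fraction=cfg.genomics.min_expressed_fraction,
        top_variance_n=cfg.genomics.top_variance_n)
    filtered, filter_log = genomics_mod.filter_genes(cohort.expression, gcfg)
    assoc = genomics_mod.associate_genes(filtered, groups, alpha=cfg.genomics.alpha)
    anova = genomics_mod.anova_groups(filtered, groups)
    rng = np.random.default_rng(_stage_seed(cfg.seed, "genomics"))
    gene_sets = cohort_mod.synthetic_gene_sets(
        list(cohort.expression.index), cohort.truth.trend_genes, rng,
        n_sets=cfg.genomics.n_gene_sets)
    universe = set(filtered.index) & set().union(*gene_sets.values())
    significant = set(assoc.index[assoc["significant"]]) & universe
    results = genomics_mod.enrich_pathways(significant, universe, gene_sets)
    table = genomics_mod.enrichment_table(results)

    assoc.to_csv(out / "gene_association.csv")
    anova.to_csv(out / "gene_anova.csv")
    table.to_csv(out / "enrichment.csv", index=False)
    (out / "genomics_log.json").write_text(json.dumps(
        {**filter_log, "n_significant": len(significant),
         "n_universe": len(universe)}, indent=2))
    return [out / "gene_association.csv", out / "gene_anova.csv",
            out / "enrichment.csv", out / "genomics_log.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess_extract": _stage_preprocess_extract,
    "train": _stage_train,
    "predict": _stage_predict,
    "stratify": _stage_stratify,
    "survive": _stage_survive,
    "genomics": _stage_genomics,
}


def report(out_dir: str | Path) -> str:
    """Deterministic, human-readable summary rendered from artifacts only."""
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(
            f"no manifest at {manifest_path}; run the pipeline first")
    manifest = json.loads(manifest_path.read_text())
    lines = [f"run config hash: {manifest['config_hash'][:12]}  seed: {manifest['seed']}", ""]
    metrics = out / "validation_metrics.csv"
    if metrics.exists():
        df = pd.read_csv(metrics)
        lines.append("validation performance (inner validation split)")
        header = f"{'task':<6}{'AUC (95% CI)':<24}{'Sens':>7}{'Spec':>7}{'Prec':>7}{'F1':>7}"
        lines.append(header)
        for _, r in df.iterrows():
            ci = f"{r['auc']:.3f} ({r['ci_low']:.3f}-{r['ci_high']:.3f})"
            lines.append(f"{r['task']:<6}{ci:<24}{r['sensitivity']:>7.3f}"
                         f"{r['specificity']:>7.3f}{r['precision']:>7.3f}{r['f1']:>7.3f}")
        lines.append("")
    cox = out / "cox_summary.csv"
    if cox.exists():
        df = pd.read_csv(cox)
        lines.append("Cox models (adjusted for age, PR, HER2, diameter)")
        for _, r in df.iterrows():
            lines.append(f"  {r['endpoint'].upper():<4} {r['exposure']:<14} "
                         f"HR {r['hr']:.3f} ({r['ci_low']:.3f}-{r['ci_high']:.3f}) "
                         f"p={r['wald_p']:.4g} LR p={r['lr_p']:.4g}")
        lines.append(f"  overall 3-group log-rank p (OS): "
                     f"{df.loc[df.endpoint == 'os', 'overall_logrank_p'].iloc[0]:.4g}")
        lines.append("")
    enr = out / "enrichment.csv"
    if enr.exists():
        df = pd.read_csv(enr).head(5)
        lines.append("top enriched pathways")
        for _, r in df.iterrows():
            lines.append(f"  {r['pathway']:<28} p={r['p_value']:.3g} "
                         f"corrected={r['corrected_p']:.3g} markers={r['gene_markers']}")
        lines.append("")
    skipped = [s for s, info in manifest["stages"].items()
               if info.get("status") == "skipped"]
    if skipped:
        lines.append(f"skipped stages: {', '.join(skipped)}")
    return "\n".join(lines) + "\n"
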