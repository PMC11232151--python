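"""Synthetic study generator.

Produces a full cohort with known ground truth: paired pre-treatment and
early-NAC tumour volumes following the concentric/non-concentric shrinkage
taxonomy, correlated binary outcomes (CS, pCR), group-dependent survival
with 10-year administrative censoring, and gene expression with planted
monotone trends across the three response groups. Every downstream stage of
the pipeline is testable against the planted truth without any external
download.

Patients fall into three groups: 1 = nonpCR and non-CS, 2 = nonpCR and CS,
3 = pCR. pCR is a subtype of concentric shrinkage, so by default every pCR
patient is also CS.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import VolumeImage

GROUP_NONCS = 1
GROUP_CS = 2
GROUP_PCR = 3

NONCS_SUBTYPES = ("diffuse_decrease", "enlargement", "intensity_decrease", "no_change")

# independent substreams of the cohort seed
_STREAM_LABELS, _STREAM_IMAGES, _STREAM_FEATURES, _STREAM_SURVIVAL, _STREAM_EXPRESSION = range(5)


class CohortConfigError(ValueError):
    """An impossible or inconsistent cohort configuration."""


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    Prevalences default to the development-cohort values (CS 77.3%,
    pCR 26.7%); survival hazards are monthly exponential rates obeying
    pCR < CS&nonpCR < nonCS&nonpCR, with administrative censoring at
    120 months.
    """

    n_patients: int = 120
    cs_prevalence: float = 0.773
    pcr_prevalence: float = 0.267
    pcr_implies_cs: bool = True
    seed: int = 0
    image_shape: tuple[int, int, int] = (36, 36, 24)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)
    n_noise_features: int = 50
    n_shared_signal_features: int = 5
    signal_effect_size: float = 1.5
    feature_correlation: float = 0.2
    hazard_by_group: tuple[float, float, float] = (0.012, 0.005, 0.002)  # groups 1,2,3 per month
    rfs_hazard_multiplier: float = 1.5
    admin_censor_months: float = 120.0
    n_genes: int = 400
    n_trend_genes: int = 20
    expression_trend_effect: float = 1.0
    expression_missing_gene_fraction: float = 0.05
    low_expressed_gene_fraction: float = 0.10
    image_noise_sigma: float = 5.0
    tumor_enhancement: float = 80.0
    parenchyma_enhancement: float = 20.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise CohortConfigError("n_patients must be positive")
        for name in ("cs_prevalence", "pcr_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortConfigError(f"{name} must lie in [0, 1]")
        if self.pcr_implies_cs and self.pcr_prevalence > self.cs_prevalence:
            raise CohortConfigError(
                "pcr_prevalence exceeds cs_prevalence, impossible when every "
                "pCR patient shows concentric shrinkage")
        h1, h2, h3 = self.hazard_by_group
        if not (h3 < h2 < h1) or h3 <= 0:
            raise CohortConfigError(
                "hazards must be positive with ordering pCR < CS&nonpCR < nonCS&nonpCR "
                "(hazard_by_group is given for groups 1, 2, 3)")
        if self.n_trend_genes > self.n_genes:
            raise CohortConfigError("n_trend_genes cannot exceed n_genes")
        if min(self.n_noise_features, self.n_shared_signal_features) < 0:
            raise CohortConfigError("feature counts must be non-negative")
        if self.admin_censor_months < 0:
            raise CohortConfigError("admin_censor_months must be non-negative")
        self.image_shape = tuple(int(s) for s in self.image_shape)
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)


@dataclass
class GroundTruth:
    group: np.ndarray                    # per-patient code in {1, 2, 3}
    signal_features: list[str]
    trend_genes: list[str]
    trend_signs: dict[str, int]
    noncs_subtypes: dict[str, str] = field(default_factory=dict)


def _rng(cfg: CohortConfig, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream, *extra]))


def _patient_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


# ---------------------------------------------------------------------------
# labels

def generate_labels(cfg: CohortConfig) -> pd.DataFrame:
    """Paired binary labels and group codes.

    Under ``pcr_implies_cs``, pCR is drawn first and non-pCR patients get CS
    with the conditional probability that restores the configured marginal.
    Otherwise the two labels are drawn independently.
    """
    rng = _rng(cfg, _STREAM_LABELS)
    n = cfg.n_patients
    pcr = rng.random(n) < cfg.pcr_prevalence
    if cfg.pcr_implies_cs:
        if cfg.pcr_prevalence < 1.0:
            p_cs_given_nonpcr = ((cfg.cs_prevalence - cfg.pcr_prevalence)
                                 / (1.0 - cfg.pcr_prevalence))
        else:
            p_cs_given_nonpcr = 0.0
        cs = pcr | (rng.random(n) < p_cs_given_nonpcr)
    else:
        cs = rng.random(n) < cfg.cs_prevalence
    group = np.where(pcr, GROUP_PCR, np.where(cs, GROUP_CS, GROUP_NONCS))
    return pd.DataFrame({"cs": cs.astype(int), "pcr": pcr.astype(int),
                         "group": group}, index=_patient_ids(n))


# ---------------------------------------------------------------------------
# images

def _ellipsoid_mask(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) * sp for s, sp in zip(shape, spacing)],
                        indexing="ij")
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center_mm, radii_mm):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def _lobe_params(rng, n_lobes):
    """Surface-lobe geometry in units of the base ellipsoid (so lobes scale
    with the tumour under concentric shrinkage)."""
    lobes = []
    for _ in range(n_lobes):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        lobes.append((direction, rng.uniform(0.25, 0.5)))
    return lobes


def _composite_mask(shape, spacing, center_mm, radii_mm, lobes,
                    scale: float = 1.0) -> np.ndarray:
    radii = np.asarray(radii_mm) * scale
    out = _ellipsoid_mask(shape, spacing, center_mm, radii)
    for direction, rel_r in lobes:
        lobe_center = np.asarray(center_mm) + direction * radii
        lobe_r = rel_r * radii.min()
        out |= _ellipsoid_mask(shape, spacing, lobe_center, (lobe_r,) * 3)
    return out


def _texture(shape, rng, sigma_vox: float, amplitude: float) -> np.ndarray:
    if amplitude == 0:
        return np.zeros(shape)
    noise = rng.normal(size=shape)
    if sigma_vox > 0:
        noise = ndimage.gaussian_filter(noise, sigma_vox)
        noise /= max(noise.std(), 1e-12)
    return amplitude * noise


def generate_image_pair(group_code: int, cfg: CohortConfig,
                        rng: np.random.Generator,
                        subtype: str | None = None) -> dict:
    """One patient's pre-treatment and early-NAC S0/SM volumes plus masks.

    The pre-treatment tumour is an axis-aligned ellipsoid with small surface
    lobes. The early mask encodes the response: pCR leaves a small
    near-spherical residual; CS without pCR scales the ellipsoid down
    preserving axis ratios; non-CS draws one of the four non-concentric
    subtypes. Contrast enhancement carries group-dependent texture so that
    texture features, not only shape, are informative.
    """
    if group_code not in (GROUP_NONCS, GROUP_CS, GROUP_PCR):
        raise ValueError(f"invalid group code {group_code}")
    shape = cfg.image_shape
    spacing = cfg.voxel_spacing_mm
    extent = np.array(shape) * np.array(spacing)
    center = extent / 2.0 + rng.uniform(-2.0, 2.0, size=3)
    r0 = rng.uniform(6.0, 9.0)
    ratios = np.array([1.0, rng.uniform(0.6, 0.9), rng.uniform(0.4, 0.7)])
    radii = r0 * ratios

    lobes = _lobe_params(rng, int(rng.integers(2, 5)))
    pre_mask = _composite_mask(shape, spacing, center, radii, lobes)
    if not pre_mask.any():
        raise RuntimeError("generated pre-treatment mask is empty")

    chosen_subtype = None
    tumor_enh_early = cfg.tumor_enhancement
    if group_code == GROUP_PCR:
        resid_r = rng.uniform(2.5, 4.0)
        early_mask = _ellipsoid_mask(shape, spacing, center, (resid_r,) * 3)
        if not early_mask.any():  # ensure a minimal one-voxel residual blob
            idx = tuple(np.round(center / np.array(spacing)).astype(int))
            early_mask = np.zeros(shape, dtype=bool)
            early_mask[tuple(np.clip(idx, 0, np.array(shape) - 1))] = True
    elif group_code == GROUP_CS:
        # concentric shrinkage: the whole composite shape scales about its
        # centre, so axis ratios are preserved
        scale = rng.uniform(0.5, 0.8)
        early_mask = _composite_mask(shape, spacing, center, radii, lobes, scale)
    else:
        chosen_subtype = subtype or rng.choice(NONCS_SUBTYPES)
        if chosen_subtype == "no_change":
            early_mask = pre_mask.copy()
        elif chosen_subtype == "intensity_decrease":
            early_mask = pre_mask.copy()
            tumor_enh_early = cfg.tumor_enhancement * rng.uniform(0.3, 0.6)
        elif chosen_subtype == "enlargement":
            grow = rng.uniform(1.1, 1.35)
            extra = _lobe_params(rng, int(rng.integers(3, 6)))
            early_mask = _composite_mask(shape, spacing, center, radii,
                                         lobes + extra, grow)
        elif chosen_subtype == "diffuse_decrease":
            # fragmented, irregular residual inside the original envelope
            field3 = ndimage.gaussian_filter(rng.normal(size=shape), 1.0)
            early_mask = pre_mask & (field3 > np.percentile(field3[pre_mask], 40))
            if not early_mask.any():
                early_mask = pre_mask.copy()
        else:
            raise ValueError(f"unknown non-CS subtype {chosen_subtype!r}")

    # group-dependent texture correlation length inside the enhancing tissue
    sigma_by_group = {GROUP_NONCS: 0.5, GROUP_CS: 1.0, GROUP_PCR: 1.5}
    tex_sigma = sigma_by_group[group_code]

    def build(mask, tumor_enh):
        s0 = np.full(shape, 100.0) + _texture(shape, rng, 1.0, cfg.image_noise_sigma)
        enh = (cfg.parenchyma_enhancement
               + _texture(shape, rng, 2.0, cfg.image_noise_sigma / 2.0))
        tumor_soft = ndimage.gaussian_filter(mask.astype(float), 0.4)
        enh = enh + tumor_enh * tumor_soft
        enh = enh + mask * _texture(shape, rng, tex_sigma, cfg.image_noise_sigma)
        sm = s0 + enh
        return (VolumeImage(s0, spacing), VolumeImage(sm, spacing))

    s0_pre, sm_pre = build(pre_mask, cfg.tumor_enhancement)
    s0_early, sm_early = build(early_mask, tumor_enh_early)
    return {
        "pre": {"s0": s0_pre, "sm": sm_pre, "mask": pre_mask},
        "early": {"s0": s0_early, "sm": sm_early, "mask": early_mask},
        "subtype": chosen_subtype,
    }


# ---------------------------------------------------------------------------
# feature-table fast path (bypasses imaging)

def generate_feature_table(cfg: CohortConfig
                           ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Tabular shortcut for learner tests: plants
    ``n_shared_signal_features`` with a standardized mean step of
    ``signal_effect_size`` between adjacent response groups (driving both
    tasks through the shared group structure), the rest pure equicorrelated
    Gaussian noise."""
    total = cfg.n_shared_signal_features + cfg.n_noise_features
    if total < 1:
        raise CohortConfigError("no features configured")
    labels = generate_labels(cfg)
    rng = _rng(cfg, _STREAM_FEATURES)
    n = cfg.n_patients
    rho = cfg.feature_correlation
    if not 0.0 <= rho < 1.0:
        raise CohortConfigError("feature_correlation must be in [0, 1)")
    common = rng.normal(size=(n, 1))
    X = np.sqrt(1.0 - rho) * rng.normal(size=(n, total)) + np.sqrt(rho) * common
    group = labels["group"].to_numpy()
    names = ([f"signal_{i:03d}" for i in range(cfg.n_shared_signal_features)]
             + [f"noise_{i:03d}" for i in range(cfg.n_noise_features)])
    X[:, :cfg.n_shared_signal_features] += (
        cfg.signal_effect_size * (group - 2.0)[:, None])
    table = pd.DataFrame(X, index=labels.index, columns=names)
    truth = GroundTruth(group=group,
                        signal_features=names[:cfg.n_shared_signal_features],
                        trend_genes=[], trend_signs={})
    return table, labels[["cs", "pcr"]], truth


# ---------------------------------------------------------------------------
# survival

def generate_survival(group_codes: np.ndarray, cfg: CohortConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Exponential event times by group hazard, for OS and RFS.

    Recurrence hazard is the death hazard times ``rfs_hazard_multiplier``;
    the RFS time is the earlier of recurrence and death, so RFS <= OS per
    patient. Both endpoints are administratively censored at
    ``admin_censor_months``. Clinical covariates are drawn with the
    prevalences of a typical NAC-treated cohort.
    """
    rng = rng if rng is not None else _rng(cfg, _STREAM_SURVIVAL)
    g = np.asarray(group_codes)
    hazards = {GROUP_NONCS: cfg.hazard_by_group[0],
               GROUP_CS: cfg.hazard_by_group[1],
               GROUP_PCR: cfg.hazard_by_group[2]}
    h_os = np.array([hazards[c] for c in g])
    death = rng.exponential(1.0 / h_os)
    recurrence = rng.exponential(1.0 / (h_os * cfg.rfs_hazard_multiplier))
    rfs_raw = np.minimum(death, recurrence)

    horizon = cfg.admin_censor_months
    os_event = (death <= horizon).astype(int)
    os_time = np.minimum(death, horizon)
    rfs_event = (rfs_raw <= horizon).astype(int)
    rfs_time = np.minimum(rfs_raw, horizon)

    n = len(g)
    df = pd.DataFrame({
        "group": g,
        "os_months": os_time, "os_event": os_event,
        "rfs_months": rfs_time, "rfs_event": rfs_event,
        "age": np.clip(rng.normal(48.9, 10.4, size=n), 25.0, 79.0),
        "er": (rng.random(n) < 0.584).astype(int),
        "pr": (rng.random(n) < 0.459).astype(int),
        "her2": (rng.random(n) < 0.435).astype(int),
        "diameter_mm": np.clip(rng.normal(37.6, 17.0, size=n), 8.0, 95.0),
    }, index=_patient_ids(n))
    return df


# ---------------------------------------------------------------------------
# expression

def generate_expression(group_codes: np.ndarray, cfg: CohortConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, GroundTruth]:
    """Genes x patients matrix with planted monotone trends.

    The first ``n_trend_genes`` genes carry a linear slope of alternating
    sign on the ordinal group code (positive = rising toward pCR). A
    configurable fraction of the remaining genes is expressed in fewer than
    20% of patients, and another fraction carries missing values, so the
    downstream filters have real work to do.
    """
    rng = rng if rng is not None else _rng(cfg, _STREAM_EXPRESSION)
    g = np.asarray(group_codes, dtype=float)
    n = len(g)
    genes = [f"GENE{i:04d}" for i in range(cfg.n_genes)]
    base = rng.normal(6.0, 1.0, size=(cfg.n_genes, 1))
    expr = base + rng.normal(0.0, 1.0, size=(cfg.n_genes, n))

    signs = {}
    for i in range(cfg.n_trend_genes):
        sign = 1 if i % 2 == 0 else -1
        expr[i] += sign * cfg.expression_trend_effect * (g - 2.0)
        signs[genes[i]] = sign

    rest = np.arange(cfg.n_trend_genes, cfg.n_genes)
    n_low = int(round(cfg.low_expressed_gene_fraction * cfg.n_genes))
    n_miss = int(round(cfg.expression_missing_gene_fraction * cfg.n_genes))
    low_idx = rest[:n_low]
    miss_idx = rest[n_low:n_low + n_miss]
    for i in low_idx:
        expressed = rng.random(n) < rng.uniform(0.02, 0.15)
        expr[i] = np.where(expressed, rng.uniform(0.5, 1.5, size=n), 0.0)
    for i in miss_idx:
        holes = rng.random(n) < rng.uniform(0.05, 0.30)
        expr[i, holes] = np.nan

    frame = pd.DataFrame(expr, index=genes, columns=_patient_ids(n))
    truth = GroundTruth(group=np.asarray(group_codes),
                        signal_features=[],
                        trend_genes=genes[:cfg.n_trend_genes],
                        trend_signs=signs)
    return frame, truth


# ---------------------------------------------------------------------------
# whole-cohort orchestration

@dataclass
class Cohort:
    cfg: CohortConfig
    manifest: pd.DataFrame       # labels + survival + covariates per patient
    expression: pd.DataFrame
    truth: GroundTruth


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Labels, survival and expression for every patient. Images are drawn
    lazily by :func:`patient_images` from an independent per-patient
    substream, so adding or re-running a stage never perturbs another."""
    labels = generate_labels(cfg)
    surv = generate_survival(labels["group"].to_numpy(), cfg)
    expr, truth = generate_expression(labels["group"].to_numpy(), cfg)
    truth.group = labels["group"].to_numpy()
    manifest = labels.join(surv.drop(columns="group"))
    manifest.index.name = "patient_id"
    return Cohort(cfg=cfg, manifest=manifest, expression=expr, truth=truth)


def patient_images(cohort: Cohort, patient_id: str) -> dict:
    """Deterministic image pair for one patient of the cohort."""
    i = cohort.manifest.index.get_loc(patient_id)
    rng = _rng(cohort.cfg, _STREAM_IMAGES, i)
    group = int(cohort.manifest.iloc[i]["group"])
    images = generate_image_pair(group, cohort.cfg, rng)
    if images["subtype"] is not None:
        cohort.truth.noncs_subtypes[patient_id] = images["subtype"]
    return images


def synthetic_gene_sets(genes: list[str], trend_genes: list[str],
                        rng: np.random.Generator, n_sets: int = 20,
                        set_size: int = 15) -> dict[str, set[str]]:
    """Pathway gene sets for the synthetic cohort: one pathway seeded with
    the planted trend genes (plus a few random members) and ``n_sets - 1``
    random same-sized pathways drawn from the remaining genes."""
    pool = [g for g in genes if g not in set(trend_genes)]
    planted = set(trend_genes) | set(rng.choice(pool, size=min(5, len(pool)),
                                                replace=False).tolist())
    sets = {"PLANTED_RESPONSE_PATHWAY": planted}
    for i in range(n_sets - 1):
        members = rng.choice(pool, size=min(set_size, len(pool)), replace=False)
        sets[f"RANDOM_PATHWAY_{i:02d}"] = set(members.tolist())
    return sets


def write_gene_sets(gene_sets: dict[str, set[str]], path: str | Path) -> None:
    """Write gene sets in GMT format (name, description, members)."""
    with open(path, "w") as fh:
        for name in gene_sets:
            members = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\tsynthetic\t{members}\n")


def write_cohort(cohort: Cohort, out_dir: str | Path,
                 with_images: bool = False) -> None:
    """Persist manifest CSV, expression TSV, ground-truth JSON and
    (optionally) NIfTI volumes with spacing in the header."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.manifest.to_csv(out / "manifest.csv")
    cohort.expression.to_csv(out / "expression.tsv", sep="\t")
    truth = {
        "group": {pid: int(v) for pid, v in
                  zip(cohort.manifest.index, cohort.truth.group)},
        "signal_features": cohort.truth.signal_features,
        "trend_genes": cohort.truth.trend_genes,
        "trend_signs": cohort.truth.trend_signs,
        "noncs_subtypes": cohort.truth.noncs_subtypes,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cohort.cfg).items()},
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    if with_images:
        import nibabel as nib
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for pid in cohort.manifest.index:
            images = patient_images(cohort, pid)
            for tp in ("pre", "early"):
                affine = np.diag(list(cohort.cfg.voxel_spacing_mm) + [1.0])
                for key in ("s0", "sm"):
                    vol = images[tp][key]
                    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), affine),
                             img_dir / f"{pid}_{tp}_{key}.nii")
                nib.save(nib.Nifti1Image(
                    images[tp]["mask"].astype(np.uint8), affine),
                    img_dir / f"{pid}_{tp}_mask.nii")
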