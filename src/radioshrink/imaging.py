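"""Preprocessing of paired DCE-MRI-like volumes.

The chain mirrors the standard radiomics workflow for dynamic
contrast-enhanced breast MRI: resample every series to an isotropic grid,
normalize intensities by the mean of the inter-quartile range, form the
subtraction image SM0 = SM - S0, segment the enhancing tumour on SM0 with a
spatially regularized fuzzy C-means, and delineate a fixed-width parenchymal
ring around the lesion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class SegmentationFailure(RuntimeError):
    """Raised when FCM converges but no voxel is assigned to the tumour."""


@dataclass(frozen=True)
class VolumeImage:
    """A 3D scalar grid with physical voxel spacing in millimetres."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={v.ndim}")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite values")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive values, got {self.spacing_mm}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def same_grid(self, other: "VolumeImage") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin, other.origin)
        )

    def with_values(self, values: np.ndarray) -> "VolumeImage":
        return VolumeImage(values, self.spacing_mm, self.origin)


@dataclass(frozen=True)
class SequenceTriplet:
    """Precontrast (S0), intermediate postcontrast (SM) and subtraction (SM0)."""

    s0: VolumeImage
    sm: VolumeImage
    sm0: VolumeImage


@dataclass(frozen=True)
class RegionMasks:
    """Tumour mask and the surrounding parenchymal ring (disjoint by construction)."""

    tumor: np.ndarray
    parenchyma_ring: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.tumor, dtype=bool)
        r = np.asarray(self.parenchyma_ring, dtype=bool)
        if t.shape != r.shape:
            raise ValueError("masks must share a grid")
        if np.any(t & r):
            raise ValueError("tumor and parenchymal ring overlap")
        object.__setattr__(self, "tumor", t)
        object.__setattr__(self, "parenchyma_ring", r)


@dataclass
class PreprocessConfig:
    """Knobs of the preprocessing chain.

    ``target_spacing_mm`` defaults to 0.8 mm isotropic; ``ring_width_mm`` to a
    20 mm parenchymal margin. FCM uses two clusters (lesion vs background)
    with fuzzifier m=2 and Chuang-style spatial membership smoothing.
    """

    target_spacing_mm: float = 0.8
    ring_width_mm: float = 20.0
    fcm_clusters: int = 2
    fcm_fuzzifier: float = 2.0
    fcm_spatial_weight: float = 1.0
    fcm_tol: float = 1e-4
    fcm_max_iter: int = 100

    def __post_init__(self) -> None:
        for name in ("target_spacing_mm", "ring_width_mm", "fcm_fuzzifier",
                     "fcm_spatial_weight", "fcm_tol"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.target_spacing_mm <= 0:
            raise ValueError("target_spacing_mm must be positive")
        if self.fcm_clusters < 2:
            raise ValueError("fcm_clusters must be >= 2")
        if self.fcm_max_iter < 1:
            raise ValueError("fcm_max_iter must be >= 1")


def resample_isotropic(img: VolumeImage, target_spacing: float,
                       is_mask: bool = False) -> VolumeImage:
    """Resample to an isotropic grid at ``target_spacing`` mm.

    Intensities are interpolated trilinearly; masks use nearest-neighbour so
    labels stay binary. The voxel count per axis scales by the spacing ratio
    (rounded), preserving the physical extent to within one voxel.
    """
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    zoom = np.asarray(img.spacing_mm, dtype=float) / float(target_spacing)
    if np.allclose(zoom, 1.0):
        return VolumeImage(img.values.copy(), (target_spacing,) * 3, img.origin)
    new_shape = np.maximum(1, np.round(np.array(img.shape) * zoom)).astype(int)
    exact_zoom = new_shape / np.array(img.shape)
    order = 0 if is_mask else 1
    out = ndimage.zoom(np.asarray(img.values, dtype=float), exact_zoom,
                       order=order, mode="nearest", grid_mode=True)
    if is_mask:
        out = out > 0.5
    return VolumeImage(out.astype(float), (target_spacing,) * 3, img.origin)


def normalize_intensity(img: VolumeImage) -> VolumeImage:
    """Divide by the mean of intensities inside the inter-quartile range.

    Scale invariant: normalize(c * img) == normalize(img) for any c > 0.
    Applying it twice is the identity because the IQR-mean of the output is 1.
    """
    v = img.values
    q1, q3 = np.percentile(v, [25.0, 75.0])
    central = v[(v >= q1) & (v <= q3)]
    if central.size == 0:
        raise ValueError("no voxels inside the inter-quartile range")
    factor = float(central.mean())
    if factor <= 0:
        raise ValueError(f"IQR-mean normalization factor is non-positive ({factor:g})")
    if np.isclose(q1, q3) and np.allclose(v, v.flat[0]):
        raise ValueError("cannot normalize a constant image")
    return img.with_values(v / factor)


def build_triplet(s0: VolumeImage, sm: VolumeImage) -> SequenceTriplet:
    """Assemble the (S0, SM, SM0) triplet with SM0 = SM - S0 voxelwise."""
    if not s0.same_grid(sm):
        raise ValueError(
            f"S0 and SM grids differ: {s0.shape}@{s0.spacing_mm} vs {sm.shape}@{sm.spacing_mm}")
    sm0 = sm.with_values(sm.values - s0.values)
    return SequenceTriplet(s0=s0, sm=sm, sm0=sm0)


def _neighbour_mean(u: np.ndarray) -> np.ndarray:
    # mean membership over the 26-neighbourhood (centre excluded)
    s = ndimage.uniform_filter(u, size=3, mode="nearest") * 27.0
    return (s - u) / 26.0


def segment_tumor_fcm(sm0: VolumeImage, cfg: PreprocessConfig,
                      init_box: tuple[slice, slice, slice] | None = None) -> np.ndarray:
    """Segment the enhancing lesion with spatially regularized fuzzy C-means.

    Two clusters are fit to the intensities inside ``init_box`` (whole volume
    by default). Each iteration first computes the standard FCM membership
    u_ik = (1/d_ik^2)^{1/(m-1)} normalized over clusters, then multiplies it
    by the mean membership of the voxel's 26-neighbourhood raised to the
    spatial weight, and renormalizes. The tumour is the brighter cluster's
    membership > 0.5, reduced to its largest 26-connected component.

    Raises :class:`SegmentationFailure` when no voxel ends up assigned.
    """
    box = init_box if init_box is not None else tuple(slice(0, s) for s in sm0.shape)
    sub = np.asarray(sm0.values[box], dtype=float)
    if sub.size == 0:
        raise ValueError("init_box selects no voxels")
    flatv = sub
    k = cfg.fcm_clusters
    m = cfg.fcm_fuzzifier
    lo, hi = flatv.min(), flatv.max()
    if np.isclose(lo, hi):
        raise SegmentationFailure("constant intensity inside the initialization box")
    # centers initialized at evenly spaced quantiles for determinism
    centers = np.quantile(flatv, np.linspace(0.05, 0.95, k))
    u = np.full((k,) + sub.shape, 1.0 / k)
    expo = 1.0 / (m - 1.0)
    for _ in range(cfg.fcm_max_iter):
        d2 = np.stack([(flatv - c) ** 2 for c in centers]) + 1e-12
        new_u = (1.0 / d2) ** expo
        new_u /= new_u.sum(axis=0)
        if cfg.fcm_spatial_weight > 0:
            h = np.stack([_neighbour_mean(new_u[j]) for j in range(k)]) + 1e-12
            new_u = new_u * h ** cfg.fcm_spatial_weight
            new_u /= new_u.sum(axis=0)
        w = new_u ** m
        centers = np.array([(w[j] * flatv).sum() / w[j].sum() for j in range(k)])
        delta = np.abs(new_u - u).max()
        u = new_u
        if delta < cfg.fcm_tol:
            break
    bright = int(np.argmax(centers))
    sub_mask = u[bright] > 0.5
    mask = np.zeros(sm0.shape, dtype=bool)
    mask[box] = sub_mask
    if not mask.any():
        raise SegmentationFailure("no voxel assigned to the tumour cluster")
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def extract_parenchymal_ring(tumor_mask: np.ndarray,
                             spacing_mm: tuple[float, float, float],
                             width_mm: float = 20.0) -> np.ndarray:
    """Ring of parenchyma within ``width_mm`` of the tumour surface.

    Computed from the exact Euclidean distance transform of the tumour
    complement (anisotropic sampling honoured), then the tumour is removed,
    so ring and tumour are always disjoint. Clipped at the volume borders.
    """
    t = np.asarray(tumor_mask, dtype=bool)
    if not t.any():
        raise ValueError("tumor mask is empty")
    if width_mm <= 0:
        return np.zeros_like(t)
    dist = ndimage.distance_transform_edt(~t, sampling=spacing_mm)
    return (dist > 0) & (dist <= width_mm)


def preprocess_pair(s0: VolumeImage, sm: VolumeImage, cfg: PreprocessConfig,
                    init_box: tuple[slice, slice, slice] | None = None,
                    tumor_mask: np.ndarray | None = None,
                    ) -> tuple[SequenceTriplet, RegionMasks]:
    """Full chain: resample both series, subtract, normalize each derived
    sequence, segment (unless a mask on the resampled grid is supplied) and
    build the parenchymal ring."""
    s0r = resample_isotropic(s0, cfg.target_spacing_mm)
    smr = resample_isotropic(sm, cfg.target_spacing_mm)
    raw = build_triplet(s0r, smr)
    # Subtraction happens on the raw co-registered grids; each derived
    # sequence is then normalized independently. SM0 keeps a positive
    # IQR-mean because parenchyma itself enhances after contrast.
    triplet = SequenceTriplet(
        s0=normalize_intensity(raw.s0),
        sm=normalize_intensity(raw.sm),
        sm0=normalize_intensity(raw.sm0),
    )
    if tumor_mask is None:
        tumor = segment_tumor_fcm(raw.sm0, cfg, init_box=init_box)
    else:
        tumor = np.asarray(tumor_mask, dtype=bool)
        if tumor.shape != raw.sm0.shape:
            raise ValueError("supplied tumor mask is not on the resampled grid")
    ring = extract_parenchymal_ring(tumor, (cfg.target_spacing_mm,) * 3, cfg.ring_width_mm)
    return triplet, RegionMasks(tumor=tumor, parenchyma_ring=ring)
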