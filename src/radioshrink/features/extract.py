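"""Per-patient feature extraction over sequences and regions.

For every (sequence in {S0, SM, SM0}) x (region in {tumor, parenchyma}) the
full 102-feature catalogue is emitted, plus NGTDM busyness as an extra.
Shape features depend only on the mask, so they are computed once per region
and replicated across sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..imaging import RegionMasks, SequenceTriplet
from .catalogue import CATALOGUE, EXTRA_FEATURES, FAMILIES
from .firstorder import compute_first_order_features
from .shape import compute_shape_features
from .texture import DiscretizationSpec, compute_ngtdm_busyness, discretize, texture_features

SEQUENCES = ("S0", "SM", "SM0")
REGIONS = ("tumor", "parenchyma")


@dataclass
class FeatureVector:
    """Named feature values for one (patient, timepoint, sequence, region).

    ``undefined`` lists features whose value could not be computed (e.g.
    busyness on a single-level region); their entry in ``values`` is NaN and
    the flag travels with the vector rather than becoming a silent NaN.
    """

    patient_id: str
    timepoint: str  # "pre" or "earlyNAC"
    sequence: str
    region: str
    values: dict[str, float] = field(default_factory=dict)
    undefined: set[str] = field(default_factory=set)

    def set(self, name: str, value: float | None) -> None:
        if value is None or not np.isfinite(value):
            self.values[name] = float("nan")
            self.undefined.add(name)
        else:
            self.values[name] = float(value)


def extract_all(triplet: SequenceTriplet, masks: RegionMasks, patient_id: str,
                timepoint: str,
                spec: DiscretizationSpec | None = None) -> list[FeatureVector]:
    """Extract the catalogue for all sequence/region combinations.

    Returns one :class:`FeatureVector` per combination; each carries exactly
    102 catalogue values plus the extras family.
    """
    spec = spec or DiscretizationSpec()
    spacing = triplet.sm0.spacing_mm
    voxvol = float(np.prod(spacing))
    region_masks = {"tumor": masks.tumor, "parenchyma": masks.parenchyma_ring}
    shape_by_region = {
        region: compute_shape_features(mask, spacing) if mask.any() else None
        for region, mask in region_masks.items()
    }
    volumes = {"S0": triplet.s0.values, "SM": triplet.sm.values, "SM0": triplet.sm0.values}

    vectors: list[FeatureVector] = []
    for seq in SEQUENCES:
        vol = volumes[seq]
        for region in REGIONS:
            mask = region_masks[region]
            fv = FeatureVector(patient_id, timepoint, seq, region)
            if not mask.any():
                for name in CATALOGUE + tuple(f"extras_{e}" for e in EXTRA_FEATURES):
                    fv.set(name, None)
                vectors.append(fv)
                continue
            shape = shape_by_region[region]
            for name in FAMILIES["shape"]:
                fv.set(f"shape_{name}", shape[name])
            levels = discretize(vol, mask, spec)
            fo = compute_first_order_features(vol[mask], levels[mask], voxvol)
            for name in FAMILIES["firstorder"]:
                fv.set(f"firstorder_{name}", fo[name])
            for family in ("glcm", "glrlm", "glszm", "gldm"):
                vals = texture_features(levels, family)
                for name in FAMILIES[family]:
                    fv.set(f"{family}_{name}", vals[name])
            fv.set("extras_Busyness", compute_ngtdm_busyness(levels))
            vectors.append(fv)
    return vectors


def vectors_to_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Tidy long-format table (patient_id, timepoint, sequence, region,
    feature, value, undefined)."""
    rows = []
    for fv in vectors:
        for name, value in fv.values.items():
            rows.append({
                "patient_id": fv.patient_id,
                "timepoint": fv.timepoint,
                "sequence": fv.sequence,
                "region": fv.region,
                "feature": name,
                "value": value,
                "undefined": name in fv.undefined,
            })
    return pd.DataFrame(rows)


def wide_feature_table(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy table into one row per patient with fully qualified
    column names ``timepoint__sequence__region__feature``."""
    df = long.copy()
    df["column"] = (df["timepoint"] + "__" + df["sequence"] + "__"
                    + df["region"] + "__" + df["feature"])
    wide = df.pivot_table(index="patient_id", columns="column", values="value",
                          aggfunc="first", sort=True)
    wide.columns.name = None
    return wide
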