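"""Lesion-derived predictor tables and the standard model families.

Two families of regression models are compared throughout:

* ``LV``      — overall percentage damage to the left hemisphere, optionally
                with demographic covariates (age / edu / onset / all);
* ``LV-PCA``  — the functionally-partitioned lesion: percentage damage to each
                behaviourally-derived cluster plus the residual-hemisphere
                percentage, with the same demographic variants.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import MaskStack, VolumeGrid

__all__ = ["ModelSpec", "model_specs", "compute_predictors", "DEMOGRAPHICS"]

DEMOGRAPHICS = ("age", "edu", "onset")


@dataclass(frozen=True)
class ModelSpec:
    name: str
    columns: tuple

    def design(self, predictors: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns if c not in predictors.columns]
        if missing:
            raise KeyError(f"model {self.name}: missing predictor columns {missing}")
        return predictors[list(self.columns)]


def model_specs(cluster_names=("phonology", "semantics", "speech_quanta")):
    """The ten standard model variants (LV family and LV-PCA family)."""
    lv = ("LV",)
    lvpca = ("residual_LV",) + tuple(f"overlap_{c}" for c in cluster_names)
    demo_variants = {
        "": (),
        "-age": ("age",),
        "-edu": ("edu",),
        "-ons": ("onset",),
        "-all": ("age", "edu", "onset"),
    }
    specs = []
    for fam_name, fam_cols in (("LV", lv), ("LV-PCA", lvpca)):
        for suffix, demo in demo_variants.items():
            specs.append(ModelSpec(fam_name + suffix, fam_cols + demo))
    return specs


def _overlap_pct(lesions_flat: np.ndarray, region_flat: np.ndarray) -> np.ndarray:
    size = region_flat.sum()
    return 100.0 * (lesions_flat @ region_flat.astype(float)) / size


def compute_predictors(
    lesions: MaskStack,
    hemisphere_mask: VolumeGrid | np.ndarray,
    cluster_masks: dict | None,
    demographics: pd.DataFrame | None = None,
    on_empty_residual: str = "raise",
) -> pd.DataFrame:
    """Per-patient percentage-overlap predictors plus demographics.

    ``LV`` is the percentage of the hemisphere mask lesioned;
    ``overlap_<name>`` the percentage of each cluster lesioned; and
    ``residual_LV`` the percentage of the hemisphere *outside* the cluster
    union that is lesioned. Clusters must be nonempty; voxels of a cluster
    outside the hemisphere are dropped with a warning.
    """
    hemi = (
        hemisphere_mask.data
        if isinstance(hemisphere_mask, VolumeGrid)
        else np.asarray(hemisphere_mask)
    ).astype(bool)
    flat = lesions.flat().astype(float)
    hemi_flat = hemi.ravel()
    out = pd.DataFrame(index=pd.Index(lesions.ids, name="id"))
    out["LV"] = _overlap_pct(flat, hemi_flat)

    union = np.zeros_like(hemi_flat)
    if cluster_masks:
        for name, mask in cluster_masks.items():
            m = (mask.data if isinstance(mask, VolumeGrid) else np.asarray(mask)).astype(bool)
            mflat = m.ravel()
            if not mflat.any():
                raise ValueError(f"cluster {name!r} is empty")
            if np.any(mflat & ~hemi_flat):
                warnings.warn(
                    f"cluster {name!r} extends outside the hemisphere mask; "
                    "using the intersection",
                    stacklevel=2,
                )
                mflat = mflat & hemi_flat
                if not mflat.any():
                    raise ValueError(f"cluster {name!r} empty after intersection")
            out[f"overlap_{name}"] = _overlap_pct(flat, mflat)
            union |= mflat
        residual = hemi_flat & ~union
        if residual.any():
            out["residual_LV"] = _overlap_pct(flat, residual)
        elif on_empty_residual == "zero":
            warnings.warn(
                "clusters cover the whole hemisphere; residual_LV set to 0",
                stacklevel=2,
            )
            out["residual_LV"] = 0.0
        else:
            raise ValueError("residual hemisphere region is empty")

    if demographics is not None:
        demo = demographics.reset_index(drop=True)
        for col in DEMOGRAPHICS:
            if col in demo.columns:
                out[col] = np.asarray(demo[col], dtype=float)
    bad = out.columns[~np.isfinite(out.to_numpy(dtype=float)).all(axis=0)]
    if len(bad):
        raise ValueError(f"non-finite predictor column(s): {list(bad)}")
    return out
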