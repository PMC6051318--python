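"""Synthetic chronic-aphasia cohorts: lesions, behaviour, demographics, labels.

The generator emulates the statistical structure the analysis pipeline assumes:

* contiguous left-hemisphere lesions of widely varying volume, grown by
  randomised boundary accretion from seeds in a perisylvian "core" (mimicking
  the middle-cerebral-artery territory where stroke lesions concentrate);
* K planted functional regions (default 3: phonology, semantics, speech
  quanta); the percentage damage to each region drives a battery of T
  correlated test scores through a nonnegative test-on-factor loading matrix;
* a linear-in-damage score link with clipping to [0, 100], an additive age
  effect and Gaussian residual noise;
* threshold rules on the damage vector yielding aphasia-subtype labels and a
  fluent/non-fluent split.

Everything is reproducible from a single integer seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes import MaskStack, VolumeGrid

__all__ = [
    "make_hemisphere_mask",
    "grow_lesion",
    "SubtypeRules",
    "default_subtype_rules",
    "assign_subtype",
    "GroundTruth",
    "generate_ground_truth",
    "SyntheticCohort",
    "generate_cohort",
]

# 6-connected neighbourhood offsets used for lesion growth
_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)

DEFAULT_GRID = (40, 48, 40)
DEFAULT_VOXEL_MM = 4.0


def make_hemisphere_mask(
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    voxel_mm: float = DEFAULT_VOXEL_MM,
) -> VolumeGrid:
    """Half-ellipsoid stand-in for a left hemisphere on the given grid.

    The affine is diagonal with the grid centre at world origin, so the mask
    occupies negative world x (the left side under radiological-free
    convention used here).
    """
    nx, ny, nz = grid_shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    rx, ry, rz = 0.46 * nx, 0.46 * ny, 0.46 * nz
    i, j, k = np.ogrid[0:nx, 0:ny, 0:nz]
    ellipsoid = (
        ((i - cx) / rx) ** 2 + ((j - cy) / ry) ** 2 + ((k - cz) / rz) ** 2
    ) <= 1.0
    left = i <= cx
    mask = ellipsoid & np.broadcast_to(left, ellipsoid.shape)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * np.array([cx, cy, cz])
    return VolumeGrid(mask, affine)


def grow_lesion(
    seed_voxel,
    target_volume: int,
    hemisphere_mask: np.ndarray | VolumeGrid,
    rng,
    compactness: float = 2.0,
) -> np.ndarray:
    """Grow a single 6-connected blob of exactly ``target_volume`` voxels.

    Randomised boundary accretion: at each step a frontier voxel is drawn with
    probability proportional to (number of already-lesioned 6-neighbours) **
    ``compactness``, which biases growth toward compact, blob-like shapes.

    Returns a boolean volume. The blob contains the seed and never leaves the
    hemisphere mask.
    """
    mask = hemisphere_mask.data if isinstance(hemisphere_mask, VolumeGrid) else hemisphere_mask
    mask = np.asarray(mask, dtype=bool)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seed = tuple(int(c) for c in seed_voxel)
    if not mask[seed]:
        raise ValueError(f"seed voxel {seed} lies outside the hemisphere mask")
    total = int(mask.sum())
    target_volume = int(target_volume)
    if not (1 <= target_volume <= total):
        raise ValueError(
            f"target_volume {target_volume} outside [1, {total}] for this mask"
        )
    if target_volume == total:
        return mask.copy()

    lesion = np.zeros_like(mask)
    lesion[seed] = True
    shape = np.array(mask.shape)

    def neighbours(idx):
        pts = np.asarray(idx) + _OFFSETS
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        return [tuple(p) for p in pts[ok]]

    # frontier voxel -> number of lesioned 6-neighbours
    frontier: dict[tuple, int] = {}
    for p in neighbours(seed):
        if mask[p]:
            frontier[p] = 1

    while int(lesion.sum()) < target_volume:
        if not frontier:
            raise ValueError(
                "lesion growth exhausted the connected component of the seed "
                "before reaching target_volume"
            )
        keys = list(frontier.keys())
        w = np.array([frontier[k] for k in keys], dtype=float) ** compactness
        pick = keys[rng.choice(len(keys), p=w / w.sum())]
        del frontier[pick]
        lesion[pick] = True
        for p in neighbours(pick):
            if mask[p] and not lesion[p]:
                frontier[p] = frontier.get(p, 0) + 1
    return lesion


# ---------------------------------------------------------------------------
# subtype rules
# ---------------------------------------------------------------------------

#: BDAE-like label set used when K = 3 (factor order: phonology, semantics,
#: speech quanta). Purely synthetic rules; no clinical validity claimed.
_BDAE3_TABLE = {
    (0, 0, 0): "anomia",
    (1, 0, 0): "conduction",
    (0, 1, 0): "TSA",
    (1, 1, 0): "TSA",
    (0, 0, 1): "TMA",
    (1, 0, 1): "Broca",
    (0, 1, 1): "mixed nonfluent",
    (1, 1, 1): "global",
}
_BDAE3_FLUENT = frozenset({"anomia", "conduction", "TSA"})


@dataclass(frozen=True)
class SubtypeRules:
    """Deterministic mapping from a K-vector of %damage to a subtype label."""

    thresholds: tuple  # per-factor damage threshold in %
    table: dict  # binary K-tuple -> label
    fluent_labels: frozenset  # labels counted as fluent

    @property
    def n_factors(self) -> int:
        return len(self.thresholds)

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.table.values()))


def default_subtype_rules(n_factors: int = 3, threshold: float = 25.0) -> SubtypeRules:
    if n_factors == 3:
        return SubtypeRules((threshold,) * 3, dict(_BDAE3_TABLE), _BDAE3_FLUENT)
    # generic grading by number of damaged systems
    table = {}
    for bits in np.ndindex(*(2,) * n_factors):
        table[tuple(int(b) for b in bits)] = f"grade_{sum(bits)}"
    fluent = frozenset(f"grade_{g}" for g in range(0, (n_factors + 1) // 2))
    return SubtypeRules((threshold,) * n_factors, table, fluent)


def assign_subtype(damage_vector, rules: SubtypeRules) -> tuple[str, bool]:
    """Label a patient from their per-region %damage; returns (label, fluent)."""
    d = np.asarray(damage_vector, dtype=float)
    if d.shape != (rules.n_factors,):
        raise ValueError(f"expected {rules.n_factors} damage values, got {d.shape}")
    if np.any((d < 0) | (d > 100)):
        raise ValueError("damage values must lie in [0, 100]")
    bits = tuple(int(di >= ti) for di, ti in zip(d, rules.thresholds))
    label = rules.table[bits]
    return label, label in rules.fluent_labels


# ---------------------------------------------------------------------------
# ground truth and cohort generation
# ---------------------------------------------------------------------------

FACTOR_NAMES = ("phonology", "semantics", "speech_quanta")


@dataclass
class GroundTruth:
    """The generative quantities a recovery test can check against."""

    region_masks: np.ndarray  # (K, x, y, z) boolean, pairwise disjoint
    loading_matrix: np.ndarray  # (T, K) nonnegative
    noise_sd: float
    age_coefs: np.ndarray  # (T,) score-units per year of age above the mean
    subtype_rules: SubtypeRules
    hemisphere: VolumeGrid
    factor_names: tuple = FACTOR_NAMES

    def __post_init__(self) -> None:
        K = len(self.region_masks)
        if K < 1:
            raise ValueError("need at least one region")
        if self.loading_matrix.shape[1] != K:
            raise ValueError("loading matrix does not match region count")
        if self.loading_matrix.shape[0] < K:
            raise ValueError("need at least as many tests as factors")
        if np.any(self.loading_matrix < 0):
            raise ValueError("loadings must be nonnegative")
        if not np.all(self.loading_matrix.max(axis=1) > 0):
            raise ValueError("every test needs at least one positive loading")
        flat = self.region_masks.reshape(K, -1)
        if np.any(flat.sum(axis=1) == 0):
            raise ValueError("every region mask must be nonempty")
        if np.any(flat.sum(axis=0) > 1):
            raise ValueError("region masks must be pairwise disjoint")
        hemi = self.hemisphere.data
        if np.any(flat[:, ~hemi.ravel()]):
            raise ValueError("region masks must lie inside the hemisphere mask")

    @property
    def n_factors(self) -> int:
        return len(self.region_masks)

    @property
    def n_tests(self) -> int:
        return self.loading_matrix.shape[0]

    def region_label_map(self) -> VolumeGrid:
        labels = np.zeros(self.hemisphere.shape, dtype=np.int16)
        for k, m in enumerate(self.region_masks, start=1):
            labels[m] = k
        return VolumeGrid(labels, self.hemisphere.affine)


def _spread_seeds(core_idx: np.ndarray, n: int, rng) -> np.ndarray:
    """Greedy max-min selection of n spread-out seed voxels from candidates."""
    cand = core_idx[rng.choice(len(core_idx), size=min(len(core_idx), 256), replace=False)]
    chosen = [cand[rng.integers(len(cand))]]
    while len(chosen) < n:
        d = np.min(
            [np.linalg.norm(cand - c, axis=1) for c in chosen], axis=0
        )
        chosen.append(cand[int(np.argmax(d))])
    return np.array(chosen)


def _default_loadings(T: int, K: int, cross: float = 0.1) -> np.ndarray:
    """Round-robin simple structure: each test loads 1.0 on one factor."""
    lam = np.full((T, K), cross)
    for t in range(T):
        lam[t, t % K] = 1.0
    return lam


def generate_ground_truth(
    grid_shape=DEFAULT_GRID,
    n_factors: int = 3,
    n_tests: int = 21,
    region_volume_frac: float = 0.12,
    noise_sd: float = 8.0,
    age_coef: float = 0.35,
    rng=None,
    voxel_mm: float = DEFAULT_VOXEL_MM,
) -> GroundTruth:
    """Plant K disjoint functional regions and a simple-structure battery."""
    rng = np.random.default_rng(rng)
    hemi = make_hemisphere_mask(grid_shape, voxel_mm)
    hemi_idx = np.argwhere(hemi.data)
    centroid = hemi_idx.mean(axis=0)
    # perisylvian core: central half of the hemisphere by distance to centroid
    dist = np.linalg.norm(hemi_idx - centroid, axis=1)
    core = hemi_idx[dist <= np.quantile(dist, 0.5)]
    seeds = _spread_seeds(core, n_factors, rng)
    vol = max(8, int(round(region_volume_frac * len(hemi_idx))))
    free = hemi.data.copy()
    regions = []
    for s in seeds:
        # functional territories are grown highly compact (near-spherical)
        blob = grow_lesion(tuple(s), vol, free, rng, compactness=6.0)
        regions.append(blob)
        free &= ~blob
    names = FACTOR_NAMES if n_factors == 3 else tuple(
        f"factor_{k+1}" for k in range(n_factors)
    )
    return GroundTruth(
        region_masks=np.stack(regions),
        loading_matrix=_default_loadings(n_tests, n_factors),
        noise_sd=noise_sd,
        age_coefs=np.full(n_tests, age_coef),
        subtype_rules=default_subtype_rules(n_factors),
        hemisphere=hemi,
        factor_names=names,
    )


@dataclass
class SyntheticCohort:
    lesions: MaskStack
    behaviour: pd.DataFrame  # n x T, columns test_01..test_T, values in [0,100]
    demographics: pd.DataFrame  # columns id, age, edu, onset
    subtype: pd.Series
    fluency: pd.Series  # boolean, True = fluent
    damage: pd.DataFrame  # n x K true %damage per region (generative record)
    truth: GroundTruth

    @property
    def n(self) -> int:
        return len(self.behaviour)

    def cohort_table(self) -> pd.DataFrame:
        """Single CSV-ready table: id, demographics, labels, test scores."""
        out = self.demographics.copy()
        out["subtype"] = self.subtype.values
        out["fluency"] = self.fluency.astype(int).values
        for c in self.behaviour.columns:
            out[c] = self.behaviour[c].values
        return out

    def write(self, directory: str | Path) -> None:
        """Write lesions (gzipped NIfTI), cohort CSV and ground truth to disk."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.lesions.save(directory / "lesions")
        self.cohort_table().to_csv(directory / "cohort.csv", index=False)
        self.truth.hemisphere.save(directory / "hemisphere.nii.gz")
        self.truth.region_label_map().save(directory / "regions.nii.gz")
        params = {
            "n": self.n,
            "n_factors": self.truth.n_factors,
            "n_tests": self.truth.n_tests,
            "factor_names": list(self.truth.factor_names),
            "noise_sd": self.truth.noise_sd,
            "age_coefs": self.truth.age_coefs.tolist(),
            "loading_matrix": self.truth.loading_matrix.tolist(),
            "subtype_thresholds": list(self.truth.subtype_rules.thresholds),
        }
        (directory / "truth.json").write_text(json.dumps(params, indent=2))


def _sample_lesion_volumes(n, hemi_size, rng, median_frac, sigma):
    frac = np.exp(rng.normal(np.log(median_frac), sigma, size=n))
    frac = np.clip(frac, 0.005, 0.7)
    return np.maximum(1, np.round(frac * hemi_size)).astype(int)


def generate_cohort(
    n: int = 70,
    grid_shape=DEFAULT_GRID,
    n_factors: int = 3,
    n_tests: int = 21,
    effect_size: float = 1.0,
    noise_sd: float = 8.0,
    age_coef: float = 0.35,
    rng_seed: int | None = 0,
    truth: GroundTruth | None = None,
    lesion_frac_median: float = 0.12,
    lesion_frac_sigma: float = 1.0,
    voxel_mm: float = DEFAULT_VOXEL_MM,
) -> SyntheticCohort:
    """Generate a full synthetic cohort.

    Score model, per test t and patient i with region damages d_ik (%):

        score_ti = clip(100 * sum_k lam_tk (1 - e*d_ik/100) / sum_k lam_tk
                        - a_t * (age_i - 65) + eps_ti, 0, 100)

    with e = ``effect_size``, a_t the age coefficient and eps ~ N(0, noise_sd).
    Lesion volumes are log-normal fractions of the hemisphere (median
    ``lesion_frac_median``, log-sd ``lesion_frac_sigma``), seeds drawn from the
    perisylvian core so that the planted regions are damaged with realistic
    frequency.
    """
    if n < 1 or n_factors < 1 or n_tests < 1:
        raise ValueError("n, n_factors and n_tests must be positive")
    if effect_size < 0:
        raise ValueError("effect_size must be nonnegative")
    rng = np.random.default_rng(rng_seed)
    if truth is None:
        truth = generate_ground_truth(
            grid_shape,
            n_factors,
            n_tests,
            noise_sd=noise_sd,
            age_coef=age_coef,
            rng=rng,
            voxel_mm=voxel_mm,
        )
    hemi = truth.hemisphere
    hemi_idx = np.argwhere(hemi.data)
    centroid = hemi_idx.mean(axis=0)
    dist = np.linalg.norm(hemi_idx - centroid, axis=1)
    core = hemi_idx[dist <= np.quantile(dist, 0.6)]
    volumes = _sample_lesion_volumes(
        n, len(hemi_idx), rng, lesion_frac_median, lesion_frac_sigma
    )
    lesions = np.zeros((n,) + hemi.shape, dtype=bool)
    for i in range(n):
        seed = tuple(core[rng.integers(len(core))])
        lesions[i] = grow_lesion(seed, volumes[i], hemi.data, rng)

    K, T = truth.n_factors, truth.n_tests
    region_flat = truth.region_masks.reshape(K, -1).astype(float)
    region_sizes = region_flat.sum(axis=1)
    damage = 100.0 * (lesions.reshape(n, -1) @ region_flat.T) / region_sizes

    lam = truth.loading_matrix
    intact = 1.0 - effect_size * damage / 100.0  # (n, K)
    base = 100.0 * (intact @ lam.T) / lam.sum(axis=1)  # (n, T)

    age = np.clip(rng.normal(65.0, 12.0, size=n), 35, 90)
    edu = np.clip(rng.normal(12.0, 2.2, size=n), 8, 20)
    sigma_on = np.sqrt(np.log(1 + (50.17 / 56.6) ** 2))
    onset = np.maximum(
        12.0, np.exp(rng.normal(np.log(56.6) - sigma_on**2 / 2, sigma_on, size=n))
    )
    eps = rng.normal(0.0, truth.noise_sd, size=(n, T)) if truth.noise_sd > 0 else 0.0
    scores = np.clip(base - np.outer(age - 65.0, truth.age_coefs) + eps, 0.0, 100.0)

    labels, fluent = zip(
        *(assign_subtype(damage[i], truth.subtype_rules) for i in range(n))
    )
    ids = [f"p{i+1:03d}" for i in range(n)]
    test_cols = [f"test_{t+1:02d}" for t in range(T)]
    return SyntheticCohort(
        lesions=MaskStack(lesions, hemi.affine, ids=list(ids)),
        behaviour=pd.DataFrame(scores, columns=test_cols, index=ids),
        demographics=pd.DataFrame(
            {"id": ids, "age": age, "edu": edu, "onset": onset}
        ).set_index("id", drop=False),
        subtype=pd.Series(labels, index=ids, name="subtype"),
        fluency=pd.Series(fluent, index=ids, name="fluency"),
        damage=pd.DataFrame(damage, columns=list(truth.factor_names), index=ids),
        truth=truth,
    )
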