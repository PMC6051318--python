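"""Voxel-based correlational mapping with permutation cluster-FWE correction.

Each analysed voxel gets the t statistic of the lesion-status term in an
ordinary least-squares fit of the behavioural outcome on
``[intercept, lesion, covariates]``. Family-wise error over clusters is
controlled nonparametrically: the outcome is permuted (Freedman-Lane scheme
when covariates are present), the t-map rebuilt, and the maximum
suprathreshold cluster extent recorded to form the null distribution.

The default test is one-tailed in the deficit direction (lesion presence
associated with *lower* scores), since the clusters of interest are deficit
correlates; two-tailed and positive tails are available.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .volumes import MaskStack, VolumeGrid

__all__ = [
    "StatMap",
    "Cluster",
    "ClusterSet",
    "voxelwise_glm",
    "threshold_and_cluster",
    "fwe_cluster_correction",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _as_flat_masks(lesions) -> tuple[np.ndarray, tuple, np.ndarray]:
    """Return (n, V) float lesion matrix plus grid shape and affine."""
    if isinstance(lesions, MaskStack):
        return lesions.flat().astype(float), lesions.grid_shape, lesions.affine
    arr = np.asarray(lesions)
    if arr.ndim != 4:
        raise ValueError("lesions must be a MaskStack or an (n, x, y, z) array")
    return arr.reshape(len(arr), -1).astype(float), arr.shape[1:], np.eye(4)


def _nuisance_basis(n: int, covariates) -> np.ndarray:
    """Orthonormal basis of [intercept, covariates]; errors if rank deficient."""
    cols = [np.ones(n)]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if len(C) != n:
            raise ValueError("covariate rows do not match the number of patients")
        cols.append(C)
    W = np.column_stack(cols)
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates)")
    Q, _ = np.linalg.qr(W)
    return Q


@dataclass
class StatMap:
    """Voxelwise lesion-term t statistics on the analysis mask."""

    t: np.ndarray  # 3D, NaN outside the analysis mask, +-inf on perfect fits
    df: int
    analysis_mask: np.ndarray  # 3D bool: voxels meeting coverage (and variance)
    perfect_fit: np.ndarray  # 3D bool: zero residual variance flagged
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def t_volume(self) -> VolumeGrid:
        return VolumeGrid(np.nan_to_num(self.t, nan=0.0, posinf=0.0, neginf=0.0),
                          self.affine)


def _tmaps(Lr: np.ndarray, Yr: np.ndarray, df: int) -> np.ndarray:
    """Lesion-term t for many outcomes at once.

    ``Lr`` is the (n, V) nuisance-residualised lesion matrix, ``Yr`` a (P, n)
    matrix of nuisance-residualised outcomes. Returns (P, V) t values; voxels
    with zero residualised-lesion variance give NaN, zero-residual fits give
    signed infinity (or 0 where the coefficient itself is 0).
    """
    ssL = np.einsum("ij,ij->j", Lr, Lr)
    ssY = np.einsum("ij,ij->i", Yr, Yr)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = Yr @ Lr  # (P, V)
        beta = num / ssL
        rss = np.maximum(ssY[:, None] - beta * num, 0.0)
        se = np.sqrt(rss / df / ssL)
        t = beta / se
    # zero-residual (perfect) fits: signed infinity unless the coefficient is
    # itself zero (e.g. a constant outcome), which is reported as t = 0
    zero_rss = rss <= 1e-10 * np.maximum(ssY[:, None], 1.0)
    sign = np.sign(beta)
    t = np.where(zero_rss, np.where(np.abs(beta) > 1e-12, sign * np.inf, 0.0), t)
    # lesion column collinear with nuisance: undefined
    t[:, ssL == 0] = np.nan
    return t


def voxelwise_glm(
    lesions,
    outcome,
    covariates=None,
    min_coverage: int | None = None,
) -> StatMap:
    """Mass-univariate lesion-deficit GLM.

    Only voxels lesioned in at least ``min_coverage`` patients *and* intact in
    at least ``min_coverage`` patients are analysed (default ``n // 10``).
    """
    L, shape, affine = _as_flat_masks(lesions)
    y = np.asarray(outcome, dtype=float).ravel()
    n = len(y)
    if L.shape[0] != n:
        raise ValueError("outcome length does not match the number of lesions")
    if min_coverage is None:
        min_coverage = max(1, n // 10)
    ncov = 0
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        ncov = 1 if C.ndim == 1 else C.shape[1]
    df = n - ncov - 2
    if df < 1:
        raise ValueError("not enough patients for the requested covariates")
    lesioned = L.sum(axis=0)
    cover = (lesioned >= min_coverage) & ((n - lesioned) >= min_coverage)
    if not cover.any():
        raise ValueError("analysis mask is empty at this coverage threshold")
    Q = _nuisance_basis(n, covariates)
    La = L[:, cover]
    Lr = La - Q @ (Q.T @ La)
    yr = y - Q @ (Q.T @ y)
    t_flat = _tmaps(Lr, yr[None, :], df)[0]

    tvol = np.full(int(np.prod(shape)), np.nan)
    perfect = np.zeros(int(np.prod(shape)), dtype=bool)
    amask = np.zeros(int(np.prod(shape)), dtype=bool)
    idx = np.flatnonzero(cover)
    valid = ~np.isnan(t_flat)
    amask[idx[valid]] = True
    tvol[idx] = t_flat
    perfect[idx[np.isinf(t_flat)]] = True
    return StatMap(
        t=tvol.reshape(shape),
        df=df,
        analysis_mask=amask.reshape(shape),
        perfect_fit=perfect.reshape(shape),
        affine=affine,
    )


@dataclass
class Cluster:
    label: int
    extent: int
    peak_t: float
    peak_ijk: tuple
    peak_mm: tuple
    fwe_p: float | None = None


@dataclass
class ClusterSet:
    label_map: VolumeGrid
    clusters: list
    df: int
    connectivity: int
    factor: str | None = None
    null_max_extent: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.clusters)

    def surviving_mask(self, alpha: float = 0.05) -> np.ndarray:
        """Union of clusters with FWE p below alpha (binary volume)."""
        out = np.zeros(self.label_map.shape, dtype=bool)
        for c in self.clusters:
            if c.fwe_p is not None and c.fwe_p < alpha:
                out |= self.label_map.data == c.label
        return out

    def table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "cluster": c.label,
                    "extent_voxels": c.extent,
                    "peak_t": c.peak_t,
                    "peak_x_mm": c.peak_mm[0],
                    "peak_y_mm": c.peak_mm[1],
                    "peak_z_mm": c.peak_mm[2],
                    "fwe_p": c.fwe_p,
                }
                for c in self.clusters
            ]
        )


def _supra(tmap: np.ndarray, df: int, voxel_p: float, tail: str) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        if tail == "deficit":
            crit = stats.t.ppf(voxel_p, df)
            return tmap < crit
        if tail == "positive":
            crit = stats.t.ppf(1.0 - voxel_p, df)
            return tmap > crit
        if tail == "two":
            crit = stats.t.ppf(1.0 - voxel_p / 2.0, df)
            return np.abs(tmap) > crit
    raise ValueError(f"unknown tail {tail!r}")


def threshold_and_cluster(
    statmap: StatMap,
    voxel_p: float = 0.005,
    tail: str = "deficit",
    connectivity: int = 26,
) -> ClusterSet:
    """Voxel-height threshold then connected-component labelling."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    supra = _supra(statmap.t, statmap.df, voxel_p, tail) & statmap.analysis_mask
    labels, nlab = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    clusters = []
    grid = VolumeGrid(labels.astype(np.int32), statmap.affine)
    for lab in range(1, nlab + 1):
        where = np.argwhere(labels == lab)
        tvals = statmap.t[labels == lab]
        absvals = np.abs(tvals)
        pk = int(np.argmax(absvals))
        peak_ijk = tuple(int(v) for v in where[pk])
        peak_mm = tuple(float(v) for v in grid.world_coords(peak_ijk))
        clusters.append(
            Cluster(
                label=lab,
                extent=int(len(where)),
                peak_t=float(tvals[pk]),
                peak_ijk=peak_ijk,
                peak_mm=peak_mm,
            )
        )
    clusters.sort(key=lambda c: -c.extent)
    return ClusterSet(grid, clusters, statmap.df, connectivity)


def _max_cluster_stat(
    supra: np.ndarray, structure, tvals=None, statistic: str = "extent"
) -> float:
    labels, nlab = ndimage.label(supra, structure=structure)
    if nlab == 0:
        return 0.0
    if statistic == "extent":
        return float(np.bincount(labels.ravel())[1:].max())
    # cluster mass: sum of |t| over each cluster
    mass = ndimage.sum_labels(np.abs(tvals), labels, index=np.arange(1, nlab + 1))
    return float(np.max(mass))


def fwe_cluster_correction(
    lesions,
    outcome,
    covariates=None,
    voxel_p: float = 0.005,
    n_perm: int = 1000,
    rng_seed=None,
    alpha: float = 0.05,
    tail: str = "deficit",
    connectivity: int = 26,
    min_coverage: int | None = None,
    statistic: str = "extent",
    factor: str | None = None,
) -> ClusterSet:
    """Permutation FWE correction of suprathreshold clusters.

    The null distribution of the maximum cluster ``statistic`` ("extent" or
    "mass") is built by permuting the nuisance-residualised outcome
    (Freedman-Lane) and rebuilding the t-map; each observed cluster gets
    ``fwe_p = (b + 1) / (n_perm + 1)`` with ``b`` the number of null maxima at
    or above its observed statistic.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if (n_perm + 1) * alpha < 1:
        warnings.warn(
            f"n_perm={n_perm} cannot resolve FWE p < {alpha}; increase n_perm",
            stacklevel=2,
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    L, shape, affine = _as_flat_masks(lesions)
    y = np.asarray(outcome, dtype=float).ravel()
    n = len(y)
    if min_coverage is None:
        min_coverage = max(1, n // 10)

    smap = voxelwise_glm(lesions, y, covariates, min_coverage)
    observed = threshold_and_cluster(smap, voxel_p, tail, connectivity)
    observed.factor = factor

    # permutation engine on the residualised system
    cover = smap.analysis_mask.ravel()
    Q = _nuisance_basis(n, covariates)
    La = L[:, cover]
    Lr = La - Q @ (Q.T @ La)
    yr = y - Q @ (Q.T @ y)
    perm_idx = np.stack([rng.permutation(n) for _ in range(n_perm)])
    Yp = yr[perm_idx]  # (n_perm, n)
    Yp = Yp - (Yp @ Q) @ Q.T  # re-residualise (Freedman-Lane)
    T = _tmaps(Lr, Yp, smap.df)

    structure = _STRUCTURES[connectivity]
    null_max = np.zeros(n_perm)
    tvol = np.zeros(int(np.prod(shape)))
    for b in range(n_perm):
        tvol[:] = np.nan
        tvol[cover] = T[b]
        supra = _supra(tvol.reshape(shape), smap.df, voxel_p, tail)
        supra &= smap.analysis_mask
        if not supra.any():
            continue
        null_max[b] = _max_cluster_stat(
            supra, structure, tvol.reshape(shape), statistic
        )

    for c in observed.clusters:
        if statistic == "extent":
            obs_stat = c.extent
        else:
            lab_data = observed.label_map.data == c.label
            obs_stat = float(np.abs(smap.t[lab_data]).sum())
        b = int(np.sum(null_max >= obs_stat))
        c.fwe_p = (b + 1) / (n_perm + 1)
    observed.null_max_extent = null_max
    return observed
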