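"""Behavioural dimensions: correlation-matrix PCA, varimax, regression scores.

The battery mixes percentage scores with raw counts, so the decomposition is
always of the correlation matrix (every test on unit-variance scale).
Components with eigenvalue strictly greater than 1.0 are retained (Kaiser
criterion), rotated by varimax with Kaiser row normalisation, and subject
scores are produced by the regression method: standardised data times
``R^{-1} Lambda``. Holdout subjects are standardised with the *training*
means and SDs, never their own.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "varimax",
    "varimax_criterion",
    "kaiser_count",
    "fit_pca",
    "score_subjects",
    "FactorModel",
    "BehaviouralPCA",
    "align_loadings",
    "congruence",
]


def kaiser_count(eigenvalues) -> int:
    """Number of components retained under the strict eigenvalue > 1.0 rule."""
    return int(np.sum(np.asarray(eigenvalues, dtype=float) > 1.0))


def varimax_criterion(loadings: np.ndarray, row_normalize: bool = True) -> float:
    """Sum over factors of the variance of squared loadings.

    With ``row_normalize`` (Kaiser normalisation) each row is scaled to unit
    communality before the criterion is evaluated.
    """
    L = np.asarray(loadings, dtype=float)
    if row_normalize:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    sq = L**2
    return float(sq.var(axis=0).sum())


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation by pairwise (Jacobi) planar rotations.

    Returns ``(rotated_loadings, rotation)`` with ``rotation`` orthonormal and
    ``rotated = loadings @ rotation``. The criterion is non-decreasing across
    sweeps; iteration stops when a full sweep gains less than ``tol`` or after
    ``max_iter`` sweeps. K = 1 returns the identity rotation.
    """
    L0 = np.asarray(loadings, dtype=float)
    if L0.ndim != 2:
        raise ValueError("loadings must be 2D")
    T, K = L0.shape
    if K == 1:
        return L0.copy(), np.eye(1)
    h = np.sqrt((L0**2).sum(axis=1))
    h_safe = np.where(h == 0, 1.0, h)
    Ln = L0 / h_safe[:, None] if kaiser_normalize else L0.copy()
    R = np.eye(K)
    crit = varimax_criterion(Ln, row_normalize=False)
    for _ in range(max_iter):
        for p, q in itertools.combinations(range(K), 2):
            x, y = Ln[:, p], Ln[:, q]
            u = x * x - y * y
            v = 2.0 * x * y
            A, B = u.sum(), v.sum()
            C = (u * u - v * v).sum()
            D = 2.0 * (u * v).sum()
            num = D - 2.0 * A * B / T
            den = C - (A * A - B * B) / T
            phi = 0.25 * np.arctan2(num, den)
            if abs(phi) < 1e-12:
                continue
            c, s = np.cos(phi), np.sin(phi)
            G = np.array([[c, -s], [s, c]])
            Ln[:, [p, q]] = Ln[:, [p, q]] @ G
            R[:, [p, q]] = R[:, [p, q]] @ G
        new_crit = varimax_criterion(Ln, row_normalize=False)
        if new_crit - crit < tol:
            crit = new_crit
            break
        crit = new_crit
    rotated = (Ln * h_safe[:, None]) if kaiser_normalize else Ln
    return rotated, R


@dataclass
class FactorModel:
    """Fitted factor solution plus everything needed to score new subjects."""

    eigenvalues: np.ndarray  # full spectrum of the training correlation matrix
    loadings: pd.DataFrame  # T x K rotated loadings (tests x factors)
    score_weights: pd.DataFrame  # T x K regression-method weights
    train_means: pd.Series
    train_sds: pd.Series
    rotation: np.ndarray

    @property
    def n_retained(self) -> int:
        return self.loadings.shape[1]

    @property
    def test_names(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def factor_names(self) -> list[str]:
        return list(self.loadings.columns)

    def score(self, scores: pd.DataFrame | np.ndarray) -> pd.DataFrame:
        """Regression-method factor scores for (possibly new) subjects."""
        return score_subjects(self, scores)

    def explained_variance(self) -> pd.Series:
        """Post-rotation variance explained by each retained factor."""
        return pd.Series(
            (self.loadings.values**2).sum(axis=0), index=self.factor_names
        )

    def summary(self) -> str:
        lines = [
            "Behavioural PCA (correlation matrix, varimax rotation)",
            f"  tests: {len(self.test_names)}   retained factors: {self.n_retained}",
            "  eigenvalues: "
            + ", ".join(f"{v:.3f}" for v in self.eigenvalues[: self.n_retained + 2]),
            "",
            self.loadings.round(3).to_string(),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "loadings": self.loadings.to_dict(),
            "score_weights": self.score_weights.to_dict(),
            "train_means": self.train_means.to_dict(),
            "train_sds": self.train_sds.to_dict(),
        }


def _as_frame(scores, test_names=None) -> pd.DataFrame:
    if isinstance(scores, pd.DataFrame):
        return scores
    scores = np.asarray(scores, dtype=float)
    if test_names is None:
        test_names = [f"test_{t+1:02d}" for t in range(scores.shape[1])]
    return pd.DataFrame(scores, columns=test_names)


def fit_pca(scores, test_names=None) -> FactorModel:
    """Fit the correlation-matrix PCA with Kaiser retention and varimax.

    Raises if any test has zero variance (named in the error) or if no
    eigenvalue exceeds 1.0 (a degenerate battery for this workflow).
    """
    df = _as_frame(scores, test_names)
    X = df.to_numpy(dtype=float)
    n, T = X.shape
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        raise ValueError(
            "zero-variance test column(s): " + ", ".join(df.columns[i] for i in dead)
        )
    Z = (X - means) / sds
    Rmat = (Z.T @ Z) / (n - 1)
    np.fill_diagonal(Rmat, 1.0)
    w, V = np.linalg.eigh(Rmat)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    K = kaiser_count(w)
    if K == 0:
        raise ValueError("no eigenvalue exceeds 1.0; nothing to retain")
    load = V[:, :K] * np.sqrt(w[:K])
    rotated, rotation = varimax(load)
    # order by post-rotation explained variance, then flip signs so the
    # highest-|loading| test of each factor loads positively
    ev = (rotated**2).sum(axis=0)
    order2 = np.argsort(ev)[::-1]
    rotated = rotated[:, order2]
    rotation = rotation[:, order2]
    flip = np.sign(rotated[np.abs(rotated).argmax(axis=0), np.arange(K)])
    flip[flip == 0] = 1.0
    rotated = rotated * flip
    rotation = rotation * flip
    weights = np.linalg.pinv(Rmat) @ rotated
    fnames = [f"factor_{k+1}" for k in range(K)]
    return FactorModel(
        eigenvalues=w,
        loadings=pd.DataFrame(rotated, index=df.columns, columns=fnames),
        score_weights=pd.DataFrame(weights, index=df.columns, columns=fnames),
        train_means=pd.Series(means, index=df.columns),
        train_sds=pd.Series(sds, index=df.columns),
        rotation=rotation,
    )


def score_subjects(model: FactorModel, scores) -> pd.DataFrame:
    """Score subjects with training standardisation constants and weights."""
    df = _as_frame(scores, model.test_names)
    if list(df.columns) != model.test_names:
        if set(df.columns) == set(model.test_names):
            df = df[model.test_names]
        else:
            raise ValueError(
                "battery mismatch: expected tests "
                f"{model.test_names}, got {list(df.columns)}"
            )
    Z = (df.to_numpy(dtype=float) - model.train_means.values) / model.train_sds.values
    S = Z @ model.score_weights.values
    return pd.DataFrame(S, index=df.index, columns=model.factor_names)


class BehaviouralPCA:
    """Model-style wrapper: ``BehaviouralPCA(scores).fit()`` -> FactorModel."""

    def __init__(self, scores, test_names=None):
        self.data = _as_frame(scores, test_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, test_columns=None) -> "BehaviouralPCA":
        cols = test_columns if test_columns is not None else list(df.columns)
        return cls(df[cols])

    def fit(self) -> FactorModel:
        return fit_pca(self.data)


# ---------------------------------------------------------------------------
# loading-matrix comparison helpers (fold stability, recovery tests)
# ---------------------------------------------------------------------------

def congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker congruence coefficient between two loading vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def align_loadings(reference: np.ndarray, other: np.ndarray):
    """Permute and sign-flip ``other``'s columns to best match ``reference``.

    Returns ``(aligned, congruences)`` where congruences are the per-factor
    |Tucker| coefficients after optimal one-to-one assignment.
    """
    A = np.asarray(reference, dtype=float)
    B = np.asarray(other, dtype=float)
    K = A.shape[1]
    C = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            C[i, j] = abs(congruence(A[:, i], B[:, j]))
    rows, cols = linear_sum_assignment(-C)
    aligned = B[:, cols].copy()
    for i in range(K):
        if congruence(A[:, i], aligned[:, i]) < 0:
            aligned[:, i] *= -1
    return aligned, C[rows, cols]
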