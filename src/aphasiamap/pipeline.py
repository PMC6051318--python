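"""Nested cross-validated lesion-to-behaviour prediction.

The pipeline, run independently inside every training fold so that no holdout
information reaches any fitting step:

1. split patients into k random folds;
2. PCA the training battery, score training patients on the retained factors;
3. map each factor to lesion clusters (permutation cluster-FWE VBCM) on the
   training patients, with lesion volume and age as nuisance covariates;
4. convert every patient's lesion into percentage-damage predictors using the
   fold's clusters;
5. fit one OLS regression per behavioural test on the training patients;
6. predict the holdout fold and record the predicted-observed correlation.

Model fit is summarised by the adjusted R^2 of the full-cohort fit, predictive
power by the mean per-fold holdout correlation (a pooled-prediction
correlation is reported as a secondary column). Significance is assessed by
Monte-Carlo randomisation of the outcome, model pairs are compared with
Wilcoxon signed-rank tests, and poorly-predicted patients are flagged by the
root-residual-sum-of-squares rule (> mean + 2 SD).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .factors import fit_pca
from .predictors import ModelSpec, compute_predictors, model_specs
from .vbcm import fwe_cluster_correction
from .volumes import MaskStack, VolumeGrid

__all__ = [
    "make_folds",
    "fit_linear_model",
    "adjusted_r2",
    "monte_carlo_null",
    "compare_models",
    "flag_poor_predictions",
    "CVConfig",
    "run_cv",
    "CVResult",
    "LesionPredictionModel",
]


def make_folds(n: int, k: int, rng_seed=None) -> np.ndarray:
    """Uniformly random partition of n patients into k folds (sizes within 1)."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < k:
        raise ValueError(f"cannot split {n} patients into {k} folds")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class LinearFit:
    params: pd.Series  # includes "const"
    r2: float
    adj_r2: float
    pvalues: pd.Series
    _results: object = field(repr=False, default=None)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = pd.DataFrame(X)
        Xc = sm.add_constant(X, has_constant="add")
        return Xc.to_numpy(dtype=float) @ self.params.to_numpy()


def fit_linear_model(X, y) -> LinearFit:
    """OLS with intercept; raises on a singular design."""
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    Xc = sm.add_constant(X, has_constant="add")
    arr = Xc.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError("singular design matrix")
    res = sm.OLS(y, arr).fit()
    r2 = float(res.rsquared) if p > 0 else 0.0
    return LinearFit(
        params=pd.Series(res.params, index=Xc.columns),
        r2=r2,
        adj_r2=adjusted_r2(r2, n, p),
        pvalues=pd.Series(res.pvalues, index=Xc.columns),
        _results=res,
    )


@dataclass
class MonteCarloNull:
    observed: float
    null: np.ndarray
    p: float


def monte_carlo_null(X, y, n_iter: int = 10000, rng_seed=None) -> MonteCarloNull:
    """Permutation null of the adjusted R^2: p = (b + 1)/(n_iter + 1)."""
    if n_iter < 100:
        raise ValueError("n_iter must be at least 100")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Xc = sm.add_constant(X, has_constant="add").to_numpy(dtype=float)
    Q, _ = np.linalg.qr(Xc)
    tss = float(((y - y.mean()) ** 2).sum())

    def adj_of(vec_rows: np.ndarray) -> np.ndarray:
        proj = vec_rows @ Q  # (m, p+1)
        ess = (proj**2).sum(axis=1) - n * vec_rows.mean(axis=1) ** 2
        r2 = ess / tss
        return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)

    observed = float(adj_of(y[None, :])[0])
    perm = np.stack([rng.permutation(y) for _ in range(n_iter)])
    null = adj_of(perm)
    b = int(np.sum(null >= observed))
    return MonteCarloNull(observed=observed, null=null, p=(b + 1) / (n_iter + 1))


@dataclass
class WilcoxonComparison:
    statistic: float
    p: float
    n_nonzero: int
    method: str


def compare_models(metric_a, metric_b) -> WilcoxonComparison:
    """Two-sided Wilcoxon signed-rank test on paired per-test metrics.

    Zero differences are dropped; the null is exact for n <= 25 (tie-free
    enumeration) and a normal approximation with continuity correction above.
    With very few pairs the test has no power (minimum two-sided p is
    2^{-(n-1)}, so p >= 0.5 at n = 2).
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired metric vectors must have equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero")
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(
        nz,
        zero_method="wilcox",
        alternative="two-sided",
        correction=(method == "approx"),
        method=method,
    )
    return WilcoxonComparison(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        n_nonzero=int(nz.size),
        method=method,
    )


def flag_poor_predictions(observed, predicted):
    """Root-RSS outlier rule: flag patients with score > mean + 2 SD.

    ``score_i = sqrt(sum_t (obs_it - pred_it)^2)`` across all tests.
    Returns ``(flagged_indices, scores)``.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have matching shapes")
    if obs.shape[0] < 3:
        raise ValueError("need at least 3 patients for a stable SD")
    score = np.sqrt(((obs - pred) ** 2).sum(axis=1))
    cut = score.mean() + 2.0 * score.std(ddof=1)
    return np.flatnonzero(score > cut), score


# ---------------------------------------------------------------------------
# the cross-validation engine
# ---------------------------------------------------------------------------


@dataclass
class CVConfig:
    k_folds: int = 5
    voxel_p: float = 0.005
    fwe_alpha: float = 0.05
    n_perm_fwe: int = 1000
    min_coverage: int | None = None
    connectivity: int = 26
    tail: str = "deficit"
    vbcm_covariates: tuple = ("LV", "age")
    partitions: object = "derive"  # "derive" or {name: binary volume}
    monte_carlo: int | None = None
    n_factors: int | None = None  # target factor count when deriving


def _dedupe(X: pd.DataFrame):
    """Drop exactly duplicated and constant columns (kept deterministic)."""
    drop, seen = [], []
    for c in X.columns:
        col = X[c].to_numpy()
        if np.all(col == col[0]):
            drop.append(c)
            continue
        if any(np.array_equal(col, s) for s in seen):
            drop.append(c)
            continue
        seen.append(col)
    return X.drop(columns=drop), drop


def _derive_partitions(lesions, hemi, behaviour, base_pred, config, n_target, rng, events, tag):
    """PCA + per-factor FWE-corrected VBCM on one patient subset."""
    fm = fit_pca(behaviour)
    scores = fm.score(behaviour)
    cov_cols = [c for c in config.vbcm_covariates if c in base_pred.columns]
    cov = base_pred[cov_cols].to_numpy(dtype=float) if cov_cols else None
    hemi_data = hemi.data if isinstance(hemi, VolumeGrid) else np.asarray(hemi, bool)
    masks, missing = {}, []
    for k in range(n_target):
        name = f"factor_{k+1}"
        if k < fm.n_retained:
            cs = fwe_cluster_correction(
                lesions,
                scores.iloc[:, k].to_numpy(),
                covariates=cov,
                voxel_p=config.voxel_p,
                n_perm=config.n_perm_fwe,
                rng_seed=rng,
                alpha=config.fwe_alpha,
                tail=config.tail,
                connectivity=config.connectivity,
                min_coverage=config.min_coverage,
                factor=name,
            )
            m = cs.surviving_mask(config.fwe_alpha)
            if m.any():
                masks[name] = m
                continue
            events.append(f"{tag}: no surviving cluster for {name}; residual fallback")
        else:
            events.append(f"{tag}: only {fm.n_retained} factors retained; "
                          f"residual fallback for {name}")
        missing.append(name)
    union = np.zeros_like(hemi_data)
    for m in masks.values():
        union |= m
    residual = hemi_data & ~union
    for name in missing:
        masks[name] = residual
    return {f"factor_{k+1}": masks[f"factor_{k+1}"] for k in range(n_target)}


@dataclass
class CVResult:
    """Per-test, per-model fit and prediction metrics from the k-fold pipeline."""

    adj_r2: pd.DataFrame  # tests x models (full-cohort fit)
    holdout_corr: pd.DataFrame  # tests x models, mean of per-fold Pearson r
    pooled_corr: pd.DataFrame  # tests x models, single pooled correlation
    fold_corr: dict  # model -> (tests x folds) DataFrame
    predictions: dict  # model -> (n x tests) pooled holdout predictions
    mc_p: pd.DataFrame | None
    fold_plan: np.ndarray
    model_means: pd.DataFrame
    best_model_counts: pd.DataFrame
    winning_model: str
    coefficients: pd.DataFrame  # per test: full-cohort betas of winning model
    coef_pvalues: pd.DataFrame
    flagged_patients: list
    residual_scores: pd.Series
    events: list

    def compare(self, model_a: str, model_b: str, metric: str = "holdout_corr"):
        """Wilcoxon signed-rank comparison of two models on a per-test metric."""
        table = getattr(self, metric)
        return compare_models(table[model_a], table[model_b])

    def summary(self) -> str:
        lines = [
            "Cross-validated lesion-to-behaviour prediction",
            f"  tests: {self.adj_r2.shape[0]}   models: {self.adj_r2.shape[1]}   "
            f"folds: {int(self.fold_plan.max()) + 1}",
            "",
            "Model means (adjusted R^2 | mean holdout r | pooled r):",
            self.model_means.round(3).to_string(),
            "",
            f"Winning model ({self.model_means['mean_holdout_corr'].idxmax()}): "
            f"best on {int(self.best_model_counts['holdout_corr'].max())} tests "
            "by holdout correlation",
            f"Poorly predicted patients (root-RSS > mean + 2 SD): "
            f"{self.flagged_patients if self.flagged_patients else 'none'}",
        ]
        if self.events:
            lines += ["", f"Fold events logged: {len(self.events)}"]
        return "\n".join(lines)

    def plot_metrics(self, ax=None):
        """Bar chart of per-model mean metrics."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        self.model_means[["mean_adj_r2", "mean_holdout_corr"]].plot.bar(ax=ax)
        ax.set_ylabel("mean across tests")
        ax.set_xlabel("model")
        return ax


def run_cv(
    lesions: MaskStack,
    hemisphere: VolumeGrid,
    behaviour: pd.DataFrame,
    demographics: pd.DataFrame,
    specs: list | None = None,
    config: CVConfig | None = None,
    rng_seed=0,
) -> CVResult:
    """Run the full k-fold pipeline for every model variant."""
    config = config or CVConfig()
    rng = np.random.default_rng(rng_seed)
    n = len(behaviour)
    tests = list(behaviour.columns)
    folds = make_folds(n, config.k_folds, rng)
    events: list[str] = []

    base_pred = compute_predictors(lesions, hemisphere, None, demographics)
    needs_partitions = True
    if specs is not None:
        needs_partitions = any("residual_LV" in s.columns for s in specs)

    fixed = isinstance(config.partitions, dict)
    if needs_partitions and fixed:
        cluster_names = list(config.partitions.keys())
        full_clusters = config.partitions
    elif needs_partitions:
        probe = fit_pca(behaviour)
        n_target = config.n_factors or probe.n_retained
        cluster_names = [f"factor_{k+1}" for k in range(n_target)]
        full_clusters = _derive_partitions(
            lesions, hemisphere, behaviour, base_pred, config, n_target, rng,
            events, "full-cohort",
        )
    else:
        cluster_names, full_clusters = [], None

    if specs is None:
        specs = model_specs(cluster_names)

    def _predictors(clusters, tag):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            table = compute_predictors(
                lesions, hemisphere, clusters, demographics,
                on_empty_residual="zero",
            )
        for w in caught:
            events.append(f"{tag}: {w.message}")
        return table

    pred_full = (
        _predictors(full_clusters, "full-cohort") if needs_partitions else base_pred
    )

    # fold-specific predictor tables (clusters re-derived on training data only)
    pred_folds = []
    for f in range(config.k_folds):
        train = np.flatnonzero(folds != f)
        if needs_partitions and not fixed:
            fold_clusters = _derive_partitions(
                lesions.subset(train),
                hemisphere,
                behaviour.iloc[train],
                base_pred.iloc[train],
                config,
                len(cluster_names),
                rng,
                events,
                f"fold {f}",
            )
        else:
            fold_clusters = full_clusters
        pred_folds.append(
            _predictors(fold_clusters, f"fold {f}") if needs_partitions else base_pred
        )

    model_names = [s.name for s in specs]
    adj = pd.DataFrame(index=tests, columns=model_names, dtype=float)
    hold = pd.DataFrame(index=tests, columns=model_names, dtype=float)
    pooled = pd.DataFrame(index=tests, columns=model_names, dtype=float)
    mc = pd.DataFrame(index=tests, columns=model_names, dtype=float) if config.monte_carlo else None
    fold_corr: dict[str, pd.DataFrame] = {}
    predictions: dict[str, pd.DataFrame] = {}

    for spec in specs:
        fc = pd.DataFrame(index=tests, columns=range(config.k_folds), dtype=float)
        pred_mat = pd.DataFrame(
            index=behaviour.index, columns=tests, dtype=float
        )
        X_full, dropped = _dedupe(spec.design(pred_full))
        if dropped:
            events.append(f"{spec.name}: dropped degenerate columns {dropped} (full)")
        for t in tests:
            y = behaviour[t].to_numpy(dtype=float)
            fit = fit_linear_model(X_full, y)
            adj.loc[t, spec.name] = fit.adj_r2
            if config.monte_carlo:
                mc.loc[t, spec.name] = monte_carlo_null(
                    X_full, y, config.monte_carlo, rng
                ).p
        for f in range(config.k_folds):
            train = folds != f
            test_idx = ~train
            Xf = spec.design(pred_folds[f])
            Xtr, dropped = _dedupe(Xf.iloc[np.flatnonzero(train)])
            if dropped:
                events.append(
                    f"{spec.name} fold {f}: dropped degenerate columns {dropped}"
                )
            Xte = Xf.iloc[np.flatnonzero(test_idx)][Xtr.columns]
            for t in tests:
                y = behaviour[t].to_numpy(dtype=float)
                fit = fit_linear_model(Xtr, y[train])
                yp = fit.predict(Xte)
                pred_mat.loc[behaviour.index[test_idx], t] = yp
                yo = y[test_idx]
                if np.std(yo) == 0 or np.std(yp) == 0:
                    fc.loc[t, f] = np.nan
                else:
                    fc.loc[t, f] = float(np.corrcoef(yo, yp)[0, 1])
        fold_corr[spec.name] = fc
        predictions[spec.name] = pred_mat
        hold[spec.name] = fc.mean(axis=1, skipna=True)
        for t in tests:
            yo = behaviour[t].to_numpy(dtype=float)
            yp = pred_mat[t].to_numpy(dtype=float)
            pooled.loc[t, spec.name] = (
                float(np.corrcoef(yo, yp)[0, 1]) if np.std(yp) > 0 else np.nan
            )

    model_means = pd.DataFrame(
        {
            "mean_adj_r2": adj.mean(axis=0),
            "mean_holdout_corr": hold.mean(axis=0),
            "mean_pooled_corr": pooled.mean(axis=0),
        }
    )
    best = pd.DataFrame(
        {
            "adj_r2": adj.idxmax(axis=1).value_counts().reindex(model_names, fill_value=0),
            "holdout_corr": hold.idxmax(axis=1).value_counts().reindex(model_names, fill_value=0),
        }
    )
    winning = str(model_means["mean_holdout_corr"].idxmax())
    win_spec = next(s for s in specs if s.name == winning)
    Xw, _ = _dedupe(win_spec.design(pred_full))
    coefs, pvals = {}, {}
    for t in tests:
        fit = fit_linear_model(Xw, behaviour[t].to_numpy(dtype=float))
        coefs[t] = fit.params
        pvals[t] = fit.pvalues
    coefficients = pd.DataFrame(coefs).T
    coef_pvalues = pd.DataFrame(pvals).T

    flagged_idx, scores = flag_poor_predictions(
        behaviour.to_numpy(dtype=float), predictions[winning].to_numpy(dtype=float)
    )
    residual_scores = pd.Series(scores, index=behaviour.index, name="root_rss")
    flagged = [behaviour.index[i] for i in flagged_idx]

    return CVResult(
        adj_r2=adj,
        holdout_corr=hold,
        pooled_corr=pooled,
        fold_corr=fold_corr,
        predictions=predictions,
        mc_p=mc,
        fold_plan=folds,
        model_means=model_means,
        best_model_counts=best,
        winning_model=winning,
        coefficients=coefficients,
        coef_pvalues=coef_pvalues,
        flagged_patients=flagged,
        residual_scores=residual_scores,
        events=events,
    )


class LesionPredictionModel:
    """Statsmodels-style front end: construct from data, ``fit`` -> results.

    Parameters
    ----------
    behaviour : DataFrame (n x T)
        Test scores, one column per test.
    lesions : MaskStack
        Binary lesion masks on a common grid, one per patient.
    hemisphere : VolumeGrid
        Binary left-hemisphere reference mask.
    demographics : DataFrame
        Columns age, edu (years) and onset (months).
    specs, config : optional
        Model variants (default: the ten LV / LV-PCA variants) and pipeline
        settings (``CVConfig``).
    """

    def __init__(self, behaviour, lesions, hemisphere, demographics,
                 specs=None, config=None):
        self.behaviour = behaviour
        self.lesions = lesions
        self.hemisphere = hemisphere
        self.demographics = demographics
        self.specs = specs
        self.config = config or CVConfig()

    @classmethod
    def from_cohort(cls, cohort, specs=None, config=None) -> "LesionPredictionModel":
        """Build directly from a :class:`~aphasiamap.simulate.SyntheticCohort`."""
        return cls(
            cohort.behaviour,
            cohort.lesions,
            cohort.truth.hemisphere,
            cohort.demographics,
            specs=specs,
            config=config,
        )

    def fit(self, rng_seed=0) -> CVResult:
        return run_cv(
            self.lesions,
            self.hemisphere,
            self.behaviour,
            self.demographics,
            self.specs,
            self.config,
            rng_seed,
        )
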