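"""Aphasia classification from lesion predictors, with permutation chance.

Fluent/non-fluent status is predicted with a binary logistic regression and
the seven-way subtype with a multinomial (softmax) logistic regression, both
maximum-likelihood fits with an intercept. Accuracy is in-sample by default —
the calibrated comparison point is the permutation "chance" level, obtained by
refitting the same model on label permutations (which preserves class
multiplicities); in-sample null accuracy sits at or above the majority-class
proportion, which is exactly why the permutation mean, not 1/#classes, is the
honest chance level. A cross-validated accuracy mode is available.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ClassificationResult",
    "fit_binary_logistic",
    "fit_multinomial",
    "permutation_chance",
    "AphasiaClassifier",
]


@dataclass
class ClassificationResult:
    model: str
    classes: list
    accuracy: float  # overall, percent
    per_class_accuracy: pd.Series  # percent
    confusion: pd.DataFrame  # rows true, columns predicted
    coefficients: pd.DataFrame | None
    coef_pvalues: pd.DataFrame | None
    predicted: np.ndarray
    separation: bool = False
    n: int = 0
    chance_mean: float | None = None  # permutation mean chance, percent
    permutation_p: float | None = None
    null_accuracies: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            f"{self.model} classification (n = {self.n})",
            f"  overall accuracy: {self.accuracy:.1f}%",
            "  per-class: "
            + ", ".join(
                f"{c}: {a:.1f}%" for c, a in self.per_class_accuracy.items()
            ),
        ]
        if self.chance_mean is not None:
            lines.append(
                f"  permutation chance: {self.chance_mean:.2f}%  "
                f"(p = {self.permutation_p:.4g})"
            )
        if self.separation:
            lines.append("  warning: (quasi-)separation detected")
        return "\n".join(lines)


def _prepare(X, labels):
    X = pd.DataFrame(X)
    y = pd.Series(labels).reset_index(drop=True)
    if len(X) != len(y):
        raise ValueError("X and labels must have equal length")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        warnings.warn(
            f"dropping zero-variance predictor column(s): {const}", stacklevel=3
        )
        X = X.drop(columns=const)
    return X.reset_index(drop=True), y


def _accuracy_tables(y: pd.Series, pred: np.ndarray, classes):
    confusion = pd.crosstab(
        pd.Categorical(y, categories=classes),
        pd.Categorical(pred, categories=classes),
        dropna=False,
    )
    confusion.index = classes
    confusion.columns = classes
    correct = np.asarray(y) == np.asarray(pred)
    overall = 100.0 * correct.mean()
    per_class = pd.Series(
        {
            c: 100.0 * correct[np.asarray(y) == c].mean() if (np.asarray(y) == c).any() else np.nan
            for c in classes
        }
    )
    return overall, per_class, confusion


def fit_binary_logistic(X, labels) -> ClassificationResult:
    """ML logistic fit; predicted class is posterior >= 0.5.

    Perfect separation does not raise: the fit is run with bounded iterations
    and flagged in the result.
    """
    X, y = _prepare(X, labels)
    classes = sorted(y.unique(), key=str)
    if len(classes) != 2:
        raise ValueError(f"binary classification needs exactly 2 classes, got {classes}")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    ybin = (y == classes[1]).to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(ybin, Xc).fit(disp=0, maxiter=200)
        except Exception:
            res = sm.Logit(ybin, Xc).fit(disp=0, method="bfgs", maxiter=200)
        prob = np.asarray(res.predict(Xc))
    if np.all((prob > 0.999) == (ybin == 1)) and np.all((prob < 0.001) == (ybin == 0)):
        separation = True
    pred = np.where(prob >= 0.5, classes[1], classes[0])
    overall, per_class, confusion = _accuracy_tables(y, pred, classes)
    if overall == 100.0 and (prob.max() > 0.999 or prob.min() < 0.001):
        separation = True
    return ClassificationResult(
        model="binary logistic",
        classes=classes,
        accuracy=overall,
        per_class_accuracy=per_class,
        confusion=confusion,
        coefficients=pd.DataFrame({"beta": res.params}, index=Xc.columns),
        coef_pvalues=pd.DataFrame({"p": res.pvalues}, index=Xc.columns),
        predicted=pred,
        separation=separation,
        n=n,
    )


def fit_multinomial(X, labels) -> ClassificationResult:
    """Softmax ML fit over all classes; in-sample argmax classification."""
    X, y = _prepare(X, labels)
    classes = sorted(y.unique(), key=str)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = y.value_counts()
    tiny = counts[counts < 2]
    if len(tiny):
        warnings.warn(
            f"class(es) with fewer than 2 members: {list(tiny.index)}", stacklevel=2
        )
    codes = pd.Categorical(y, categories=classes).codes.astype(int)
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MNLogit(codes, Xc).fit(disp=0, maxiter=500)
        except Exception:
            res = None
        if res is None or not np.all(np.isfinite(np.asarray(res.params))):
            # (quasi-)separation: newton diverges; capped quasi-Newton fit
            res = sm.MNLogit(codes, Xc).fit(disp=0, method="lbfgs", maxiter=1000)
        prob = np.asarray(res.predict(Xc))
    pred = np.asarray(classes)[prob.argmax(axis=1)]
    overall, per_class, confusion = _accuracy_tables(y, pred, classes)
    params = pd.DataFrame(
        np.asarray(res.params), index=Xc.columns, columns=classes[1:]
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pv = np.asarray(res.pvalues)
    except ValueError:  # no parameter covariance under the fallback optimiser
        pv = np.full_like(np.asarray(res.params), np.nan)
    pvals = pd.DataFrame(pv, index=Xc.columns, columns=classes[1:])
    separation = bool(np.any(np.abs(np.asarray(res.params)) > 50) or not np.all(np.isfinite(np.asarray(res.params))))
    return ClassificationResult(
        model="multinomial logistic",
        classes=classes,
        accuracy=overall,
        per_class_accuracy=per_class,
        confusion=confusion,
        coefficients=params,
        coef_pvalues=pvals,
        predicted=pred,
        separation=separation,
        n=len(y),
    )


def _fast_insample_accuracy(Xa: np.ndarray, y_codes: np.ndarray) -> float:
    """Unpenalised ML logistic accuracy used inside the permutation loop."""
    clf = LogisticRegression(C=np.inf, max_iter=200, tol=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xa, y_codes)
        return float((clf.predict(Xa) == y_codes).mean())


def permutation_chance(
    X, labels, n_iter: int = 10000, rng_seed=None, observed_accuracy=None
):
    """Permutation null of in-sample classification accuracy.

    Labels are shuffled (class multiplicities preserved exactly), the model
    refit, and in-sample accuracy recorded. Returns
    ``(mean_chance_pct, p, null_accuracies_pct)`` with
    ``p = (b + 1)/(n_iter + 1)``, ``b`` the number of null accuracies at or
    above the observed one.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be at least 100")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    X, y = _prepare(X, labels)
    classes = sorted(y.unique(), key=str)
    codes = pd.Categorical(y, categories=classes).codes.astype(int)
    Xa = X.to_numpy(dtype=float)
    if observed_accuracy is None:
        fit = (
            fit_binary_logistic(X, y) if len(classes) == 2 else fit_multinomial(X, y)
        )
        observed_accuracy = fit.accuracy
    null = np.empty(n_iter)
    for b in range(n_iter):
        null[b] = _fast_insample_accuracy(Xa, rng.permutation(codes))
    null *= 100.0
    bcount = int(np.sum(null >= observed_accuracy))
    return float(null.mean()), (bcount + 1) / (n_iter + 1), null


class AphasiaClassifier:
    """Model-style wrapper choosing binary vs multinomial by label count.

    ``AphasiaClassifier(X, labels).fit()`` returns a
    :class:`ClassificationResult`; ``fit(permutations=N, rng_seed=s)`` also
    attaches the permutation chance level and p-value. ``fit(cv=k)`` reports
    k-fold cross-validated accuracy instead of in-sample accuracy.
    """

    def __init__(self, X, labels, name: str | None = None):
        self.X = pd.DataFrame(X)
        self.labels = pd.Series(labels).reset_index(drop=True)
        self.name = name

    def fit(self, permutations: int | None = None, rng_seed=None, cv: int | None = None):
        binary = self.labels.nunique() == 2
        fitter = fit_binary_logistic if binary else fit_multinomial
        result = fitter(self.X, self.labels)
        if self.name:
            result.model = f"{self.name} ({result.model})"
        if cv:
            from .pipeline import make_folds

            folds = make_folds(len(self.labels), cv, rng_seed)
            correct = np.zeros(len(self.labels), dtype=bool)
            for f in range(cv):
                tr = np.flatnonzero(folds != f)
                te = np.flatnonzero(folds == f)
                if self.labels.iloc[tr].nunique() < self.labels.nunique():
                    continue  # a class absent from training; fold skipped
                sub = fitter(self.X.iloc[tr], self.labels.iloc[tr])
                clf = LogisticRegression(C=np.inf, max_iter=200, tol=1e-6)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf.fit(self.X.iloc[tr].to_numpy(dtype=float), self.labels.iloc[tr])
                    pred = clf.predict(self.X.iloc[te].to_numpy(dtype=float))
                correct[te] = pred == self.labels.iloc[te].to_numpy()
            result.accuracy = 100.0 * correct.mean()
            result.model += " [cross-validated]"
        if permutations:
            mean_chance, p, null = permutation_chance(
                self.X,
                self.labels,
                n_iter=permutations,
                rng_seed=rng_seed,
                observed_accuracy=result.accuracy,
            )
            result.chance_mean = mean_chance
            result.permutation_p = p
            result.null_accuracies = null
        return result
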