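"""Model comparison and interpretable logistic inference.

The binary target is HAC (highly abundant cytoplasmic, label 1) versus
extracellular (label 0).  Two distinct logistic fits are used:

* an unpenalized maximum-likelihood fit for inference — Wald standard
  errors from the inverse Fisher information, odds ratios exp(beta) with
  normal 95% confidence intervals exp(beta +/- 1.96 SE); and
* a cross-validated, optionally L2-regularized fit inside the model
  comparison, where KNN, random forest, RBF-SVM and logistic regression are
  grid-search tuned on repeated stratified 80/20 splits and scored by
  accuracy and ROC-AUC on the held-out fifth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_curve, auc as _auc
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SplitSpec",
    "LogisticFit",
    "ModelEvaluation",
    "stratified_split",
    "fit_logistic_mle",
    "wald_report",
    "roc_auc",
    "compare_models",
    "DEFAULT_GRIDS",
    "DEFAULT_SPLIT_SEEDS",
]

Z_95 = 1.96  # normal 95% CI multiplier

DEFAULT_SPLIT_SEEDS = (0, 1, 2, 3, 4)

DEFAULT_GRIDS: dict[str, dict] = {
    "KNN": {"n_neighbors": [3, 5, 7, 9, 11, 13, 15]},
    "RF": {"n_estimators": [100, 300], "max_depth": [None, 5, 10]},
    "SVM": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01, 0.1]},
    "LR": {"C": [0.01, 0.1, 1.0, 10.0]},
}


@dataclass
class SplitSpec:
    """One stratified 80/20 split, reproducible from its seed."""

    seed: int
    train_ids: list
    test_ids: list


def stratified_split(
    ids: pd.Index | list,
    labels: pd.Series,
    test_size: float = 0.2,
    seed: int = 0,
) -> SplitSpec:
    """Stratified train/test split preserving the class ratio."""
    ids = list(ids)
    y = pd.Series(labels).loc[ids]
    train, test = train_test_split(
        ids, test_size=test_size, stratify=y, random_state=seed
    )
    return SplitSpec(seed=seed, train_ids=list(train), test_ids=list(test))


@dataclass
class LogisticFit:
    """Unpenalized logistic MLE with Wald inference per descriptor."""

    names: list[str]
    beta0: float
    betas: np.ndarray
    ses: np.ndarray
    se0: float

    @property
    def z(self) -> np.ndarray:
        return self.betas / self.ses

    @property
    def p(self) -> np.ndarray:
        from scipy.stats import norm

        return 2.0 * norm.sf(np.abs(self.z))

    @property
    def or_(self) -> np.ndarray:
        return np.exp(self.betas)

    @property
    def ci95(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.exp(self.betas - Z_95 * self.ses),
            np.exp(self.betas + Z_95 * self.ses),
        )

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.beta0 + np.asarray(X, dtype=float) @ self.betas

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = self.linear_predictor(X)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic_mle(X, y, names: list[str] | None = None) -> LogisticFit:
    """Fit the unpenalized logistic model by maximum likelihood (IRLS).

    Standard errors come from the inverse Fisher information at the optimum.
    Complete separation (diverging coefficients) raises with a diagnostic.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if names is None else names
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    model = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-8)
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    fitted = np.asarray(res.fittedvalues)
    saturated = np.all(np.abs(y - fitted) < 1e-6)
    if not np.all(np.isfinite(bse)) or np.max(np.abs(params)) > 1e3 or saturated:
        raise RuntimeError(
            "logistic MLE diverged (likely complete separation): "
            f"max |beta| = {np.max(np.abs(params)):.3g}"
        )
    return LogisticFit(
        names=names,
        beta0=float(params[0]),
        betas=params[1:],
        ses=bse[1:],
        se0=float(bse[0]),
    )


def wald_report(fits: LogisticFit | list[LogisticFit]) -> pd.DataFrame:
    """Inference table: beta, SE, z, p, odds ratio and 95% CI per descriptor.

    Given several fits (one per repeated split), coefficients and Wald SEs
    are averaged across splits before the odds ratios and CIs are formed;
    the across-split SD of the coefficients is reported alongside.
    """
    if isinstance(fits, LogisticFit):
        fits = [fits]
    names = fits[0].names
    betas = np.mean([f.betas for f in fits], axis=0)
    beta_sd = np.std([f.betas for f in fits], axis=0, ddof=0)
    ses = np.mean([f.ses for f in fits], axis=0)
    z = betas / ses
    from scipy.stats import norm

    p = 2.0 * norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "beta": betas,
            "se": ses,
            "beta_sd_across_splits": beta_sd,
            "z": z,
            "p": p,
            "odds_ratio": np.exp(betas),
            "ci_low": np.exp(betas - Z_95 * ses),
            "ci_high": np.exp(betas + Z_95 * ses),
        },
        index=pd.Index(names, name="descriptor"),
    )


def roc_auc(scores, y) -> dict:
    """ROC curve and trapezoidal AUC for class-1 scores.

    The threshold sweep over unique scores makes the AUC equal to the
    Mann-Whitney U statistic divided by n1*n0, ties counted one half.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute ROC-AUC")
    fpr, tpr, thresholds = roc_curve(y, np.asarray(scores, dtype=float))
    return {"fpr": fpr, "tpr": tpr, "thresholds": thresholds, "auc": float(_auc(fpr, tpr))}


@dataclass
class ModelEvaluation:
    """Per-split and mean test metrics for one algorithm."""

    algorithm: str
    accuracies: list[float] = field(default_factory=list)
    aucs: list[float] = field(default_factory=list)
    best_params: list[dict] = field(default_factory=list)
    roc: dict | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=0))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "KNN":
        return KNeighborsClassifier()
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed)
    if algorithm == "SVM":
        return SVC(kernel="rbf", random_state=seed)
    if algorithm == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _class1_scores(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


def compare_models(
    table: pd.DataFrame,
    labels: pd.Series,
    algorithms: tuple[str, ...] = ("KNN", "RF", "SVM", "LR"),
    n_repeats: int = 5,
    cv_folds: int = 5,
    grids: dict[str, dict] | None = None,
    seeds: tuple[int, ...] | None = None,
    test_size: float = 0.2,
) -> dict[str, ModelEvaluation]:
    """Grid-search-tuned comparison over repeated stratified splits.

    Per repeat: stratified 80/20 split, scaler fit on the training portion,
    per-algorithm grid search by ``cv_folds``-fold CV accuracy, refit of the
    best configuration on the full training set, then accuracy and ROC-AUC
    on the held-out test set.  The ROC of the last split is retained for
    plotting.
    """
    grids = DEFAULT_GRIDS if grids is None else grids
    if seeds is None:
        seeds = tuple(range(n_repeats))
    if any(alg not in grids or not grids[alg] for alg in algorithms):
        raise ValueError("every algorithm needs a non-empty grid")
    y_all = pd.Series(labels).loc[table.index]
    if y_all.value_counts().min() < cv_folds:
        raise ValueError("need at least cv_folds samples per class")
    evals = {alg: ModelEvaluation(algorithm=alg) for alg in algorithms}
    for seed in seeds[:n_repeats]:
        split = stratified_split(table.index, y_all, test_size=test_size, seed=seed)
        scaler = StandardScaler().fit(table.loc[split.train_ids])
        x_train = scaler.transform(table.loc[split.train_ids])
        x_test = scaler.transform(table.loc[split.test_ids])
        y_train = y_all.loc[split.train_ids].values
        y_test = y_all.loc[split.test_ids].values
        for alg in algorithms:
            gs = GridSearchCV(
                _make_estimator(alg, seed),
                grids[alg],
                cv=cv_folds,
                scoring="accuracy",
                n_jobs=1,
            )
            gs.fit(x_train, y_train)
            best = gs.best_estimator_
            y_pred = best.predict(x_test)
            scores = _class1_scores(best, x_test)
            ev = evals[alg]
            ev.accuracies.append(float(accuracy_score(y_test, y_pred)))
            roc = roc_auc(scores, y_test)
            ev.aucs.append(roc["auc"])
            ev.best_params.append(dict(gs.best_params_))
            ev.roc = roc
    return evals
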