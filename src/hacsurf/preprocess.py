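"""Statistical preprocessing ahead of classification.

Three steps, mirroring the standard assumptions of an interpretable
logistic model:

1. Pearson screening: descriptors whose point-biserial correlation with the
   class label is not significant at ``alpha`` are dropped; then, within
   each descriptor category, highly collinear descriptors (|r| >= 0.8 by
   default) are eliminated greedily.
2. Influence-based outlier removal: Cook's distance from an unpenalized
   logistic fit; observations that are simultaneously highly influential
   (D > 4/n) and outlying (|standardized Pearson residual| > 2) are removed.
3. Standardization (z-scoring) with means/SDs fit on the training partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DESCRIPTOR_CATEGORIES",
    "CorrelationReport",
    "PreprocessResult",
    "ScalerParams",
    "pearson_screen",
    "cooks_outlier_removal",
    "standardize",
]

#: Descriptor -> category map used by the collinearity elimination.
DESCRIPTOR_CATEGORIES: dict[str, str] = {
    "s_phobic_avg": "hydrophobicity",
    "s_pos_area": "charge",
    "s_neg_area": "charge",
    "s_charge_avg": "charge",
    "s_ah": "structure",
    "s_bs": "structure",
    "s_do": "structure",
    "s_sf": "structure",
    "norm_s_b": "flexibility",
    "fd": "geometry",
}


@dataclass
class CorrelationReport:
    """Pairwise Pearson matrix, p-values, and descriptor-vs-label correlations."""

    r_matrix: pd.DataFrame
    p_matrix: pd.DataFrame
    target_r: pd.Series
    target_p: pd.Series


@dataclass
class PreprocessResult:
    kept: list[str] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)
    removed_ids: list[str] = field(default_factory=list)


@dataclass
class ScalerParams:
    means: pd.Series
    sds: pd.Series

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return (table[self.means.index] - self.means) / self.sds

    def inverse_transform(self, scaled: pd.DataFrame) -> pd.DataFrame:
        return scaled * self.sds + self.means


def _pairwise_pearson(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    cols = list(table.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rr, pp = stats.pearsonr(table[cols[i]], table[cols[j]])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def pearson_screen(
    table: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    collinearity_threshold: float = 0.8,
    categories: dict[str, str] | None = None,
) -> tuple[CorrelationReport, PreprocessResult]:
    """Significance screening plus category-aware collinearity elimination.

    The label correlation is the point-biserial r (Pearson against the 0/1
    label, t-test with n-2 df).  Within each category the descriptor with
    the largest mean absolute within-category correlation is dropped until
    no within-category pair reaches the threshold; ties break by descriptor
    name.  Constant columns are dropped with a warning.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 observations")
    cats = DESCRIPTOR_CATEGORIES if categories is None else categories
    result = PreprocessResult()
    work = table.copy()
    for col in list(work.columns):
        if work[col].std(ddof=0) == 0:
            warnings.warn(f"constant descriptor {col!r} dropped", stacklevel=2)
            result.dropped[col] = "constant"
            work = work.drop(columns=col)
    y = labels.loc[work.index].astype(float)
    target_r, target_p = {}, {}
    for col in work.columns:
        r, p = stats.pearsonr(work[col], y)
        target_r[col], target_p[col] = r, p
    target_r = pd.Series(target_r, name="r")
    target_p = pd.Series(target_p, name="p")
    r_mat, p_mat = _pairwise_pearson(work)
    report = CorrelationReport(r_mat, p_mat, target_r, target_p)

    kept = [c for c in work.columns]
    for col in list(kept):
        if target_p[col] >= alpha:
            result.dropped[col] = "nonsignificant_vs_target"
            kept.remove(col)

    # greedy within-category elimination
    changed = True
    while changed:
        changed = False
        for cat in sorted(set(cats.get(c, c) for c in kept)):
            members = [c for c in kept if cats.get(c, c) == cat]
            if len(members) < 2:
                continue
            sub = r_mat.loc[members, members].abs()
            off = sub.values[~np.eye(len(members), dtype=bool)]
            if (off >= collinearity_threshold).any():
                mean_abs = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
                worst = sorted(members, key=lambda c: (-mean_abs[c], c))[0]
                result.dropped[worst] = "collinear_in_category"
                kept.remove(worst)
                changed = True
    result.kept = kept
    return report, result


def _fit_unpenalized_logit(X: np.ndarray, y: np.ndarray) -> sm.GLM:
    model = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial())
    return model.fit()


def cooks_outlier_removal(
    table: pd.DataFrame,
    labels: pd.Series,
    cooks_threshold: float | None = None,
    resid_threshold: float = 2.0,
) -> PreprocessResult:
    """Remove observations that are both highly influential and outlying.

    Fits an unpenalized logistic regression on the (z-scored) table, takes
    Cook's distance and internally studentized Pearson residuals from the
    fit's influence measures, and removes rows exceeding both the Cook's
    threshold (default 4/n) and the residual threshold.  Runs once, no
    iterative re-removal.
    """
    n = len(table)
    if cooks_threshold is None:
        cooks_threshold = 4.0 / n
    X = ((table - table.mean()) / table.std(ddof=0)).values
    y = labels.loc[table.index].values.astype(float)
    try:
        res = _fit_unpenalized_logit(X, y)
    except Exception as exc:  # pragma: no cover - statsmodels raises various
        raise RuntimeError(
            "logistic fit failed; standardize features or check separation"
        ) from exc
    infl = res.get_influence(observed=False)
    cooks = infl.cooks_distance[0]
    resid = infl.resid_studentized
    flag = (cooks > cooks_threshold) & (np.abs(resid) > resid_threshold)
    out = PreprocessResult(kept=list(table.columns))
    out.removed_ids = list(table.index[flag])
    return out


def standardize(
    table: pd.DataFrame,
    fit_ids: list | pd.Index | None = None,
) -> tuple[pd.DataFrame, ScalerParams]:
    """Z-score descriptors with means/SDs estimated on ``fit_ids`` rows only.

    The returned scaler applies the training-set parameters to any partition
    (so a test set is scaled with training statistics).
    """
    fit_rows = table if fit_ids is None else table.loc[fit_ids]
    if len(fit_rows) == 0:
        raise ValueError("empty fit partition")
    means = fit_rows.mean()
    sds = fit_rows.std(ddof=0)
    zero = sds[sds == 0]
    if len(zero):
        raise ValueError(f"zero standard deviation for descriptor(s) {list(zero.index)}")
    params = ScalerParams(means=means, sds=sds)
    return params.transform(table), params
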