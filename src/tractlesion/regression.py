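"""Forward-selection linear regression and nested-model comparison.

Predictors of tremor suppression are found with a two-stage forward
selection. At each step every remaining candidate is added individually to
the current ordinary-least-squares model and the candidate whose
coefficient has the lowest t-test p-value is adopted if that p-value is
under ``alpha``; selection stops when no candidate qualifies. Stage one
searches patient-specific pre-treatment variables only; stage two adds
treatment-specific variables with the stage-one predictors locked in. The
extended model is compared to the baseline with the nested-model F test on
residual sums of squares:

    F = ((RSS_s - RSS_l) / d_extra) / (RSS_l / (n - p_l - 1))

Coefficients are reported both on the raw scale and standardized
(beta_hat * sd(x) / sd(y)); p-values are invariant to that rescaling.

Model fits go through statsmodels OLS; the selection procedure, the
nested-model comparison and the estimator wrapper are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ValidationError

__all__ = [
    "FittedModel",
    "ModelComparison",
    "PearsonResult",
    "standardize",
    "ols_fit",
    "forward_select",
    "two_stage_select",
    "anova_compare",
    "pearson",
    "ForwardSelectionOLS",
]


@dataclass
class FittedModel:
    """An OLS fit with both raw and standardized coefficients."""

    response: str
    predictors: list                 # in selection order
    beta_std: dict                   # standardized coefficients
    beta_raw: dict                   # raw-scale coefficients
    intercept: float
    pvalues: dict
    tvalues: dict
    r2: float
    rss: float
    n: int

    @property
    def n_params(self) -> int:
        return len(self.predictors)

    @property
    def df_resid(self) -> int:
        return self.n - self.n_params - 1


@dataclass
class ModelComparison:
    """Nested-model F comparison of residual sums of squares."""

    f: float
    p: float
    df: tuple                        # (extra params, residual df of large model)
    identical: bool = False


@dataclass
class PearsonResult:
    r: float
    p: float

    @property
    def r2(self) -> float:
        return self.r ** 2


def standardize(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Z-score the given columns (mean 0, SD 1, ddof=1); returns a copy."""
    out = table.copy()
    if columns is None:
        columns = [c for c in table.columns
                   if pd.api.types.is_numeric_dtype(table[c])]
    for c in columns:
        sd = out[c].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValidationError(f"column '{c}' has zero variance")
        out[c] = (out[c] - out[c].mean()) / sd
    return out


def _check_design(table: pd.DataFrame, response: str, predictors) -> None:
    cols = [response, *predictors]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValidationError(f"columns not in table: {missing}")
    if table[cols].isna().any().any():
        bad = table[cols].columns[table[cols].isna().any()].tolist()
        raise ValidationError(f"missing values in columns: {bad}")
    if predictors:
        X = table[list(predictors)].to_numpy(dtype=np.float64)
        Xc = np.column_stack([np.ones(len(X)), X])
        rank = np.linalg.matrix_rank(Xc)
        if rank < Xc.shape[1]:
            collinear = []
            for j, name in enumerate(predictors):
                reduced = np.delete(Xc, j + 1, axis=1)
                if np.linalg.matrix_rank(reduced) == rank:
                    collinear.append(name)
            raise ValidationError(f"rank-deficient design; collinear columns: "
                                  f"{collinear or list(predictors)}")


def ols_fit(table: pd.DataFrame, response: str, predictors) -> FittedModel:
    """Ordinary least squares of ``response`` on ``predictors`` with intercept.

    Returns raw coefficients, standardized coefficients, two-sided t-test
    p-values, R^2 and the residual sum of squares. An empty predictor list
    yields the intercept-only model.
    """
    predictors = list(predictors)
    _check_design(table, response, predictors)
    y = table[response].to_numpy(dtype=np.float64)
    n = len(y)
    if n < len(predictors) + 2:
        raise ValidationError(
            f"n = {n} rows cannot support {len(predictors)} predictors"
        )
    if predictors:
        X = sm.add_constant(table[predictors].to_numpy(dtype=np.float64))
    else:
        X = np.ones((n, 1))
    res = sm.OLS(y, X).fit()
    sd_y = y.std(ddof=1)
    beta_raw, beta_std, pvalues, tvalues = {}, {}, {}, {}
    for j, name in enumerate(predictors):
        coef = res.params[j + 1]
        sd_x = table[name].std(ddof=1)
        beta_raw[name] = float(coef)
        beta_std[name] = float(coef * sd_x / sd_y) if sd_y > 0 else np.nan
        pvalues[name] = float(res.pvalues[j + 1])
        tvalues[name] = float(res.tvalues[j + 1])
    return FittedModel(
        response=response, predictors=predictors,
        beta_std=beta_std, beta_raw=beta_raw,
        intercept=float(res.params[0]),
        pvalues=pvalues, tvalues=tvalues,
        r2=float(res.rsquared) if predictors else 0.0,
        rss=float(res.ssr), n=n,
    )


def forward_select(table: pd.DataFrame, response: str, candidate_pool,
                   alpha: float = 0.05, locked=()) -> FittedModel:
    """Forward selection by lowest coefficient p-value under ``alpha``.

    Starting from the ``locked`` predictors (always kept), each remaining
    candidate is added individually; the candidate with the lowest p-value
    below ``alpha`` joins the model, iterating until none qualifies. Ties
    on p-value break by larger |t|, then by pool order. An empty selection
    (the locked-only or intercept-only model) is a valid outcome.
    """
    pool = list(candidate_pool)
    if not pool:
        raise ValidationError("candidate pool is empty")
    selected = list(locked)
    remaining = [c for c in pool if c not in selected]
    while remaining:
        best = None  # (p, -|t|, pool position, name)
        for pos, cand in enumerate(remaining):
            fit = ols_fit(table, response, selected + [cand])
            p, t = fit.pvalues[cand], fit.tvalues[cand]
            key = (p, -abs(t), pos)
            if p < alpha and (best is None or key < best[0]):
                best = (key, cand)
        if best is None:
            break
        selected.append(best[1])
        remaining.remove(best[1])
    return ols_fit(table, response, selected)


def anova_compare(small: FittedModel, large: FittedModel) -> ModelComparison:
    """F test comparing the residual sums of squares of nested OLS models."""
    if small.n != large.n:
        raise ValidationError("models fit on different n")
    if set(small.predictors) == set(large.predictors):
        raise ValidationError("identical predictor sets; nothing to compare")
    if not set(small.predictors) <= set(large.predictors):
        raise ValidationError("small model is not nested in the large model")
    d_extra = large.n_params - small.n_params
    df_resid = large.df_resid
    if df_resid <= 0:
        raise ValidationError("large model has no residual degrees of freedom")
    f = ((small.rss - large.rss) / d_extra) / (large.rss / df_resid)
    f = max(f, 0.0)
    p = float(scipy.stats.f.sf(f, d_extra, df_resid))
    return ModelComparison(f=float(f), p=p, df=(d_extra, df_resid))


def two_stage_select(table: pd.DataFrame, response: str, patient_pool,
                     treatment_pool, alpha: float = 0.05):
    """Two-stage forward selection with a nested-model comparison.

    Stage 1 selects from patient-specific pre-treatment variables only;
    stage 2 selects from treatment-specific variables with the stage-1
    predictors locked in. Returns ``(baseline, extended, comparison)``;
    when stage 2 adds nothing the comparison is flagged ``identical``.
    """
    patient_pool, treatment_pool = list(patient_pool), list(treatment_pool)
    overlap_cols = set(patient_pool) & set(treatment_pool)
    if overlap_cols:
        raise ValidationError(f"pools overlap: {sorted(overlap_cols)}")
    baseline = forward_select(table, response, patient_pool, alpha=alpha)
    if treatment_pool:
        extended = forward_select(table, response, treatment_pool, alpha=alpha,
                                  locked=baseline.predictors)
    else:
        extended = baseline
    if set(extended.predictors) == set(baseline.predictors):
        comparison = ModelComparison(f=np.nan, p=np.nan, df=(0, extended.df_resid),
                                     identical=True)
    else:
        comparison = anova_compare(baseline, extended)
    return baseline, extended, comparison


def pearson(x, y) -> PearsonResult:
    """Pearson correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValidationError("need n >= 3")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValidationError("zero-variance input")
    r, p = scipy.stats.pearsonr(x, y)
    return PearsonResult(r=float(r), p=float(p))


class ForwardSelectionOLS(RegressorMixin, BaseEstimator):
    """Forward-selection OLS as a scikit-learn style estimator.

    Parameters
    ----------
    alpha : float
        Entry threshold on the candidate coefficient p-value.
    locked : sequence of str
        Column names always kept in the model (e.g. a previous stage's
        selection).

    Attributes
    ----------
    selected_ : list of str
        Predictors in selection order (including locked ones first).
    model_ : FittedModel
    coef_ : (n_selected,) array of raw-scale coefficients
    intercept_ : float
    """

    def __init__(self, alpha: float = 0.05, locked=()):
        self.alpha = alpha
        self.locked = locked

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            raise ValidationError("X must be a DataFrame (named candidates)")
        table = X.copy()
        response = "__response__"
        table[response] = np.asarray(y, dtype=np.float64)
        self.model_ = forward_select(table, response, list(X.columns),
                                     alpha=self.alpha, locked=list(self.locked))
        self.model_.response = "y"
        self.selected_ = list(self.model_.predictors)
        self.coef_ = np.array([self.model_.beta_raw[c] for c in self.selected_])
        self.intercept_ = self.model_.intercept
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X: pd.DataFrame):
        if not hasattr(self, "model_"):
            raise ValidationError("estimator is not fitted")
        Xs = X[self.selected_].to_numpy(dtype=np.float64) if self.selected_ \
            else np.empty((len(X), 0))
        return self.intercept_ + Xs @ self.coef_
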