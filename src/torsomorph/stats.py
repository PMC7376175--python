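"""Anthropometric indices, correlations and regression model families.

Implements the statistical side of the shape-anthropometry comparison:

* derived weight-status indices — BMI = mass/stature^2 (kg m^-2),
  WHR = waist/hip, WHT.5R = waist/sqrt(stature) with waist and stature in
  metres — and the sum of the three waist-region skinfolds (mm);
* z-scoring to a common standard-deviation scale;
* pairwise-complete Pearson correlation matrices with two-sided p-values;
* ordinary least squares with the diagnostics reported for each model:
  R^2, standardized coefficients, F with its degrees of freedom,
  per-predictor t/p, tolerance and VIF, and the Durbin-Watson statistic;
* forward-with-backward stepwise selection over candidate predictors;
* the three model families comparing size-, shape- and combined
  predictors of the sum of skinfolds.

OLS fitting, VIF and Durbin-Watson go through statsmodels; this module
adds the contracts, the family orchestration and the selection logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import durbin_watson

from .errors import (
    ConfigurationError,
    DegenerateCohortError,
    SingularDesignError,
    ValidationError,
)

P_ENTER_DEFAULT = 0.05
P_REMOVE_DEFAULT = 0.10

SIZE_COLUMNS = ("stature_m", "mass_kg", "waist_girth_m", "hip_girth_m")
INDEX_COLUMNS = ("bmi", "whr", "wht5r", "waist_girth_m")


# ---------------------------------------------------------------------------
# indices


def derive_indices(table: pd.DataFrame) -> pd.DataFrame:
    """Append BMI, WHR, WHT.5R and sum-of-skinfolds columns.

    Expects canonical units (stature/girths in m, mass in kg, skinfolds in
    mm). A missing skinfold makes the participant's sum missing.
    """
    for col in ("stature_m", "mass_kg", "waist_girth_m", "hip_girth_m"):
        if (table[col] <= 0).any():
            raise ValidationError(f"non-positive values in {col!r}")
    out = table.copy()
    out["bmi"] = out["mass_kg"] / out["stature_m"] ** 2
    out["whr"] = out["waist_girth_m"] / out["hip_girth_m"]
    out["wht5r"] = out["waist_girth_m"] / np.sqrt(out["stature_m"])
    out["sum_skinfolds_mm"] = (
        out["skinfold_iliac_crest_mm"]
        + out["skinfold_supraspinale_mm"]
        + out["skinfold_abdominal_mm"]
    )
    return out


def zscore_table(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Z-score the given (default: all numeric) columns, sample SD (ddof=1).

    Missing values stay missing; means/SDs are stored in ``df.attrs``
    under "mean" and "sd" so the transform is invertible.
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    out = table.copy()
    means, sds = {}, {}
    for col in columns:
        vals = table[col]
        if vals.dropna().nunique() < 2:
            raise DegenerateCohortError(f"column {col!r} has no variance to standardize")
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1))
        out[col] = (vals - mu) / sd
        means[col], sds[col] = mu, sd
    out.attrs["mean"] = means
    out.attrs["sd"] = sds
    return out


# ---------------------------------------------------------------------------
# correlations


@dataclass
class CorrelationTable:
    """Symmetric Pearson-r matrix with two-sided p-values and n per cell."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.p < alpha


def pearson_matrix(table: pd.DataFrame, columns: list[str] | None = None,
                   min_pairs: int = 3) -> CorrelationTable:
    """Pairwise-complete Pearson correlations; cells with fewer than
    ``min_pairs`` complete pairs are left missing."""
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    k = len(columns)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            xi = table[columns[i]]
            xj = table[columns[j]]
            mask = xi.notna() & xj.notna()
            n[i, j] = n[j, i] = int(mask.sum())
            if i == j:
                r[i, i], p[i, i] = 1.0, 0.0
                continue
            if n[i, j] < min_pairs:
                continue
            res = sps.pearsonr(xi[mask], xj[mask])
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    idx = pd.Index(columns)
    return CorrelationTable(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )


# ---------------------------------------------------------------------------
# regression


@dataclass
class RegressionResult:
    """One fitted OLS model with the diagnostics reported per model."""

    response: str
    predictors: list[str]
    r_squared: float
    coefficients: dict[str, float]        # raw (input-unit) slopes
    standardized_betas: dict[str, float]  # slopes in SD units of the model sample
    intercept: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    t_values: dict[str, float]
    p_values: dict[str, float]
    tolerance: dict[str, float]
    vif: dict[str, float]
    durbin_watson: float
    n_used: int
    selection_trace: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictors": self.predictors,
            "r_squared": self.r_squared,
            "coefficients": self.coefficients,
            "standardized_betas": self.standardized_betas,
            "intercept": self.intercept,
            "f_statistic": self.f_statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "t": self.t_values,
            "p": self.p_values,
            "tolerance": self.tolerance,
            "vif": self.vif,
            "durbin_watson": self.durbin_watson,
            "n_used": self.n_used,
            "selection_trace": self.selection_trace,
        }


def r_squared_from_beta(beta: float) -> float:
    """Single-predictor identity: R^2 equals the squared standardized slope."""
    return float(beta) ** 2


def f_from_r_squared(r_squared: float, df_reg: int, df_res: int) -> float:
    """F statistic implied by R^2 and its degrees of freedom."""
    return (r_squared / df_reg) / ((1.0 - r_squared) / df_res)


def fit_regression(data: pd.DataFrame, response: str,
                   predictors: list[str]) -> RegressionResult:
    """OLS of ``response`` on ``predictors`` with full diagnostics.

    Rows with any missing value among the involved columns are dropped
    (listwise deletion); ``n_used`` reports the surviving count.
    Standardized betas are computed from the SDs of the complete-case
    sample actually fitted, so the single-predictor identity
    R^2 = beta^2 holds per model even when listwise deletion shrinks a
    pre-standardized table. The Durbin-Watson statistic is computed over
    residuals in input row order and is therefore order-dependent on
    cross-sectional data.
    """
    cols = [response] + list(predictors)
    frame = data[cols].dropna()
    n = len(frame)
    if n <= len(predictors) + 1:
        raise ValidationError(
            f"{n} complete cases cannot support {len(predictors)} predictors"
        )
    y = frame[response].to_numpy(dtype=float)
    X = frame[list(predictors)].to_numpy(dtype=float)
    exog = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise SingularDesignError(
            f"exact collinearity among predictors of {response!r}: {list(predictors)}"
        )
    fit = sm.OLS(y, exog).fit()

    tol: dict[str, float] = {}
    vif: dict[str, float] = {}
    for j, name in enumerate(predictors):
        if len(predictors) == 1:
            vif_j = 1.0
        else:
            # intercept included so R^2_j is the centred (definitional) one
            vif_j = float(variance_inflation_factor(exog, j + 1))
        vif[name] = vif_j
        tol[name] = 1.0 / vif_j

    df_reg = int(fit.df_model)
    df_res = int(fit.df_resid)
    sd_y = float(np.std(y, ddof=1))
    sd_x = X.std(axis=0, ddof=1)
    return RegressionResult(
        response=response,
        predictors=list(predictors),
        r_squared=float(fit.rsquared),
        coefficients={name: float(fit.params[j + 1])
                      for j, name in enumerate(predictors)},
        standardized_betas={name: float(fit.params[j + 1] * sd_x[j] / sd_y)
                            for j, name in enumerate(predictors)},
        intercept=float(fit.params[0]),
        f_statistic=float(fit.fvalue),
        df=(df_reg, df_res),
        p_value=float(fit.f_pvalue),
        t_values={name: float(fit.tvalues[j + 1]) for j, name in enumerate(predictors)},
        p_values={name: float(fit.pvalues[j + 1]) for j, name in enumerate(predictors)},
        tolerance=tol,
        vif=vif,
        durbin_watson=float(durbin_watson(fit.resid)),
        n_used=n,
    )


def stepwise_select(
    data: pd.DataFrame,
    response: str,
    candidates: list[str],
    p_enter: float = P_ENTER_DEFAULT,
    p_remove: float = P_REMOVE_DEFAULT,
    entry_correction: str = "bonferroni",
) -> RegressionResult:
    """Forward-with-backward stepwise selection.

    At each forward step the candidate with the smallest partial-F
    p-value enters if it clears the entry criterion; any included
    predictor whose p-value exceeds ``p_remove`` is then dropped. The
    entry criterion controls the family of remaining candidates:
    ``entry_correction="bonferroni"`` (default) requires
    ``p < p_enter / n_remaining`` so a pool of pure-noise candidates is
    admitted at family rate ~``p_enter``; ``"none"`` uses the classic
    per-candidate rule of legacy statistics packages.

    Returns the fitted model on the selected set with a step-by-step
    ``selection_trace``. An empty selection returns an intercept-only
    result (R^2 = 0, no predictors).
    """
    if not candidates:
        raise ValidationError("empty candidate pool")
    if p_enter >= p_remove:
        raise ConfigurationError("p_enter must be < p_remove to prevent cycling")
    if entry_correction not in {"bonferroni", "none"}:
        raise ConfigurationError(f"unknown entry_correction {entry_correction!r}")

    frame = data[[response] + list(candidates)].dropna()
    selected: list[str] = []
    trace: list[dict] = []
    while True:
        changed = False
        remaining = [c for c in candidates if c not in selected]
        if remaining:
            pvals = {}
            for cand in remaining:
                trial = fit_regression(frame, response, selected + [cand])
                pvals[cand] = trial.p_values[cand]
            best = min(pvals, key=pvals.get)  # type: ignore[arg-type]
            cutoff = p_enter / len(remaining) if entry_correction == "bonferroni" else p_enter
            if pvals[best] < cutoff:
                selected.append(best)
                trace.append({"step": len(trace) + 1, "action": "enter",
                              "variable": best, "p": float(pvals[best])})
                changed = True
        if selected:
            current = fit_regression(frame, response, selected)
            worst = max(selected, key=lambda v: current.p_values[v])
            if current.p_values[worst] > p_remove:
                selected.remove(worst)
                trace.append({"step": len(trace) + 1, "action": "remove",
                              "variable": worst, "p": float(current.p_values[worst])})
                changed = True
        if not changed:
            break

    if not selected:
        y = frame[response].to_numpy(dtype=float)
        return RegressionResult(
            response=response, predictors=[], r_squared=0.0,
            coefficients={}, standardized_betas={}, intercept=float(np.mean(y)),
            f_statistic=np.nan, df=(0, len(frame) - 1), p_value=np.nan,
            t_values={}, p_values={}, tolerance={}, vif={},
            durbin_watson=float(durbin_watson(y - np.mean(y))),
            n_used=len(frame), selection_trace=trace,
        )
    result = fit_regression(frame, response, selected)
    result.selection_trace = trace
    return result


# ---------------------------------------------------------------------------
# model families


def run_model_families(
    ztable: pd.DataFrame,
    response: str = "sum_skinfolds_mm",
    n_shape_candidates: int = 11,
    p_enter: float = P_ENTER_DEFAULT,
    p_remove: float = P_REMOVE_DEFAULT,
    entry_correction: str = "bonferroni",
) -> dict[str, RegressionResult]:
    """Fit the three families predicting the skinfold sum (10 models).

    1. *Size models*: each index (BMI, WHR, waist girth, WHT.5R) alone,
       plus stature+mass+waist+hip jointly.
    2. *Shape-only*: stepwise over the first ``n_shape_candidates``
       shape principal components.
    3. *Combined*: each index together with the stepwise-selected PCs.

    ``ztable`` must hold z-scored columns for the sizes, indices,
    response, and PC1..PCn shape scores.
    """
    pc_cols = [f"PC{i + 1}" for i in range(n_shape_candidates)]
    missing = [c for c in pc_cols + list(SIZE_COLUMNS) + ["bmi", "whr", "wht5r", response]
               if c not in ztable.columns]
    if missing:
        raise ValidationError(f"z-scored table missing columns: {missing}")

    models: dict[str, RegressionResult] = {}
    index_predictors = {
        "bmi": ["bmi"],
        "whr": ["whr"],
        "waist": ["waist_girth_m"],
        "wht5r": ["wht5r"],
    }
    for name, preds in index_predictors.items():
        models[f"size_{name}"] = fit_regression(ztable, response, preds)
    models["size_all"] = fit_regression(ztable, response, list(SIZE_COLUMNS))

    shape = stepwise_select(ztable, response, pc_cols, p_enter=p_enter,
                            p_remove=p_remove, entry_correction=entry_correction)
    models["shape_stepwise"] = shape

    for name, preds in index_predictors.items():
        combined = preds + [p for p in shape.predictors if p not in preds]
        if combined == preds:
            models[f"combined_{name}"] = models[f"size_{name}"]
        else:
            models[f"combined_{name}"] = fit_regression(ztable, response, combined)
    return models
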