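"""The spatial-precision -> burst-pressure analysis chain.

Four stages, in the order they run:

1. **Spearman screen** — each spacing metric is rank-correlated with burst
   pressure; metrics with two-sided p below alpha are selected.  For every
   metric a retrospective correlation power analysis is attached, via the
   Fisher-z approximation with the observed rho as the population value.
   For Spearman's rho the Fisher-z standard error is inflated to
   ``sqrt((1 + rho^2/2) / (n - 3))`` (Bonett-Wright); the plain Pearson-style
   ``sqrt(1/(n - 3))`` variant is also reported and labelled, since either
   convention is defensible.  No multiplicity correction is applied by
   default (the screen is reported as run, at raw p < alpha across all
   metrics); Holm or Benjamini-Hochberg selection is available by flag.
2. **Collinearity diagnosis** — variance inflation factors
   ``VIF_j = 1 / (1 - R^2_j)`` from regressing each feature on all others
   with an intercept; VIF > 10 marks severe multicollinearity.
3. **Repeated K-fold gradient-boosted regression** — an XGBoost regressor
   evaluated under repeated K-fold cross-validation (default k = 5 splits,
   10 repeats, i.e. train on 80% / validate on 20%, 50 folds total), scored
   per fold by MSE, R^2 and MAE.  Per-fold R^2 on small validation folds is
   a harsh, high-variance score (it can be negative whenever the model is
   worse than the fold mean); both the per-fold average and the pooled-
   prediction R^2 are reported.
4. **Residual + SHAP analysis** — per-sample residuals with a
   shrinkage-to-the-mean flag at the distribution extremes, and exact
   TreeSHAP attributions (computed natively by xgboost) whose per-sample sum
   plus the base value reproduces each prediction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xgboost as xgb
from scipy import stats
from sklearn.model_selection import RepeatedKFold

from .errors import ConfigError, InputError
from .util import derive_seed

__all__ = [
    "spearman_screen",
    "correlation_power",
    "required_n_for_correlation",
    "vif_table",
    "RegressionReport",
    "DEFAULT_HYPERPARAMS",
    "repeated_kfold_regression",
    "residual_analysis",
    "shap_attribution",
]

DEFAULT_ALPHA = 0.05

#: Gradient-boosting defaults, echoed verbatim into every report.
DEFAULT_HYPERPARAMS = {
    "n_estimators": 100,
    "learning_rate": 0.1,
    "max_depth": 3,
    "subsample": 1.0,
}


# ---------------------------------------------------------------------------
# Correlation screen with retrospective power
# ---------------------------------------------------------------------------

def _fisher_se_factor(rho: float, variance: str) -> float:
    if variance == "bonett-wright":
        return 1.0 + rho * rho / 2.0
    if variance == "plain":
        return 1.0
    raise ConfigError(f"unknown variance convention {variance!r}")


def correlation_power(rho: float, n: int, alpha: float = DEFAULT_ALPHA,
                      variance: str = "bonett-wright") -> float:
    """Two-sided power to detect the given rho at sample size n (Fisher z)."""
    if n <= 3 or rho == 0.0:
        return alpha if rho == 0.0 else 0.0
    if abs(rho) >= 1.0:
        return 1.0
    zr = abs(math.atanh(rho))
    se = math.sqrt(_fisher_se_factor(rho, variance) / (n - 3))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(zr / se - zcrit) + stats.norm.cdf(-zr / se - zcrit))


def required_n_for_correlation(rho: float, target_power: float = 0.8,
                               alpha: float = DEFAULT_ALPHA,
                               variance: str = "bonett-wright") -> int | None:
    """Smallest n with Fisher-z power >= target for the given rho; None if rho = 0."""
    if rho == 0.0 or not math.isfinite(rho):
        return None
    if abs(rho) >= 1.0:
        return 4  # a perfect monotone association is detectable at the minimum n
    zr = abs(math.atanh(rho))
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(target_power)
    n = 3.0 + _fisher_se_factor(rho, variance) * ((za + zb) / zr) ** 2
    return max(4, math.ceil(n))


def spearman_screen(
    metric_table: pd.DataFrame,
    pressures,
    alpha: float = DEFAULT_ALPHA,
    *,
    target_power: float = 0.8,
    correction: str = "none",
) -> pd.DataFrame:
    """Rank-correlate every metric column with burst pressure and select.

    Returns one row per metric: ``rho``, ``p_value``, achieved ``power`` and
    ``required_n_80`` under both Fisher-z variance conventions, and
    ``selected`` (p < alpha after the chosen ``correction``; default none).
    Constant columns have no defined rank correlation and are excluded with
    a note rather than silently reported as zero.
    """
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha must be in (0,1), got {alpha}")
    if correction not in ("none", "holm", "bh"):
        raise ConfigError(f"unknown correction {correction!r}; use none, holm or bh")
    y = np.asarray(pressures, dtype=float)
    if len(y) != len(metric_table):
        raise InputError("metric table and pressures differ in length")
    if len(y) < 4:
        raise InputError("need at least 4 paired observations")

    rows = []
    for name in metric_table.columns:
        x = metric_table[name].to_numpy(dtype=float)
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            rows.append({"metric": name, "rho": np.nan, "p_value": np.nan,
                         "power": np.nan, "power_plain": np.nan,
                         "required_n_80": np.nan, "selected": False,
                         "note": "constant column; rho undefined"})
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({
            "metric": name,
            "rho": float(rho),
            "p_value": float(p),
            "power": correlation_power(rho, len(y), alpha, "bonett-wright"),
            "power_plain": correlation_power(rho, len(y), alpha, "plain"),
            "required_n_80": required_n_for_correlation(rho, target_power, alpha),
            "selected": False,
            "note": "",
        })
    out = pd.DataFrame(rows)
    defined = out["p_value"].notna()
    pvals = out.loc[defined, "p_value"].to_numpy()
    if correction == "none":
        sel = pvals < alpha
    else:
        from statsmodels.stats.multitest import multipletests
        sel = multipletests(pvals, alpha=alpha,
                            method={"holm": "holm", "bh": "fdr_bh"}[correction])[0]
    out.loc[defined, "selected"] = sel
    out.attrs["alpha"] = alpha
    out.attrs["correction"] = correction
    return out


# ---------------------------------------------------------------------------
# Collinearity
# ---------------------------------------------------------------------------

def vif_table(feature_matrix: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factor per feature: 1 / (1 - R^2_j), intercept included.

    Perfect collinearity is reported as ``inf``, not an error.  Requires more
    rows than features for the auxiliary regressions to be determined.
    """
    X = pd.DataFrame(feature_matrix)
    n, p = X.shape
    if p < 2:
        raise InputError("VIF needs at least 2 features")
    if n <= p:
        raise InputError(
            f"{n} rows for {p} features: auxiliary regressions are rank-deficient; "
            "reduce the feature set"
        )
    vals = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise InputError("feature matrix contains non-finite values")
    out = []
    for j, name in enumerate(X.columns):
        yj = vals[:, j]
        others = sm.add_constant(np.delete(vals, j, axis=1))
        r2 = sm.OLS(yj, others).fit().rsquared
        vif = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        out.append({"feature": name, "vif": vif})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Repeated K-fold gradient boosting
# ---------------------------------------------------------------------------

@dataclass
class RegressionReport:
    """Per-fold and aggregate cross-validation results plus provenance."""

    fold_metrics: pd.DataFrame  # repeat, fold, n_val, mse, r2, mae
    aggregates: dict
    residuals: pd.DataFrame  # sample, actual, predicted, residual
    fold_assignments: np.ndarray  # (repeats, n) validation-fold index per sample
    config: dict
    model: xgb.XGBRegressor  # refit on all data (for attribution)
    feature_names: list[str]

    def as_dict(self) -> dict:
        return {
            "config": self.config,
            "aggregates": self.aggregates,
            "fold_metrics": self.fold_metrics.to_dict(orient="records"),
            "feature_names": self.feature_names,
        }


def _make_model(hyperparams: dict, seed: int) -> xgb.XGBRegressor:
    return xgb.XGBRegressor(
        objective="reg:squarederror",
        n_jobs=1,
        random_state=seed,
        **hyperparams,
    )


def repeated_kfold_regression(
    features: pd.DataFrame,
    target,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> RegressionReport:
    """Repeated K-fold CV of a gradient-boosted regressor, fully seeded.

    Every repeat reshuffles the samples into ``k`` folds; each fold serves
    once as the validation set for a model trained on the remaining k-1
    folds, so every sample is validated exactly ``repeats`` times.  Fold
    membership, model fits and hence every reported number are functions of
    ``seed`` alone (the shuffle and model seeds are derived from it by a
    fixed labelled rule and echoed in the config).
    """
    X = pd.DataFrame(features)
    y = np.asarray(target, dtype=float)
    n = len(y)
    if len(X) != n:
        raise InputError("features and target differ in length")
    if not np.all(np.isfinite(y)):
        raise InputError("target contains non-finite values")
    if not np.all(np.isfinite(X.to_numpy(dtype=float))):
        raise InputError("features contain non-finite values")
    if k < 2 or repeats < 1:
        raise InputError(f"need k >= 2 and repeats >= 1, got k={k}, repeats={repeats}")
    if n < 2 * k:
        raise InputError(f"n={n} too small for k={k} folds (need n >= 2k)")

    hp = dict(DEFAULT_HYPERPARAMS, **(hyperparams or {}))
    seed_shuffle = derive_seed(seed, "cv-shuffle")
    seed_model = derive_seed(seed, "model")

    cv = RepeatedKFold(n_splits=k, n_repeats=repeats, random_state=seed_shuffle)
    fold_rows = []
    assignments = np.full((repeats, n), -1, dtype=int)
    pred_sum = np.zeros(n)
    for split_idx, (train_idx, val_idx) in enumerate(cv.split(X)):
        repeat, fold = divmod(split_idx, k)
        model = _make_model(hp, seed_model)
        model.fit(X.iloc[train_idx], y[train_idx])
        pred = model.predict(X.iloc[val_idx]).astype(float)
        resid = y[val_idx] - pred
        mse = float(np.mean(resid**2))
        mae = float(np.mean(np.abs(resid)))
        ss_tot = float(np.sum((y[val_idx] - y[val_idx].mean()) ** 2))
        r2 = float("nan") if ss_tot == 0.0 else 1.0 - float(np.sum(resid**2)) / ss_tot
        fold_rows.append({"repeat": repeat, "fold": fold, "n_val": len(val_idx),
                          "mse": mse, "r2": r2, "mae": mae})
        assignments[repeat, val_idx] = fold
        pred_sum[val_idx] += pred

    fold_metrics = pd.DataFrame(fold_rows)
    mean_pred = pred_sum / repeats
    residuals = pd.DataFrame({
        "sample": np.arange(n),
        "actual": y,
        "predicted": mean_pred,
        "residual": y - mean_pred,
    })
    r2_vals = fold_metrics["r2"].dropna()
    pooled_ss_tot = float(np.sum((y - y.mean()) ** 2))
    pooled_r2 = (float("nan") if pooled_ss_tot == 0.0
                 else 1.0 - float(np.sum((y - mean_pred) ** 2)) / pooled_ss_tot)
    aggregates = {
        "mean_mse": float(fold_metrics["mse"].mean()),
        "mean_r2": float(r2_vals.mean()) if len(r2_vals) else float("nan"),
        "mean_mae": float(fold_metrics["mae"].mean()),
        "frac_folds_r2_above_0.1": float((r2_vals > 0.1).mean()) if len(r2_vals) else float("nan"),
        "n_folds": len(fold_metrics),
        "mse_range": [float(fold_metrics["mse"].min()), float(fold_metrics["mse"].max())],
        "pooled_r2": pooled_r2,
    }
    final_model = _make_model(hp, seed_model)
    final_model.fit(X, y)
    config = {"k": k, "repeats": repeats, "seed": seed,
              "seed_shuffle": seed_shuffle, "seed_model": seed_model,
              "hyperparams": hp, "n_samples": n}
    return RegressionReport(
        fold_metrics=fold_metrics,
        aggregates=aggregates,
        residuals=residuals,
        fold_assignments=assignments,
        config=config,
        model=final_model,
        feature_names=list(X.columns),
    )


def residual_analysis(report: RegressionReport) -> dict:
    """Residual behaviour at the target's extremes.

    With ``residual = actual - predicted``, a model shrinking towards the
    mean overpredicts the lowest actuals (negative residual) and
    underpredicts the highest (positive residual); that sign pattern raises
    the ``shrinkage_to_mean`` flag.
    """
    res = report.residuals
    if res.empty:
        raise InputError("report carries no residuals")
    i_min = int(res["actual"].idxmin())
    i_max = int(res["actual"].idxmax())
    r_min = float(res.loc[i_min, "residual"])
    r_max = float(res.loc[i_max, "residual"])
    tol = 1e-12 * max(1.0, float(res["actual"].abs().max()))
    return {
        "min_actual": float(res.loc[i_min, "actual"]),
        "residual_at_min": r_min,
        "max_actual": float(res.loc[i_max, "actual"]),
        "residual_at_max": r_max,
        "shrinkage_to_mean": bool(r_min < -tol and r_max > tol),
    }


# ---------------------------------------------------------------------------
# SHAP attribution (exact TreeSHAP, computed natively by xgboost)
# ---------------------------------------------------------------------------

def shap_attribution(model: xgb.XGBRegressor, features: pd.DataFrame) -> dict:
    """Exact per-sample Shapley attributions for a fitted tree ensemble.

    Local accuracy holds by construction: for every sample the base value
    plus the per-feature attributions equals the model prediction.  Returns
    the per-sample attribution matrix, the base value, and features ranked
    by mean absolute attribution.
    """
    X = pd.DataFrame(features)
    booster = model.get_booster()
    expected = booster.feature_names
    if expected is not None and list(X.columns) != list(expected):
        raise InputError(
            f"feature schema mismatch: model expects {list(expected)}, got {list(X.columns)}"
        )
    contribs = booster.predict(xgb.DMatrix(X), pred_contribs=True)
    base_value = float(contribs[0, -1])
    attributions = pd.DataFrame(contribs[:, :-1], columns=X.columns, index=X.index)
    mean_abs = attributions.abs().mean(axis=0).sort_values(ascending=False)
    return {
        "attributions": attributions,
        "base_value": base_value,
        "mean_abs": mean_abs,
        "predictions": attributions.sum(axis=1).to_numpy() + contribs[:, -1],
    }
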