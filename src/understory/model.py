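"""Correlation screening, linear models, LOOCV and field validation.

Plot-level PDI responses (lower understory LU, 2-5 m; upper understory UU,
5-10 m) are modeled from ALS metrics.  Candidate predictors are screened by
Pearson correlation (|r| > 0.7 and significant), models are ordinary least
squares with intercept, and predictive skill is summarized by leave-one-out
cross-validation: RMSE over held-out predictions and its normalization by the
observed response range,

    nRMSE = RMSE / (y_max - y_min).

LOOCV for OLS uses the exact hat-matrix identity (held-out residual =
residual / (1 - leverage)); tests verify it against n explicit refits.

TLS-derived PDI is validated against conventional field data through Spearman
rank correlation with per-plot counts of small trees (DBH < 9 cm, paired with
LU) and intermediate trees (9-20 cm, paired with UU).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class FittedModel:
    """OLS fit plus LOOCV diagnostics for one understory response."""

    response_name: str
    predictor_names: list[str]
    coefficients: pd.Series        # index: const + predictors
    standard_errors: pd.Series
    t_values: pd.Series
    p_values: pd.Series
    adjusted_r2: float
    r2: float
    n_obs: int
    loocv_predictions: pd.Series | None = None
    rmse: float | None = None
    nrmse: float | None = None
    y_min: float | None = None
    y_max: float | None = None
    residuals: pd.Series | None = field(default=None, repr=False)

    def predict(self, metrics: pd.DataFrame) -> pd.Series:
        """Linear prediction for rows of a metric table."""
        missing = [p for p in self.predictor_names if p not in metrics.columns]
        if missing:
            raise KeyError(f"metric table lacks predictor column(s): {missing}")
        X = metrics[self.predictor_names].to_numpy(dtype=float)
        beta = self.coefficients.to_numpy()
        return pd.Series(beta[0] + X @ beta[1:], index=metrics.index,
                         name=self.response_name)

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.coefficients.index,
            "estimate": self.coefficients.to_numpy(),
            "std_error": self.standard_errors.to_numpy(),
            "t_value": self.t_values.to_numpy(),
            "p_value": self.p_values.to_numpy(),
        })

    def summary_dict(self) -> dict:
        return {
            "response": self.response_name,
            "predictors": list(self.predictor_names),
            "adjusted_r2": self.adjusted_r2,
            "rmse": self.rmse,
            "nrmse": self.nrmse,
            "y_min": self.y_min,
            "y_max": self.y_max,
            "n_obs": self.n_obs,
        }


def _aligned(metrics: pd.DataFrame, response: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    common = metrics.index.intersection(response.index)
    if len(common) < len(metrics) or len(common) < len(response):
        warnings.warn(
            f"dropping {len(metrics) + len(response) - 2 * len(common)} unmatched plots",
            stacklevel=3,
        )
    return metrics.loc[common], response.loc[common].astype(float)


def screen_predictors(
    metrics: pd.DataFrame,
    response: pd.Series,
    r_threshold: float = 0.7,
    alpha: float = 0.05,
) -> list[str]:
    """Metrics with |Pearson r| > threshold and correlation-test p < alpha.

    Returned in decreasing order of |r|.  Constant columns cannot be
    correlated and are skipped with a warning.  Negative correlations count:
    a metric that tracks the response inversely is as informative in a linear
    model as a positive one.
    """
    X, y = _aligned(metrics, response)
    if len(y) < 3:
        raise ValueError("need at least 3 plots for correlation screening")
    selected: list[tuple[str, float]] = []
    for name in X.columns:
        col = X[name].to_numpy(dtype=float)
        if np.any(~np.isfinite(col)) or np.ptp(col) == 0:
            warnings.warn(f"metric {name!r} constant or incomplete; skipped", stacklevel=2)
            continue
        r, p = stats.pearsonr(col, y.to_numpy())
        if abs(r) > r_threshold and p < alpha:
            selected.append((name, abs(r)))
    selected.sort(key=lambda t: -t[1])
    return [name for name, _ in selected]


def fit_linear_model(
    metrics: pd.DataFrame,
    response: pd.Series,
    predictors: list[str],
    response_name: str | None = None,
) -> FittedModel:
    """OLS fit of the response on the named metrics, with intercept."""
    X, y = _aligned(metrics, response)
    missing = [p for p in predictors if p not in X.columns]
    if missing:
        raise KeyError(f"unknown predictor column(s): {missing}")
    n, p = len(y), len(predictors)
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} plots to fit {p} predictors")
    design = sm.add_constant(X[predictors].astype(float), has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError(f"rank-deficient design; collinear predictors among {predictors}")
    res = sm.OLS(y, design).fit()
    return FittedModel(
        response_name=response_name or str(response.name or "response"),
        predictor_names=list(predictors),
        coefficients=res.params,
        standard_errors=res.bse,
        t_values=res.tvalues,
        p_values=res.pvalues,
        adjusted_r2=float(res.rsquared_adj),
        r2=float(res.rsquared),
        n_obs=n,
        residuals=res.resid,
    )


def loocv_evaluate(
    metrics: pd.DataFrame,
    response: pd.Series,
    predictors: list[str],
    response_name: str | None = None,
) -> FittedModel:
    """Fit and attach leave-one-out diagnostics (RMSE, nRMSE, predictions).

    For OLS the held-out prediction for plot i equals
    ``y_i - e_i / (1 - h_ii)`` with e the full-fit residual and h the
    leverage, so no refitting is needed; the identity is exact.
    """
    model = fit_linear_model(metrics, response, predictors, response_name)
    X, y = _aligned(metrics, response)
    n, p = len(y), len(predictors)
    if n < p + 3:
        raise ValueError(f"need at least {p + 3} plots for LOOCV with {p} predictors")
    design = sm.add_constant(X[predictors].astype(float), has_constant="add").to_numpy()
    yv = y.to_numpy()
    Q, _ = np.linalg.qr(design)
    leverage = np.sum(Q * Q, axis=1)
    if np.any(leverage >= 1.0 - 1e-12):
        bad = list(y.index[leverage >= 1.0 - 1e-12])
        raise ValueError(f"LOOCV fold(s) rank-deficient when holding out plot(s) {bad}")
    resid = yv - design @ np.linalg.lstsq(design, yv, rcond=None)[0]
    loo_resid = resid / (1.0 - leverage)
    preds = pd.Series(yv - loo_resid, index=y.index, name=f"{model.response_name}_loocv")

    model.loocv_predictions = preds
    model.rmse = float(np.sqrt(np.mean(loo_resid ** 2)))
    model.y_min = float(yv.min())
    model.y_max = float(yv.max())
    model.nrmse = normalized_rmse(yv, preds.to_numpy())
    return model


def normalized_rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """RMSE divided by the observed range (a fraction; *100 for percent)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    rmse = float(np.sqrt(np.mean((observed - predicted) ** 2)))
    span = float(observed.max() - observed.min())
    if span == 0:
        raise ValueError("observed response has zero range; nRMSE undefined")
    return rmse / span


def save_model_json(model: FittedModel, path) -> None:
    """Persist a fitted model (coefficients + diagnostics) as JSON."""
    import json

    payload = model.summary_dict()
    payload["coefficients"] = {k: float(v) for k, v in model.coefficients.items()}
    payload["standard_errors"] = {k: float(v) for k, v in model.standard_errors.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model_json(path) -> FittedModel:
    """Rebuild a predict-capable model from :func:`save_model_json` output."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    names = ["const"] + list(payload["predictors"])
    coef = pd.Series({k: payload["coefficients"][k] for k in names})
    se = pd.Series({k: payload.get("standard_errors", {}).get(k, np.nan) for k in names})
    nan = pd.Series(np.nan, index=names)
    return FittedModel(
        response_name=payload["response"],
        predictor_names=list(payload["predictors"]),
        coefficients=coef,
        standard_errors=se,
        t_values=nan,
        p_values=nan.copy(),
        adjusted_r2=payload.get("adjusted_r2", np.nan),
        r2=np.nan,
        n_obs=payload.get("n_obs", 0),
        rmse=payload.get("rmse"),
        nrmse=payload.get("nrmse"),
        y_min=payload.get("y_min"),
        y_max=payload.get("y_max"),
    )


#: DBH classes (cm) acting as field proxies for the two understory layers.
DBH_CLASSES = {"LU": (0.0, 9.0), "UU": (9.0, 20.0)}


def spearman_validation(
    profiles: pd.DataFrame,
    field_trees: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman correlation of PDI with DBH-class tree counts per plot.

    ``profiles`` is the tidy stratum-PDI table (plot_id, stratum, pdi);
    ``field_trees`` has one row per tree (plot_id, dbh_cm).  Small trees
    (DBH < 9 cm) are correlated with LU PDI, intermediate trees
    (9 <= DBH <= 20 cm) with UU PDI.  Plots missing from either table are
    excluded with a warning.
    """
    pdi = profiles.pivot_table(index="plot_id", columns="stratum", values="pdi")
    plots = pdi.index
    tree_plots = pd.Index(field_trees["plot_id"].unique())
    common = plots.intersection(tree_plots)
    dropped = set(plots.symmetric_difference(tree_plots))
    if dropped:
        warnings.warn(f"plots present in only one table excluded: {sorted(dropped)}",
                      stacklevel=2)
    if len(common) < 3:
        raise ValueError("need at least 3 matched plots for rank validation")

    rows = []
    for stratum, (lo, hi) in DBH_CLASSES.items():
        if stratum == "LU":
            sel = (field_trees["dbh_cm"] < hi)
        else:
            sel = (field_trees["dbh_cm"] >= lo) & (field_trees["dbh_cm"] <= hi)
        counts = (
            field_trees.loc[sel].groupby("plot_id").size()
            .reindex(common, fill_value=0).astype(float)
        )
        rho, p = stats.spearmanr(pdi.loc[common, stratum].to_numpy(), counts.to_numpy())
        rows.append({"stratum": stratum, "spearman_rho": float(rho),
                     "p_value": float(p), "n_plots": len(common)})
    return pd.DataFrame(rows)
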