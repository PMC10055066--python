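"""Linear models predicting codon usage bias from expression and GCI.

Four nested ordinary-least-squares models are compared by adjusted R^2:

    1. expr_only    CUB ~ mean_expr
    2. gci_only     CUB ~ GCI
    3. additive     CUB ~ mean_expr + GCI
    4. interaction  CUB ~ mean_expr + GCI + mean_expr:GCI

Collinearity of the additive design is diagnosed with variance inflation
factors (VIF_j = 1/(1 - R_j^2), where R_j^2 regresses predictor j on the
others); VIF near 1 means no collinearity, above ~5 is problematic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datatypes import ValidationError

MODEL_IDS = ("expr_only", "gci_only", "additive", "interaction")


@dataclass
class ModelFit:
    model_id: str
    params: pd.Series            # coefficient estimates, incl. intercept
    bse: pd.Series               # standard errors
    pvalues: pd.Series           # per-coefficient two-sided t-test p
    n: int
    r2: float
    adj_r2: float
    f_pvalue: float              # overall F-test


def _design(mean_expr: np.ndarray, gci: np.ndarray, model_id: str) -> pd.DataFrame:
    cols = {"const": np.ones_like(mean_expr)}
    if model_id in ("expr_only", "additive", "interaction"):
        cols["mean_expr"] = mean_expr
    if model_id in ("gci_only", "additive", "interaction"):
        cols["gci"] = gci
    if model_id == "interaction":
        cols["mean_expr:gci"] = mean_expr * gci
    return pd.DataFrame(cols)


def _align(cub, mean_expr, gci) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "cub": pd.Series(cub, dtype=float),
            "mean_expr": pd.Series(mean_expr, dtype=float),
            "gci": pd.Series(gci, dtype=float),
        }
    ).dropna()
    return df


def fit_models(cub, mean_expr, gci, min_n: int = 10) -> dict:
    """Fit the four nested OLS models on the genes shared by all inputs.

    Inputs are gene-indexed Series (or mappings); genes with any missing
    quantity are excluded listwise so every model is compared on the same n.
    Returns ``{model_id: ModelFit}``.
    """
    df = _align(cub, mean_expr, gci)
    if len(df) < min_n:
        raise ValidationError(f"only {len(df)} genes with all quantities defined")
    fits = {}
    for model_id in MODEL_IDS:
        X = _design(df["mean_expr"].to_numpy(), df["gci"].to_numpy(), model_id)
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValidationError(f"rank-deficient design for model {model_id}")
        res = sm.OLS(df["cub"].to_numpy(), X).fit()
        fits[model_id] = ModelFit(
            model_id=model_id,
            params=pd.Series(res.params, index=X.columns),
            bse=pd.Series(res.bse, index=X.columns),
            pvalues=pd.Series(res.pvalues, index=X.columns),
            n=int(res.nobs),
            r2=float(res.rsquared),
            adj_r2=float(res.rsquared_adj),
            f_pvalue=float(res.f_pvalue),
        )
    return fits


def vif(mean_expr, gci) -> dict:
    """Variance inflation factors for the additive (two-predictor) design.

    With two predictors both VIFs equal 1/(1 - r^2) for their Pearson r.
    Near-perfect collinearity is reported as a value above 1e6 with a
    warning rather than an exception.
    """
    df = pd.DataFrame(
        {"mean_expr": pd.Series(mean_expr, dtype=float),
         "gci": pd.Series(gci, dtype=float)}
    ).dropna()
    if len(df) < 3:
        raise ValidationError("need at least 3 genes")
    out = {}
    for j in ("mean_expr", "gci"):
        others = [c for c in df.columns if c != j]
        y = df[j].to_numpy()
        X = sm.add_constant(df[others].to_numpy())
        if np.std(y) == 0 or np.std(df[others[0]]) == 0:
            raise ValidationError(f"constant predictor in VIF computation")
        r2 = sm.OLS(y, X).fit().rsquared
        v = np.inf if r2 >= 1 else 1.0 / (1.0 - r2)
        if v > 1e6:
            warnings.warn(f"near-perfect collinearity: VIF({j}) > 1e6")
        out[j] = float(min(v, np.inf))
    return out


def prediction_surface(fit: ModelFit, expr_grid, gci_values) -> pd.DataFrame:
    """Predicted CUB on an expression grid at fixed GCI values.

    For the additive model the lines are parallel across GCI; the
    interaction model lets the expression slope depend on GCI.
    Returns a tidy frame with columns ``mean_expr``, ``gci``, ``predicted``.
    """
    if fit.model_id not in ("additive", "interaction"):
        raise ValidationError("prediction surface requires additive or interaction fit")
    expr_grid = np.asarray(list(expr_grid), dtype=float)
    gci_values = np.asarray(list(gci_values), dtype=float)
    if expr_grid.size == 0 or gci_values.size == 0:
        raise ValidationError("empty prediction grid")
    rows = []
    b = fit.params
    for g in gci_values:
        y = b["const"] + b["mean_expr"] * expr_grid + b["gci"] * g
        if "mean_expr:gci" in b.index:
            y = y + b["mean_expr:gci"] * expr_grid * g
        for x, yy in zip(expr_grid, y):
            rows.append({"mean_expr": x, "gci": g, "predicted": float(yy)})
    return pd.DataFrame(rows)


def compare_linear_quadratic(cub, gci) -> dict:
    """AIC comparison of a linear vs quadratic-in-GCI model for CUB.

    A lower AIC for the linear model indicates the CUB-GCI relationship is
    adequately linear.  (Model-form check; reported for diagnostics only.)
    """
    df = pd.DataFrame(
        {"cub": pd.Series(cub, dtype=float), "gci": pd.Series(gci, dtype=float)}
    ).dropna()
    if len(df) < 4:
        raise ValidationError("too few genes for model-form comparison")
    g = df["gci"].to_numpy()
    y = df["cub"].to_numpy()
    lin = sm.OLS(y, sm.add_constant(g)).fit()
    quad = sm.OLS(y, sm.add_constant(np.column_stack([g, g**2]))).fit()
    return {
        "aic_linear": float(lin.aic),
        "aic_quadratic": float(quad.aic),
        "linear_preferred": bool(lin.aic <= quad.aic),
    }


def fits_to_frame(fits: dict) -> pd.DataFrame:
    """Tidy model summary (model, term, estimate, SE, p, adj_R2, n)."""
    rows = []
    for model_id, fit in fits.items():
        for term in fit.params.index:
            rows.append(
                {
                    "model": model_id,
                    "term": term,
                    "estimate": fit.params[term],
                    "se": fit.bse[term],
                    "p_coef": fit.pvalues[term],
                    "r2": fit.r2,
                    "adj_r2": fit.adj_r2,
                    "f_pvalue": fit.f_pvalue,
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows)
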