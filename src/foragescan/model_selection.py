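"""Candidate linear mixed models and information-criterion comparison.

Ten a-priori candidate models for each organization indicator, all sharing
a random participant intercept and built from four fixed-effect predictors:
ln(age) (numeric), condition (feature = 0 / conjunction = 1), set size
(numeric: 60, 100, 140, 180) and bin (first half = 0 / second half = 1).
Model 1 carries the four main effects; Models 2-10 add specific two-, three-
and four-way interaction products.  With this coding each interaction is a
single elementwise-product column, and the total parameter count k (fixed
coefficients + random-intercept variance + residual variance) is

    Model:  1  2  3  4  5  6  7  8   9   10
    k:      7  8  8  9  8  8  9  11  12  13

Models are fitted by *maximum likelihood* (not REML) so log-likelihoods —
and hence AIC and the small-sample AICc — are comparable across different
fixed-effect structures.  Candidates are ranked by Delta_i = AICc - min
AICc; ties go to the smaller model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM

MAIN_EFFECTS = ("log_age", "condition", "set_size", "bin")

#: fixed-effect terms per model; each term is a tuple of predictor names
#: whose columns are multiplied elementwise (singletons are main effects).
MODEL_TERMS: dict[int, list[tuple[str, ...]]] = {}
_BASE = [("log_age",), ("condition",), ("set_size",), ("bin",)]
MODEL_TERMS[1] = list(_BASE)
MODEL_TERMS[2] = MODEL_TERMS[1] + [("log_age", "set_size")]
MODEL_TERMS[3] = MODEL_TERMS[1] + [("condition", "set_size")]
MODEL_TERMS[4] = MODEL_TERMS[1] + [("log_age", "set_size"),
                                   ("condition", "set_size")]
MODEL_TERMS[5] = MODEL_TERMS[1] + [("log_age", "bin")]
MODEL_TERMS[6] = MODEL_TERMS[1] + [("bin", "condition")]
MODEL_TERMS[7] = MODEL_TERMS[1] + [("log_age", "bin"), ("condition", "bin")]
MODEL_TERMS[8] = MODEL_TERMS[1] + [("log_age", "set_size"),
                                   ("condition", "set_size"),
                                   ("log_age", "bin"), ("bin", "condition")]
MODEL_TERMS[9] = MODEL_TERMS[8] + [("log_age", "set_size", "condition")]
# the four-way model retains the three-way product (hierarchical nesting);
# its total parameter count is 13
MODEL_TERMS[10] = MODEL_TERMS[9] + [("log_age", "set_size", "condition",
                                     "bin")]

MODEL_IDS = tuple(sorted(MODEL_TERMS))


def n_parameters(model_id: int) -> int:
    """Total k: intercept + fixed terms + 2 variance components."""
    return 1 + len(MODEL_TERMS[model_id]) + 2


def _coded_predictors(rows: pd.DataFrame) -> pd.DataFrame:
    cond = rows["condition"]
    if cond.dtype == object or str(cond.dtype) == "category":
        cond = (cond == "conjunction").astype(float)
    b = rows["bin"]
    if b.dtype == object or str(b.dtype) == "category":
        b = (b == "bin2").astype(float)
    return pd.DataFrame({
        "log_age": rows["log_age"].astype(float),
        "condition": cond.astype(float),
        "set_size": rows["set_size"].astype(float),
        "bin": b.astype(float),
    })


def build_design(model_id: int, rows: pd.DataFrame, indicator: str,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Response vector, fixed-effect design, grouping vector, column names.

    ``rows`` must contain participant, log_age, condition, set_size, bin and
    the indicator column; rows where the indicator is missing are dropped.
    """
    if model_id not in MODEL_TERMS:
        raise ValueError(f"unknown model_id {model_id}")
    rows = rows.dropna(subset=[indicator])
    pred = _coded_predictors(rows)
    cols = [np.ones(len(rows))]
    names = ["intercept"]
    for term in MODEL_TERMS[model_id]:
        col = np.ones(len(rows))
        for p in term:
            col = col * pred[p].to_numpy()
        cols.append(col)
        names.append(":".join(term))
    X = np.column_stack(cols)
    y = rows[indicator].to_numpy(dtype=float)
    groups = rows["participant"].to_numpy()
    return y, X, groups, names


@dataclass
class ModelFit:
    """One candidate's ML fit summary."""

    model_id: int
    loglik: float
    n: int
    k: int
    aic: float
    aicc: float
    converged: bool = True
    singular: bool = False
    coef: dict[str, float] | None = None


def aicc_from(aic: float, k: int, n: int) -> float:
    """Small-sample correction: AICc = AIC + 2k(k+1)/(n-k-1)."""
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def fit_lmm_ml(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
               model_id: int = 0,
               names: list[str] | None = None) -> ModelFit:
    """ML fit of a random-intercept linear mixed model.

    A fit whose random-intercept variance collapses to ~0 is retained and
    flagged ``singular`` (the model then coincides with OLS).
    """
    n, p = X.shape
    k = p + 2
    if n <= k + 1:
        raise ValueError(f"n={n} too small for k={k}")
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 groups")
    # column scaling (a diagonal reparameterization of the fixed effects)
    # leaves the ML log-likelihood unchanged but keeps the optimizer's
    # Hessian well conditioned for interaction columns with large ranges
    scale_cols = np.linalg.norm(X, axis=0) / np.sqrt(n)
    scale_cols[scale_cols == 0] = 1.0
    Xs = X / scale_cols
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("bfgs", "lbfgs", "powell"):
            try:
                res = MixedLM(y, Xs, groups=groups).fit(
                    reml=False, method=method, disp=False)
                break
            except np.linalg.LinAlgError:
                continue
    if res is None:
        raise np.linalg.LinAlgError(
            "mixed-model fit failed under all optimizers")
    llf = float(res.llf)
    aic = -2.0 * llf + 2.0 * k
    var_re = float(np.asarray(res.cov_re)[0, 0])
    singular = var_re < 1e-8 * max(float(res.scale), 1e-12)
    one_per_group = np.max(np.bincount(
        pd.factorize(groups)[0])) == 1
    coef = None
    if names is not None:
        coef = dict(zip(names, np.asarray(res.fe_params, dtype=float)
                        / scale_cols))
    return ModelFit(model_id=model_id, loglik=llf, n=n, k=k, aic=aic,
                    aicc=aicc_from(aic, k, n),
                    converged=bool(res.converged),
                    singular=singular or one_per_group, coef=coef)


def fit_candidates(rows: pd.DataFrame, indicator: str,
                   model_ids=MODEL_IDS) -> list[ModelFit]:
    """Fit every candidate on the identical row set (common NaN filter)."""
    rows = rows.dropna(subset=[indicator])
    fits = []
    for mid in model_ids:
        y, X, groups, names = build_design(mid, rows, indicator)
        fits.append(fit_lmm_ml(y, X, groups, model_id=mid, names=names))
    return fits


def aic_table(fits: list[ModelFit]) -> pd.DataFrame:
    """Rank fitted candidates by AICc; Delta_i = AICc - min AICc.

    All fits must be on the same rows (equal n) — information criteria on
    different data are not comparable.  Ties for the minimum go to the
    smaller k.  Sorted by model_id.
    """
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError(f"fits on differing row counts {sorted(ns)}: "
                         "not comparable")
    df = pd.DataFrame({
        "model_id": [f.model_id for f in fits],
        "k": [f.k for f in fits],
        "loglik": [f.loglik for f in fits],
        "aic": [f.aic for f in fits],
        "aicc": [f.aicc for f in fits],
        "converged": [f.converged for f in fits],
        "singular": [f.singular for f in fits],
    }).sort_values("model_id").reset_index(drop=True)
    df["delta"] = df["aicc"] - df["aicc"].min()
    best = df.loc[np.isclose(df["aicc"], df["aicc"].min())]
    best_id = int(best.sort_values(["k", "model_id"]).iloc[0]["model_id"])
    df["best"] = df["model_id"] == best_id
    return df
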