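"""Model comparison: fit metrics, information criteria, overdispersion, CV, LRT.

All metrics are computed on the response scale (counts), matching how count
regressions for surveillance data are usually compared: R² is
1 - SS_res/SS_tot against the observed counts, RMSE/MAE are raw prediction
errors, and CV-10 is the pooled out-of-fold RMSE over ten deterministic
folds.  Sample variances use the n-1 denominator throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import KFold

from countreg.distributions import FamilySpec
from countreg.glm import CountGLM, _split_design, _as_family_spec

__all__ = [
    "MetricSet",
    "DispersionTestResult",
    "LRTResult",
    "fit_metrics",
    "information_criteria",
    "dispersion_index",
    "overdispersion_test",
    "cv10",
    "lrt",
]


@dataclass
class MetricSet:
    """Per-model comparison metrics (column order of a model-comparison table)."""

    r2: float
    rmse: float
    mae: float
    aic: float
    bic: float
    cv10: float

    def as_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in ("r2", "rmse", "mae", "aic", "bic", "cv10")}


@dataclass
class DispersionTestResult:
    """One-sided test of overdispersion (H1: dispersion > 1)."""

    di: float
    z: float
    p: float

    def as_dict(self) -> dict:
        return {"di": float(self.di), "z": float(self.z), "p": float(self.p)}


@dataclass
class LRTResult:
    """Likelihood-ratio test of a nested (reduced) model against the full one."""

    stat: float
    df: int
    p: float

    def as_dict(self) -> dict:
        return {"stat": float(self.stat), "df": int(self.df), "p": float(self.p)}


def fit_metrics(y, yhat) -> tuple[float, float, float]:
    """(r2, rmse, mae) on the response scale.

    r2 = 1 - SS_res/SS_tot; NaN (with a warning) when y is constant, since
    SS_tot is then zero and explained variance is undefined.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    resid = y - yhat
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant response: R^2 undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return r2, rmse, mae


def information_criteria(loglik: float, k: int, n: int, penalty: Optional[float] = None):
    """(aic, bic) = -2*loglik + penalty*k with penalty 2 (AIC) and log n (BIC).

    A custom ``penalty`` returns the single generalized criterion instead.
    """
    if k < 1 or n < 1:
        raise ValueError("k and n must be >= 1")
    if penalty is not None:
        return -2.0 * loglik + penalty * k
    aic = -2.0 * loglik + 2.0 * k
    bic = -2.0 * loglik + np.log(n) * k
    return float(aic), float(bic)


def dispersion_index(y) -> float:
    """Sample variance (n-1 denominator) over sample mean; >1 flags overdispersion."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    m = y.mean()
    if m == 0:
        raise ValueError("zero mean: dispersion index undefined")
    return float(np.var(y, ddof=1) / m)


def overdispersion_test(design: pd.DataFrame) -> DispersionTestResult:
    """One-sided auxiliary-statistic z-test of overdispersion after a Poisson fit.

    Fits the Poisson regression, forms a_i = ((y_i - mu_i)^2 - y_i)/mu_i
    (mean nu*mu_i under a Var = mu + nu*mu^2 alternative, mean 0 under
    equidispersion) and refers z = mean(a)/(sd(a)/sqrt(n)) to the upper
    normal tail.  Also reports the raw variance-to-mean dispersion index.
    """
    X, y = _split_design(design)
    fitted = CountGLM("poisson").fit(X, y)
    mu = fitted.fitted_means_
    a = ((y - mu) ** 2 - y) / mu
    n = len(a)
    sd = float(np.std(a, ddof=1))
    if sd == 0:
        raise ValueError("degenerate auxiliary statistic: all values identical")
    z = float(np.mean(a) / (sd / np.sqrt(n)))
    return DispersionTestResult(di=dispersion_index(y), z=z, p=float(stats.norm.sf(z)))


def cv10(
    family: Union[str, FamilySpec],
    design: pd.DataFrame,
    seed: int,
    n_splits: int = 10,
) -> float:
    """Pooled out-of-fold RMSE over ``n_splits`` deterministic shuffled folds.

    Rows are shuffled by ``seed`` into near-equal folds (sizes differ by at
    most 1); each fold is predicted by a model fitted on the others.  Folds
    whose training design is rank-deficient or too small are skipped with a
    warning and excluded from the pooled error.
    """
    spec = _as_family_spec(family)
    X, y = _split_design(design)
    X = np.asarray(X, dtype=float)
    if len(y) < n_splits:
        raise ValueError(f"need at least {n_splits} rows for {n_splits}-fold CV")
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    sq_errors = []
    proto = CountGLM(family=spec.family, dispersion=spec.dispersion)
    for i, (tr, te) in enumerate(kf.split(X)):
        try:
            m = clone(proto).fit(X[tr], y[tr])
        except ValueError as exc:
            warnings.warn(f"fold {i} skipped: {exc}", stacklevel=2)
            continue
        sq_errors.append((y[te] - m.predict(X[te])) ** 2)
    if not sq_errors:
        raise ValueError("every cross-validation fold failed")
    return float(np.sqrt(np.mean(np.concatenate(sq_errors))))


def lrt(
    loglik_full: float,
    k_full: int,
    loglik_reduced: float,
    k_reduced: int,
    tol: float = 1e-8,
) -> LRTResult:
    """Likelihood-ratio test: stat = -2*(loglik_reduced - loglik_full).

    Degrees of freedom are the difference in estimated-parameter counts; the
    p-value is the upper chi-square tail.  A materially negative statistic
    (reduced model beating the full one) indicates non-nested or failed fits
    and raises.
    """
    if k_full <= k_reduced:
        raise ValueError(
            f"full model must have more parameters than the reduced one "
            f"(k_full={k_full}, k_reduced={k_reduced})"
        )
    stat = -2.0 * (loglik_reduced - loglik_full)
    if stat < -tol:
        raise ValueError(
            f"reduced log-likelihood exceeds the full one (LR stat {stat:.3g}); "
            "models are not nested or a fit failed"
        )
    stat = max(stat, 0.0)
    df = int(k_full - k_reduced)
    return LRTResult(stat=float(stat), df=df, p=float(stats.chi2.sf(stat, df)))
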