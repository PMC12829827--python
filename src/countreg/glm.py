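"""Maximum-likelihood count regression with a log link.

One estimator, :class:`CountGLM`, covers the four families.  The linear
predictor always models the mean: ``log E[Y_i] = x_i' beta``.  For the Bell
family the distribution parameter is recovered from the mean through the
principal Lambert W branch, ``lam_i = W0(exp(x_i' beta))``, so that
``lam_i * exp(lam_i) = E[Y_i]`` holds exactly.

Fitting is quasi-Newton (L-BFGS-B) on the negative log-likelihood.  Scores
in beta are analytic for every family — for the PIG family through the
mixed-Poisson identity d loglik/d eta_i = y_i - t_i(y_i) with
t_i(y) = (y+1) p_i(y+1)/p_i(y) — and dispersion parameters are optimized on
the log scale (analytic for the negative binomial, central difference for
PIG).  The Poisson solution initializes every other family.  Standard
errors come from the inverse observed information (Jacobian of the score at
the optimum), with two-sided normal (Wald) p-values.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y
from statsmodels.tools import numdiff

from countreg.distributions import (
    FamilySpec,
    bell_mean_to_lambda,
    log_bell_number,
    pig_logpmf,
)

__all__ = ["CountGLM", "fit", "predict", "coef_table"]

_ETA_MAX = 80.0  # log-mean beyond which the likelihood is treated as divergent
_LOG_DISP_BOUNDS = (np.log(1e-8), np.log(1e6))


def _as_family_spec(family: Union[str, FamilySpec], dispersion=None) -> FamilySpec:
    if isinstance(family, FamilySpec):
        return family
    return FamilySpec(family, dispersion)


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Names of columns that add no rank (greedy scan, intercept first)."""
    bad, kept = [], np.empty((X.shape[0], 0))
    rank = 0
    for j in range(X.shape[1]):
        trial = np.column_stack([kept, X[:, j]])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            kept, rank = trial, r
        else:
            bad.append(names[j])
    return bad


def _make_objective(
    family: str, Xd: np.ndarray, y: np.ndarray, est_disp: bool, fixed_disp: Optional[float]
) -> tuple[Callable, Callable]:
    """(negative loglik, its gradient) over params = beta [+ log dispersion].

    Log-likelihoods include all constants (log y!, log B_y) so that AIC/BIC
    and likelihood-ratio statistics are comparable across families.
    """
    log_bell = log_bell_number(y.astype(int)) if family == "bell" else None
    log_fact = special.gammaln(y + 1.0)

    def _mu(beta):
        eta = Xd @ beta
        if np.max(np.abs(eta)) > _ETA_MAX:
            return eta, None
        return eta, np.exp(eta)

    def loglik(beta, disp):
        eta, mu = _mu(beta)
        if mu is None:
            return -np.inf
        if family == "poisson":
            return float(np.sum(y * eta - mu - log_fact))
        if family == "negbin":
            a = 1.0 / disp
            return float(
                np.sum(
                    special.gammaln(y + a)
                    - special.gammaln(a)
                    - log_fact
                    + a * np.log(a / (a + mu))
                    + y * (eta - np.log(a + mu))
                )
            )
        if family == "pig":
            return float(np.sum(pig_logpmf(y, mu, disp)))
        lam = bell_mean_to_lambda(mu)
        return float(np.sum(y * np.log(lam) + 1.0 - np.exp(lam) + log_bell - log_fact))

    def score_beta(beta, disp):
        eta, mu = _mu(beta)
        if mu is None:  # outside the admissible region; push back
            mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        if family == "poisson":
            return Xd.T @ (y - mu)
        if family == "negbin":
            return Xd.T @ ((y - mu) / (1.0 + disp * mu))
        if family == "bell":
            lam = bell_mean_to_lambda(mu)
            return Xd.T @ ((y - mu) / (1.0 + lam))
        # PIG: d loglik/d eta_i = y_i - (y_i+1) p(y_i+1)/p(y_i)
        t = (y + 1.0) * np.exp(pig_logpmf(y + 1, mu, disp) - pig_logpmf(y, mu, disp))
        return Xd.T @ (y - t)

    def score_logdisp(beta, disp):
        if family == "negbin":
            eta, mu = _mu(beta)
            mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
            a = 1.0 / disp
            dl_da = float(
                np.sum(
                    special.digamma(y + a)
                    - special.digamma(a)
                    + np.log(a / (a + mu))
                    + 1.0
                    - (a + y) / (a + mu)
                )
            )
            return -a * dl_da  # d a / d log(nu) = -a
        # PIG: central difference in log tau
        h = 1e-5
        return (loglik(beta, disp * np.exp(h)) - loglik(beta, disp * np.exp(-h))) / (2 * h)

    if est_disp:

        def nll(params):
            return -loglik(params[:-1], np.exp(params[-1]))

        def grad(params):
            beta, disp = params[:-1], float(np.exp(params[-1]))
            return -np.r_[score_beta(beta, disp), score_logdisp(beta, disp)]

    else:

        def nll(params):
            return -loglik(params, fixed_disp)

        def grad(params):
            return -score_beta(params, fixed_disp)

    return nll, grad


class CountGLM(RegressorMixin, BaseEstimator):
    """Count regression with log link for one of four count families.

    Parameters
    ----------
    family : {"poisson", "negbin", "pig", "bell"}, default="poisson"
        Response distribution.  ``negbin`` has Var = mu + nu*mu**2 and
        ``pig`` Var = mu + tau*mu**2; both reduce to Poisson as the
        dispersion tends to zero.  ``bell`` is overdispersed with no free
        dispersion parameter (Var = mu*(1 + lam)).
    dispersion : float, optional
        Fix the dispersion (nu or tau) at this value instead of estimating
        it by maximum likelihood.  Only valid for ``negbin`` and ``pig``.
    tol : float, default=1e-13
        Optimizer function tolerance (L-BFGS-B ``ftol``).
    max_iter : int, default=500
        Maximum optimizer iterations.

    Attributes
    ----------
    beta_ : ndarray of shape (n_features + 1,)
        Coefficients, intercept first.
    coef_ : ndarray of shape (n_features,)
        Slopes (``beta_[1:]``), following the scikit-learn convention.
    intercept_ : float
    dispersion_ : float or None
        Estimated (or fixed) nu/tau; None for Poisson and Bell.
    loglik_ : float
        Maximized log-likelihood including all constants (log y!, log B_y).
    vcov_ : ndarray of shape (n_features + 1, n_features + 1)
        Coefficient covariance from the inverse observed information.
    fitted_means_ : ndarray
        Per-observation fitted means exp(x' beta) on the training design.
    k_params_ : int
        Number of estimated parameters (coefficients + estimated dispersion).
    converged_ : bool

    Examples
    --------
    >>> import numpy as np
    >>> m = CountGLM("poisson").fit(np.zeros((4, 0)), [2, 4, 3, 3])
    >>> float(np.round(m.intercept_, 4))
    1.0986
    """

    def __init__(
        self,
        family: str = "poisson",
        dispersion: Optional[float] = None,
        tol: float = 1e-13,
        max_iter: int = 500,
    ):
        self.family = family
        self.dispersion = dispersion
        self.tol = tol
        self.max_iter = max_iter

    @property
    def _spec_cache(self) -> FamilySpec:
        return _as_family_spec(self.family, self.dispersion)

    def fit(self, X, y, feature_names: Optional[Sequence[str]] = None):
        """Fit by maximum likelihood.  X: (n, p) covariates; y: counts."""
        spec = self._spec_cache
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
        if np.ndim(X) == 2 and np.shape(X)[1] == 0:
            X = np.empty((len(y), 0))
            y = np.asarray(y, dtype=float)
        else:
            X, y = check_X_y(X, y, dtype=float, y_numeric=True)
        if np.any(y < 0) or np.any(y % 1 != 0):
            raise ValueError("y must contain non-negative integer counts")
        n, p = X.shape
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(p)]
        self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        self.n_features_in_ = p

        est_disp = spec.has_dispersion and spec.dispersion is None
        k = p + 1 + (1 if est_disp else 0)
        if n < k + 1:
            raise ValueError(f"need at least {k + 1} observations to fit {k} parameters")

        Xd = np.column_stack([np.ones(n), X])
        names_d = ["const"] + list(feature_names)
        if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
            bad = _collinear_columns(Xd, names_d)
            raise ValueError(f"design matrix is rank-deficient; collinear columns: {bad}")

        # standardize slopes internally for optimizer conditioning
        center = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        Xs = np.column_stack([np.ones(n), (X - center) / scale])

        # Poisson fit initializes every family
        nll_p, grad_p = _make_objective("poisson", Xs, y, False, None)
        beta0 = np.r_[np.log(max(y.mean(), 1e-3)), np.zeros(p)]
        res_p = optimize.minimize(
            nll_p, beta0, jac=grad_p, method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-10},
        )
        beta_init = res_p.x

        if spec.family == "poisson":
            res, disp_hat = res_p, None
        else:
            nll, grad = _make_objective(spec.family, Xs, y, est_disp, spec.dispersion)
            if est_disp:
                mu_p = np.exp(np.clip(Xs @ beta_init, -_ETA_MAX, _ETA_MAX))
                mom = float(np.sum((y - mu_p) ** 2 - mu_p) / max(np.sum(mu_p**2), 1e-12))
                x0 = np.r_[beta_init, np.log(np.clip(mom, 1e-4, 1e4))]
                bounds = [(None, None)] * (p + 1) + [_LOG_DISP_BOUNDS]
            else:
                x0, bounds = beta_init, None
            res = optimize.minimize(
                nll, x0, jac=grad, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-10},
            )
            disp_hat = float(np.exp(res.x[-1])) if est_disp else spec.dispersion

        beta_std = res.x[: p + 1]
        # map standardized-space coefficients back to the original scale
        slopes = beta_std[1:] / scale
        intercept = beta_std[0] - float(slopes @ center)
        beta = np.r_[intercept, slopes]

        self.beta_ = beta
        self.intercept_ = float(intercept)
        self.coef_ = slopes
        self.dispersion_ = disp_hat
        self.n_obs_ = n
        self.k_params_ = k
        self.converged_ = bool(res.success)
        self._names_d = names_d

        nll_o, grad_o = _make_objective(spec.family, Xd, y, est_disp, spec.dispersion)
        params = np.r_[beta, np.log(disp_hat)] if est_disp else beta
        self.loglik_ = -float(nll_o(params))
        self.fitted_means_ = np.exp(np.clip(Xd @ beta, -_ETA_MAX, _ETA_MAX))
        self._compute_vcov(params, grad_o, est_disp, disp_hat)
        return self

    def _compute_vcov(self, params, grad, est_disp, disp):
        """Observed information as the Jacobian of the score at the optimum."""
        H = numdiff.approx_fprime(params, grad, centered=True)
        H = (H + H.T) / 2.0
        try:
            cov_all = np.linalg.inv(H)
            if not np.all(np.isfinite(cov_all)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cov_all = np.linalg.pinv(H)
        nb = len(params) - (1 if est_disp else 0)
        self.vcov_ = cov_all[:nb, :nb]
        self.dispersion_se_ = (
            float(np.sqrt(max(cov_all[nb, nb], 0.0)) * disp) if est_disp else None
        )
        self._information_ = H

    # -- prediction and inference -------------------------------------------

    def _validate_predict_X(self, X):
        check_is_fitted(self, "beta_")
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names_in_ if c not in X.columns]
            extra = [c for c in X.columns if c not in set(self.feature_names_in_)]
            if missing or extra:
                raise ValueError(
                    f"design columns do not match fit: missing {missing}, unexpected {extra}"
                )
            X = X.loc[:, list(self.feature_names_in_)]
        if np.ndim(X) == 2 and np.shape(X)[1] == 0:
            return np.empty((np.shape(X)[0], 0))
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns; model was fitted with {self.n_features_in_}"
            )
        return X

    def predict(self, X):
        """Fitted means exp(x' beta); strictly positive."""
        X = self._validate_predict_X(X)
        eta = self.intercept_ + X @ self.coef_
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))

    def coef_table(self) -> pd.DataFrame:
        """Wald inference table: coefficient, SE, z, two-sided normal p-value."""
        check_is_fitted(self, "beta_")
        se2 = np.diag(self.vcov_)
        if np.any(~np.isfinite(se2)) or np.any(se2 <= 0):
            raise ValueError("singular observed information; standard errors unavailable")
        se = np.sqrt(se2)
        z = self.beta_ / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"variable": self._names_d, "coef": self.beta_, "se": se, "z": z, "p_value": p}
        )

    def to_dict(self) -> dict:
        """JSON-serializable fit report."""
        check_is_fitted(self, "beta_")
        tab = self.coef_table()
        return {
            "family": self._spec_cache.family,
            "coefficients": {
                str(r.variable): {
                    "coef": float(r.coef),
                    "se": float(r.se),
                    "z": float(r.z),
                    "p_value": float(r.p_value),
                }
                for r in tab.itertuples()
            },
            "dispersion": None if self.dispersion_ is None else float(self.dispersion_),
            "loglik": float(self.loglik_),
            "k_params": int(self.k_params_),
            "n_obs": int(self.n_obs_),
            "converged": bool(self.converged_),
        }


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimator
# ---------------------------------------------------------------------------

def _split_design(design: pd.DataFrame):
    if "y" not in design.columns:
        raise ValueError("design table must contain a 'y' count column")
    X = design.drop(columns=[c for c in ("y", "month") if c in design.columns])
    return X, design["y"].to_numpy()


def fit(family: Union[str, FamilySpec], design: pd.DataFrame, **kwargs) -> CountGLM:
    """Fit one family on a monthly design table (columns: y, covariates)."""
    spec = _as_family_spec(family)
    X, y = _split_design(design)
    model = CountGLM(family=spec.family, dispersion=spec.dispersion, **kwargs)
    return model.fit(X, y)


def predict(model: CountGLM, design: pd.DataFrame) -> np.ndarray:
    X = design.drop(columns=[c for c in ("y", "month") if c in design.columns])
    return model.predict(X)


def coef_table(model: CountGLM) -> pd.DataFrame:
    return model.coef_table()
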