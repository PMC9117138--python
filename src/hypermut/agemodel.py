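"""Identity-link negative-binomial regression of de novo mutation counts.

The model is E(Y) = b0 + b1 * paternal_age + b2 * maternal_age (+ optional
covariates) with NB variance Var(Y) = mu + mu**2 / theta (theta > 0).  The
identity link mirrors the additive per-year interpretation of the parental
age effect; because it is not a canonical link the mean must be kept
positive explicitly, so the fit is constrained maximum likelihood:
Poisson-style initialization, inner SLSQP over the coefficients with the
linear predictor constrained positive, and the dispersion profiled on an
outer one-dimensional likelihood.

Goodness of fit is summarized by McFadden's pseudo R^2
(1 - loglik / loglik_null); residual diagnostics (Pearson residuals,
weighted-hat-matrix leverages) feed the hypermutation outlier scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "NbFit",
    "fit_nb_identity",
    "fit_poisson_identity",
    "fit_phased_models",
    "slope_ratio",
    "fit_with_carrier_covariates",
    "build_design",
]

_MU_FLOOR = 1e-8


def build_design(table: pd.DataFrame, columns: list[str]) -> np.ndarray:
    """Design matrix with an intercept column prepended."""
    X = np.column_stack(
        [np.ones(len(table))] + [table[c].to_numpy(dtype=float)
                                 for c in columns])
    return X


@dataclass
class NbFit:
    """A fitted identity-link negative-binomial model."""

    params: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    names: list[str]
    theta: float
    loglik: float
    null_loglik: float
    pseudo_r2: float
    fitted: np.ndarray
    pearson_resid: np.ndarray
    leverage: np.ndarray
    nobs: int
    nparams: int
    converged: bool
    boundary: bool = False
    family: str = "negative-binomial"
    dropped: list[str] = field(default_factory=list)

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.se, "p": self.pvalues},
            index=self.names)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    if np.isinf(theta):
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    return float(np.sum(
        special.gammaln(y + theta) - special.gammaln(theta)
        - special.gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))))


def _nb_grad_beta(y, mu, theta, X) -> np.ndarray:
    if np.isinf(theta):
        w = y / mu - 1.0
    else:
        w = y / mu - (y + theta) / (mu + theta)
    return X.T @ w


def _fit_beta(y: np.ndarray, X: np.ndarray, theta: float,
              beta0: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Maximize the NB likelihood over beta at fixed theta (SLSQP)."""

    def negll(b):
        mu = X @ b
        if np.any(mu <= 0):
            return np.inf
        return -_nb_loglik(y, mu, theta)

    def jac(b):
        mu = np.maximum(X @ b, _MU_FLOOR)
        return -_nb_grad_beta(y, mu, theta, X)

    cons = [{"type": "ineq",
             "fun": lambda b: X @ b - _MU_FLOOR,
             "jac": lambda b: X}]
    res = optimize.minimize(negll, beta0, jac=jac, method="SLSQP",
                            constraints=cons,
                            options={"maxiter": 200, "ftol": 1e-10})
    return res.x, -res.fun, res.success


def _init_beta(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares start, pulled inside the feasible cone if needed."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mu = X @ beta
    if np.all(mu > 0):
        return beta
    # shrink towards the flat fit at the observed mean, which is feasible
    flat = np.zeros_like(beta)
    flat[0] = max(y.mean(), 1.0)
    for lam in np.linspace(0.9, 0.0, 10):
        cand = lam * beta + (1 - lam) * flat
        if np.all(X @ cand > 0):
            return cand
    return flat


def fit_poisson_identity(counts, exog, names=None) -> NbFit:
    """Identity-link Poisson fit (the dispersion -> infinity limit)."""
    return fit_nb_identity(counts, exog, names=names, theta=np.inf)


def _profile_theta(y, X, beta_start, lo=np.log(0.5), hi=np.log(1e6)):
    """Outer profile of log(theta); returns (log_theta, beta, ll)."""
    cache = {}

    def prof(lt):
        theta = np.exp(lt)
        key = round(lt, 10)
        if key not in cache:
            beta, ll, ok = _fit_beta(y, X, theta, prof.beta)
            if ok:
                prof.beta = beta
            cache[key] = (beta, ll)
        return -cache[key][1]

    prof.beta = beta_start
    res = optimize.minimize_scalar(prof, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-3})
    lt = float(res.x)
    beta, ll = cache[round(lt, 10)]
    return lt, beta, ll


def fit_nb_identity(counts, exog, names: list[str] | None = None,
                    theta: float | None = None) -> NbFit:
    """Constrained ML fit of the identity-link NB model.

    Parameters
    ----------
    counts : array of nonnegative integers, one per child.
    exog : design matrix including the intercept column, or a DataFrame of
        covariates (an intercept is then prepended).
    theta : fix the dispersion instead of profiling it; ``numpy.inf``
        selects the Poisson limit.

    Raises
    ------
    RuntimeError on non-convergence, with optimizer diagnostics.
    """
    y = np.asarray(counts, dtype=float)
    if isinstance(exog, pd.DataFrame):
        cols = list(exog.columns)
        X = build_design(exog, cols)
        names = ["intercept"] + cols
    else:
        X = np.asarray(exog, dtype=float)
        if names is None:
            names = ["intercept"] + [f"x{i}" for i in range(1, X.shape[1])]
    n, p = X.shape
    if np.any(y < 0) or not np.all(np.isfinite(X)):
        raise ValueError("counts must be nonnegative and covariates finite")
    if n <= p:
        raise ValueError("need more observations than parameters")

    beta0 = _init_beta(y, X)
    if theta is not None:
        beta, ll, ok = _fit_beta(y, X, theta, beta0)
        theta_hat = float(theta)
        if not ok:
            # one polished retry from the flat start
            beta, ll, ok = _fit_beta(y, X, theta, _init_beta(y, X * 0 + X))
        if not ok:
            raise RuntimeError("identity-link fit did not converge "
                               f"(fixed theta={theta})")
    else:
        # Poisson-style start for the profile
        beta_p, _, _ = _fit_beta(y, X, np.inf, beta0)
        lt, beta, ll = _profile_theta(y, X, beta_p)
        theta_hat = float(np.exp(lt))
        ok = True

    mu = np.maximum(X @ beta, _MU_FLOOR)
    boundary = bool(np.any(X @ beta < 1e-6 * (1 + np.abs(y).mean())))

    var = mu + (0.0 if np.isinf(theta_hat) else mu**2 / theta_hat)
    se, pvals = _wald(y, X, beta, theta_hat)
    pearson = (y - mu) / np.sqrt(var)
    leverage = _leverage(X, var)

    ll_null, _ = _null_loglik(y, theta=theta_hat if theta is not None else None)
    pseudo = 1.0 - ll / ll_null if ll_null != 0 else np.nan

    return NbFit(params=beta, se=se, pvalues=pvals, names=list(names),
                 theta=theta_hat, loglik=ll, null_loglik=ll_null,
                 pseudo_r2=float(pseudo), fitted=mu, pearson_resid=pearson,
                 leverage=leverage, nobs=n, nparams=p, converged=bool(ok),
                 boundary=boundary,
                 family="poisson" if np.isinf(theta_hat)
                 else "negative-binomial")


def _null_loglik(y: np.ndarray, theta: float | None) -> tuple[float, float]:
    """Intercept-only fit: the ML mean is ybar (equal weights), dispersion
    profiled unless fixed."""
    mu = max(float(y.mean()), _MU_FLOOR)
    if theta is not None:
        return _nb_loglik(y, np.full_like(y, mu), theta), theta

    def negll(lt):
        return -_nb_loglik(y, np.full_like(y, mu), np.exp(lt))

    res = optimize.minimize_scalar(negll, bounds=(np.log(0.5), np.log(1e6)),
                                   method="bounded")
    return -res.fun, float(np.exp(res.x))


def _wald(y, X, beta, theta) -> tuple[np.ndarray, np.ndarray]:
    """Standard errors from the observed information (finite differences of
    the analytic score), two-sided normal p-values."""
    p = len(beta)
    eps = 1e-5 * np.maximum(np.abs(beta), 1.0)
    H = np.zeros((p, p))
    for j in range(p):
        bp = beta.copy(); bp[j] += eps[j]
        bm = beta.copy(); bm[j] -= eps[j]
        gp = _nb_grad_beta(y, np.maximum(X @ bp, _MU_FLOOR), theta, X)
        gm = _nb_grad_beta(y, np.maximum(X @ bm, _MU_FLOOR), theta, X)
        H[:, j] = (gp - gm) / (2 * eps[j])
    H = (H + H.T) / 2
    try:
        cov = np.linalg.inv(-H)
        var = np.diag(cov).copy()
        var[var < 0] = np.nan
        se = np.sqrt(var)
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    return se, pvals


def _leverage(X: np.ndarray, var: np.ndarray) -> np.ndarray:
    """Diagonal of the weighted hat matrix H = W^.5 X (X'WX)^-1 X' W^.5
    with W = 1/Var (identity link: d mu/d eta = 1)."""
    w = 1.0 / var
    Xw = X * np.sqrt(w)[:, None]
    try:
        XtX_inv = np.linalg.inv(Xw.T @ Xw)
    except np.linalg.LinAlgError:
        XtX_inv = np.linalg.pinv(Xw.T @ Xw)
    return np.einsum("ij,jk,ik->i", Xw, XtX_inv, Xw)


# ---------------------------------------------------------------------------

def fit_phased_models(paternal_counts, paternal_ages,
                      maternal_counts, maternal_ages
                      ) -> tuple[NbFit, NbFit]:
    """Single-covariate identity-link NB fits of phased mutation counts:
    E(Y_paternal) = b0 + b1 * paternal_age and likewise maternally.

    A degenerate response (all counts equal, e.g. all zero) is flagged via
    ``converged=False`` rather than raising.
    """
    fits = []
    for cnt, age in ((paternal_counts, paternal_ages),
                     (maternal_counts, maternal_ages)):
        cnt = np.asarray(cnt, dtype=float)
        X = np.column_stack([np.ones_like(cnt), np.asarray(age, dtype=float)])
        if np.all(cnt == cnt[0]):
            fit = NbFit(params=np.array([cnt[0], 0.0]),
                        se=np.full(2, np.nan), pvalues=np.full(2, np.nan),
                        names=["intercept", "age"], theta=np.inf,
                        loglik=np.nan, null_loglik=np.nan, pseudo_r2=np.nan,
                        fitted=np.full_like(cnt, max(cnt[0], _MU_FLOOR)),
                        pearson_resid=np.zeros_like(cnt),
                        leverage=np.zeros_like(cnt), nobs=len(cnt),
                        nparams=2, converged=False, boundary=True)
        else:
            fit = fit_nb_identity(cnt, X, names=["intercept", "age"])
        fits.append(fit)
    return fits[0], fits[1]


def slope_ratio(fit_pat: NbFit, fit_mat: NbFit) -> float:
    """Paternal / maternal per-year slope ratio, rounded to one decimal."""
    b_pat = fit_pat.params[1]
    b_mat = fit_mat.params[1]
    if b_mat <= 0:
        raise ValueError("maternal slope must be positive")
    if b_pat <= 0:
        raise ValueError("paternal slope must be positive")
    return round(float(b_pat / b_mat), 1)


def fit_with_carrier_covariates(counts, table: pd.DataFrame,
                                qc_columns: list[str],
                                n_regressions: int = 8,
                                alpha: float = 0.05,
                                standardize_qc: bool = True
                                ) -> tuple[NbFit, dict]:
    """Age + QC + hypermutation-excess model with parental rare-variant
    carrier indicators (``paternal_carrier``, ``maternal_carrier``).

    ``table`` must contain father_age, mother_age, hm_excess, the QC
    columns, and the two 0/1 carrier columns.  Returns the fit plus a
    report with per-carrier Wald tests at the Bonferroni threshold
    ``alpha / n_regressions`` (several gene-set regressions are run in the
    study design, hence the external count).  All-zero carrier columns are
    dropped and reported as inestimable.
    """
    work = table.copy()
    if standardize_qc:
        for c in qc_columns:
            s = work[c].std()
            work[c] = (work[c] - work[c].mean()) / (s if s > 0 else 1.0)
    candidates = (["father_age", "mother_age"] + qc_columns
                  + ["hm_excess", "paternal_carrier", "maternal_carrier"])
    cols, dropped = [], []
    for c in candidates:
        # constant columns (e.g. no carriers, no hypermutators) make the
        # information matrix singular and their effects inestimable
        if work[c].std() == 0:
            dropped.append(c)
        else:
            cols.append(c)
    fit = fit_nb_identity(np.asarray(counts), work[cols])
    fit.dropped = dropped
    threshold = alpha / n_regressions
    report = {"bonferroni_threshold": threshold, "carriers": {}}
    for carrier in ("paternal_carrier", "maternal_carrier"):
        if carrier in dropped:
            report["carriers"][carrier] = {"estimable": False}
        else:
            i = fit.names.index(carrier)
            report["carriers"][carrier] = {
                "estimable": True,
                "coef": float(fit.params[i]),
                "se": float(fit.se[i]),
                "p": float(fit.pvalues[i]),
                "significant": bool(fit.pvalues[i] < threshold),
            }
    return fit, report
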