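"""Maximum-likelihood one-factor structural equation models.

Two model classes cover the measurement and the association stages of a
latent-factor multi-trait GWAS:

``OneFactorModel``
    Confirmatory factor analysis of p observed indicators (here the four
    symptom-category scores) with a single common factor:
    Sigma(theta) = gamma gamma' + diag(delta), latent variance fixed to 1.
    Fitted by minimising the Wishart ML discrepancy
    F = log|Sigma| + tr(S Sigma^-1) - log|S| - p.

``LatentRegressionModel``
    The same measurement model with exogenous predictors (a SNP dosage and
    covariates) regressing on the latent factor:
    y_i | x_i ~ N(gamma * (b'x_i), gamma gamma' + diag(delta)),
    with the latent *residual* variance fixed to 1 for identification, so b
    is on the latent-residual-SD scale.  The per-variant GWAS effect is the
    dosage entry of b with a Wald test from the observed information.

Both expose statsmodels-style ``fit()`` returning a Results object with
estimates, standard errors, fit statistics and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

_LOG2PI = np.log(2.0 * np.pi)
_DELTA_FLOOR = 1e-6


class EstimationError(RuntimeError):
    """Optimiser failed to reach a stationary point after restarts."""


def _projected_grad_ok(result, bounds, scale: float, tol: float = 1e-6) -> bool:
    """Accept a solution the line search gave up on if the projected
    gradient is negligible relative to the likelihood scale (~n)."""
    grad = np.asarray(result.jac, dtype=float).copy()
    for i, (lo, hi) in enumerate(bounds):
        if lo is not None and result.x[i] <= lo + 1e-12 and grad[i] > 0:
            grad[i] = 0.0
        if hi is not None and result.x[i] >= hi - 1e-12 and grad[i] < 0:
            grad[i] = 0.0
    return bool(np.abs(grad).max() < tol * max(scale, 1.0))


class MonomorphicVariantError(ValueError):
    """Dosage vector has zero variance; the variant model is unidentified."""


# ---------------------------------------------------------------------------
# fit-statistic helpers


def chi2_pvalue(statistic: float, df: int) -> float:
    """Upper-tail p-value of a central chi-square statistic."""
    if statistic < 0:
        raise ValueError("chi-square statistic must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.sf(statistic, df))


def rmsea_with_ci(
    chi_square: float,
    df: int,
    n_obs: int,
    confidence: float = 0.90,
) -> tuple[float, float, float]:
    """RMSEA point estimate with a noncentrality-based confidence interval.

    estimate = sqrt(max(chi2 - df, 0) / (df * (n_obs - 1))); the CI inverts
    the noncentral chi-square at the (1 +/- confidence)/2 tail levels and
    maps the noncentrality lambda through sqrt(lambda / (df * (n_obs - 1))).
    """
    if df < 1 or n_obs < 2:
        raise ValueError("df >= 1 and n_obs >= 2 required")
    denom = df * (n_obs - 1)
    est = float(np.sqrt(max(chi_square - df, 0.0) / denom))

    def _invert(target: float) -> float:
        # find lambda >= 0 with ncx2.cdf(chi2, df, lambda) == target
        if stats.ncx2.cdf(chi_square, df, 1e-12) <= target:
            return 0.0
        hi = max(chi_square, 1.0)
        while stats.ncx2.cdf(chi_square, df, hi) > target:
            hi *= 2.0
            if hi > 1e8:  # pragma: no cover - pathological statistic
                return hi
        return float(
            optimize.brentq(
                lambda lam: stats.ncx2.cdf(chi_square, df, lam) - target,
                1e-12,
                hi,
                xtol=1e-10,
            )
        )

    alpha = (1.0 - confidence) / 2.0
    lam_lower = _invert(1.0 - alpha)
    lam_upper = _invert(alpha)
    lower = float(np.sqrt(max(lam_lower, 0.0) / denom))
    upper = float(np.sqrt(max(lam_upper, 0.0) / denom))
    return est, lower, upper


# ---------------------------------------------------------------------------
# one-factor covariance-structure model


def _implied_sigma(gamma: np.ndarray, delta: np.ndarray) -> np.ndarray:
    return np.outer(gamma, gamma) + np.diag(delta)


def _start_values(S: np.ndarray) -> np.ndarray:
    """First-principal-component start: gamma = sqrt(l1) v1, delta residual."""
    vals, vecs = linalg.eigh(S)
    v1 = vecs[:, -1]
    if v1.sum() < 0:
        v1 = -v1
    gamma0 = np.sqrt(max(vals[-1], 1e-3)) * v1
    delta0 = np.clip(np.diag(S) - gamma0**2, 0.05, None)
    return np.concatenate([gamma0, delta0])


@dataclass
class OneFactorResults:
    """Estimates and fit statistics of a fitted one-factor model."""

    model: "OneFactorModel"
    loadings: np.ndarray
    residual_variances: np.ndarray
    loadings_se: np.ndarray
    residual_se: np.ndarray
    chi_square: float
    df: int
    loglik: float
    n_obs: int
    converged: bool
    heywood: bool
    n_restarts: int

    @property
    def pvalue(self) -> float:
        return chi2_pvalue(self.chi_square, self.df)

    def rmsea(self, confidence: float = 0.90) -> tuple[float, float, float]:
        return rmsea_with_ci(self.chi_square, self.df, self.n_obs, confidence)

    @property
    def implied_cov(self) -> np.ndarray:
        return _implied_sigma(self.loadings, self.residual_variances)

    def params_vector(self) -> np.ndarray:
        return np.concatenate([self.loadings, self.residual_variances])

    def summary(self) -> str:
        rms, lo, hi = self.rmsea()
        lines = [
            "One-factor measurement model (ML, latent variance fixed to 1)",
            f"  n_obs = {self.n_obs}, indicators = {len(self.loadings)}",
            f"  chi-square = {self.chi_square:.3f}  df = {self.df}  "
            f"p = {self.pvalue:.3g}",
            f"  RMSEA = {rms:.3f}  (90% CI {lo:.3f}-{hi:.3f})",
            f"  loglik = {self.loglik:.3f}   converged = {self.converged}"
            + ("   [Heywood case]" if self.heywood else ""),
            "",
            f"  {'indicator':<16}{'loading':>10}{'SE':>9}"
            f"{'resid var':>12}{'SE':>9}",
        ]
        for k, name in enumerate(self.model.endog_names):
            lines.append(
                f"  {name:<16}{self.loadings[k]:>10.4f}"
                f"{self.loadings_se[k]:>9.4f}"
                f"{self.residual_variances[k]:>12.4f}"
                f"{self.residual_se[k]:>9.4f}"
            )
        return "\n".join(lines)


class OneFactorModel:
    """Single-common-factor covariance-structure model for p indicators.

    Build either from raw data (``OneFactorModel(df)``) or directly from a
    covariance matrix (``OneFactorModel.from_covariance(S, n_obs)``).
    Complete cases only; the latent variance is fixed to 1 so loadings are
    on the indicator scale.
    """

    def __init__(self, endog: pd.DataFrame | np.ndarray):
        endog = pd.DataFrame(endog)
        endog = endog.dropna()
        if len(endog) < 50:
            raise ValueError(
                f"need >= 50 complete cases, got {len(endog)}"
            )
        self.endog_names = [str(c) for c in endog.columns]
        self.n_obs = len(endog)
        # ML discrepancy convention: S with denominator n-1, chi2 = (n-1) F
        self.sample_cov = np.cov(endog.to_numpy(dtype=float), rowvar=False, ddof=1)
        self._validate()

    @classmethod
    def from_covariance(
        cls,
        cov: np.ndarray,
        n_obs: int,
        names: list[str] | None = None,
    ) -> "OneFactorModel":
        obj = cls.__new__(cls)
        cov = np.asarray(cov, dtype=float)
        obj.sample_cov = cov
        obj.n_obs = int(n_obs)
        obj.endog_names = names or [f"y{k + 1}" for k in range(cov.shape[0])]
        obj._validate()
        return obj

    def _validate(self) -> None:
        S = self.sample_cov
        if S.shape[0] != S.shape[1] or not np.allclose(S, S.T):
            raise ValueError("covariance matrix must be square symmetric")
        sign, self._logdet_S = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError("sample covariance is not positive definite")
        self.k_endog = S.shape[0]

    # -- ML discrepancy and gradient -------------------------------------

    def discrepancy(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        """F_ML(gamma, delta) and its analytic gradient."""
        p = self.k_endog
        gamma, delta = params[:p], params[p:]
        sigma = _implied_sigma(gamma, delta)
        try:
            c, low = linalg.cho_factor(sigma)
        except linalg.LinAlgError:
            return np.inf, np.zeros_like(params)
        omega = linalg.cho_solve((c, low), np.eye(p))
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        F = logdet + np.sum(omega * self.sample_cov) - self._logdet_S - p
        A = omega - omega @ self.sample_cov @ omega
        grad = np.concatenate([2.0 * A @ gamma, np.diag(A)])
        return float(F), grad

    def fit(
        self,
        start_params: np.ndarray | None = None,
        maxiter: int = 500,
        n_restarts: int = 5,
        gtol: float = 1e-8,
    ) -> OneFactorResults:
        p = self.k_endog
        theta0 = (
            np.asarray(start_params, dtype=float)
            if start_params is not None
            else _start_values(self.sample_cov)
        )
        bounds = [(None, None)] * p + [(_DELTA_FLOOR, None)] * p
        rng = np.random.default_rng(0)
        best = None
        used_restarts = 0
        for attempt in range(n_restarts + 1):
            x0 = theta0 if attempt == 0 else theta0 * (
                1.0 + 0.2 * rng.standard_normal(theta0.shape)
            )
            x0[p:] = np.clip(x0[p:], _DELTA_FLOOR, None)
            res = optimize.minimize(
                self.discrepancy,
                x0,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-14, "gtol": gtol},
            )
            if best is None or res.fun < best.fun:
                best = res
            used_restarts = attempt
            if res.success and res.fun < np.inf:
                break
        if best is None or not np.isfinite(best.fun):
            raise EstimationError("one-factor ML fit failed to converge")
        converged = bool(best.success) or _projected_grad_ok(
            best, bounds, scale=self.n_obs
        )
        gamma = best.x[:p].copy()
        delta = best.x[p:].copy()
        if gamma[0] < 0 or (gamma[0] == 0 and gamma.sum() < 0):
            gamma = -gamma  # factor sign indeterminacy: report gamma_1 >= 0
        heywood = bool(np.any(delta <= _DELTA_FLOOR * (1 + 1e-9)))
        se = self._standard_errors(gamma, delta)
        F = float(best.fun)
        chi_square = max((self.n_obs - 1) * F, 0.0)
        df = p * (p + 1) // 2 - 2 * p
        loglik = -0.5 * (self.n_obs - 1) * (
            F + self._logdet_S + p + p * _LOG2PI
        )
        return OneFactorResults(
            model=self,
            loadings=gamma,
            residual_variances=delta,
            loadings_se=se[:p],
            residual_se=se[p:],
            chi_square=chi_square,
            df=df,
            loglik=float(loglik),
            n_obs=self.n_obs,
            converged=converged,
            heywood=heywood,
            n_restarts=used_restarts,
        )

    def _standard_errors(self, gamma: np.ndarray, delta: np.ndarray) -> np.ndarray:
        """SEs from the inverse expected information of the covariance model."""
        p = self.k_endog
        sigma = _implied_sigma(gamma, delta)
        omega = linalg.inv(sigma)
        derivs = []
        eye = np.eye(p)
        for a in range(p):
            derivs.append(np.outer(eye[a], gamma) + np.outer(gamma, eye[a]))
        for j in range(p):
            derivs.append(np.outer(eye[j], eye[j]))
        m = len(derivs)
        J = np.empty((m, m))
        cache = [omega @ d for d in derivs]
        for i in range(m):
            for j in range(i, m):
                J[i, j] = J[j, i] = np.sum(cache[i] * cache[j].T)
        info = 0.5 * (self.n_obs - 1) * J
        try:
            cov = linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except linalg.LinAlgError:  # boundary solutions
            se = np.full(m, np.nan)
        return se


def fit_one_factor(
    categories: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> OneFactorResults | "LatentRegressionResults":
    """Fit the one-common-factor measurement model to the category table.

    With ``covariates`` the latent factor is additionally regressed on them
    (conditional-Gaussian ML); without, the pure covariance-structure model
    is fitted.
    """
    if covariates is None:
        return OneFactorModel(categories).fit()
    model = LatentRegressionModel(categories, covariates)
    return model.fit()


# ---------------------------------------------------------------------------
# latent regression (SNP + covariates -> latent factor)


@dataclass
class LatentRegressionResults:
    """ML estimates for the latent-factor model with exogenous predictors."""

    model: "LatentRegressionModel"
    loadings: np.ndarray
    residual_variances: np.ndarray
    exog_effects: np.ndarray
    bse: np.ndarray  # full parameter vector order: gamma, delta, b
    loglik: float
    chi_square: float
    df: int
    n_obs: int
    converged: bool
    heywood: bool

    @property
    def exog_se(self) -> np.ndarray:
        p = len(self.loadings)
        return self.bse[2 * p:]

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.exog_effects / self.exog_se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def effect(self, name: str) -> tuple[float, float, float, float]:
        """(beta, se, z, p) for one named exogenous predictor."""
        i = self.model.exog_names.index(name)
        return (
            float(self.exog_effects[i]),
            float(self.exog_se[i]),
            float(self.zvalues[i]),
            float(self.pvalues[i]),
        )

    def params_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.loadings, self.residual_variances, self.exog_effects]
        )

    def summary(self) -> str:
        lines = [
            "Latent-factor regression model (ML, latent residual variance = 1)",
            f"  n_obs = {self.n_obs}   loglik = {self.loglik:.3f}   "
            f"converged = {self.converged}",
            f"  chi-square vs saturated = {self.chi_square:.3f}  df = {self.df}",
            "",
            f"  {'predictor -> latent':<22}{'beta':>10}{'SE':>9}"
            f"{'z':>8}{'p':>12}",
        ]
        for i, name in enumerate(self.model.exog_names):
            lines.append(
                f"  {name:<22}{self.exog_effects[i]:>10.4f}"
                f"{self.exog_se[i]:>9.4f}{self.zvalues[i]:>8.2f}"
                f"{self.pvalues[i]:>12.3e}"
            )
        lines.append("")
        p = len(self.loadings)
        lines.append(f"  {'indicator':<22}{'loading':>10}{'SE':>9}{'resid var':>12}")
        for k, name in enumerate(self.model.endog_names):
            lines.append(
                f"  {name:<22}{self.loadings[k]:>10.4f}"
                f"{self.bse[k]:>9.4f}{self.residual_variances[k]:>12.4f}"
            )
        return "\n".join(lines)


class LatentRegressionModel:
    """One-factor model whose latent variable is regressed on predictors.

    endog: n x p indicator table; exog: n x k predictors (dosage first by
    convention in the GWAS driver).  Both are mean-centred internally, which
    saturates the mean structure; complete cases only.  The conditional
    likelihood depends on the data only through Y'Y, Y'X and X'X, so the
    per-evaluation cost is independent of n.
    """

    def __init__(
        self,
        endog: pd.DataFrame | np.ndarray,
        exog: pd.DataFrame | np.ndarray,
    ):
        endog = pd.DataFrame(endog)
        exog = pd.DataFrame(exog)
        if len(endog) != len(exog):
            raise ValueError("endog and exog must have the same rows")
        joined = pd.concat([endog, exog], axis=1).dropna()
        Y = joined.iloc[:, : endog.shape[1]].to_numpy(dtype=float)
        X = joined.iloc[:, endog.shape[1]:].to_numpy(dtype=float)
        if np.any(X.std(axis=0) <= 0):
            zero = [
                str(exog.columns[i])
                for i in np.flatnonzero(X.std(axis=0) <= 0)
            ]
            raise MonomorphicVariantError(
                f"zero-variance exogenous column(s): {zero}"
            )
        self.endog_names = [str(c) for c in endog.columns]
        self.exog_names = [str(c) for c in exog.columns]
        self.n_obs, self.k_endog = Y.shape
        self.k_exog = X.shape[1]
        Y = Y - Y.mean(axis=0)
        X = X - X.mean(axis=0)
        self.syy = Y.T @ Y
        self.syx = Y.T @ X
        self.sxx = X.T @ X

    # -- likelihood ------------------------------------------------------

    def nloglik(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        """Negative conditional log-likelihood and analytic gradient."""
        p, k, n = self.k_endog, self.k_exog, self.n_obs
        gamma, delta, b = params[:p], params[p: 2 * p], params[2 * p:]
        sigma = _implied_sigma(gamma, delta)
        try:
            c, low = linalg.cho_factor(sigma)
        except linalg.LinAlgError:
            return np.inf, np.zeros_like(params)
        omega = linalg.cho_solve((c, low), np.eye(p))
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        u = self.syx @ b  # p-vector
        q = float(b @ self.sxx @ b)
        M = (
            self.syy
            - np.outer(u, gamma)
            - np.outer(gamma, u)
            + q * np.outer(gamma, gamma)
        )
        nll = 0.5 * (n * logdet + np.sum(omega * M) + n * p * _LOG2PI)
        A = 0.5 * n * omega - 0.5 * omega @ M @ omega
        og = omega @ gamma
        grad_gamma = 2.0 * A @ gamma - omega @ u + q * og
        grad_delta = np.diag(A)
        grad_b = -self.syx.T @ og + float(gamma @ og) * (self.sxx @ b)
        return float(nll), np.concatenate([grad_gamma, grad_delta, grad_b])

    def _saturated_loglik(self) -> float:
        p, n = self.k_endog, self.n_obs
        R = self.syy - self.syx @ linalg.solve(
            self.sxx, self.syx.T, assume_a="pos"
        )
        sign, logdet = np.linalg.slogdet(R / n)
        return -0.5 * n * (logdet + p + p * _LOG2PI)

    def start_params(self) -> np.ndarray:
        S = self.syy / (self.n_obs - 1)
        theta_meas = _start_values(S)
        return np.concatenate([theta_meas, np.zeros(self.k_exog)])

    def fit(
        self,
        start_params: np.ndarray | None = None,
        maxiter: int = 500,
        n_restarts: int = 5,
        gtol: float = 1e-8,
        compute_se: bool = True,
    ) -> LatentRegressionResults:
        p, k = self.k_endog, self.k_exog
        theta0 = (
            np.asarray(start_params, dtype=float)
            if start_params is not None
            else self.start_params()
        )
        bounds = (
            [(None, None)] * p + [(_DELTA_FLOOR, None)] * p + [(None, None)] * k
        )
        rng = np.random.default_rng(0)
        best = None
        for attempt in range(n_restarts + 1):
            x0 = theta0 if attempt == 0 else theta0 + 0.2 * rng.standard_normal(
                theta0.shape
            )
            x0[p: 2 * p] = np.clip(x0[p: 2 * p], _DELTA_FLOOR, None)
            res = optimize.minimize(
                self.nloglik,
                x0,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-14, "gtol": gtol},
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success and np.isfinite(res.fun):
                break
        if best is None or not np.isfinite(best.fun):
            raise EstimationError("latent regression ML fit failed")
        converged = bool(best.success) or _projected_grad_ok(
            best, bounds, scale=self.n_obs
        )
        theta = best.x.copy()
        if theta[0] < 0:
            # flip factor sign: loadings and latent-regression effects together
            theta[:p] = -theta[:p]
            theta[2 * p:] = -theta[2 * p:]
        heywood = bool(np.any(theta[p: 2 * p] <= _DELTA_FLOOR * (1 + 1e-9)))
        bse = (
            self._observed_info_se(theta)
            if compute_se
            else np.full(theta.shape, np.nan)
        )
        loglik = -float(best.fun)
        chi_square = max(2.0 * (self._saturated_loglik() - loglik), 0.0)
        df = (p * k + p * (p + 1) // 2) - (2 * p + k)
        return LatentRegressionResults(
            model=self,
            loadings=theta[:p],
            residual_variances=theta[p: 2 * p],
            exog_effects=theta[2 * p:],
            bse=bse,
            loglik=loglik,
            chi_square=chi_square,
            df=df,
            n_obs=self.n_obs,
            converged=converged,
            heywood=heywood,
        )

    def _observed_info_se(self, theta: np.ndarray) -> np.ndarray:
        """SEs from the observed information (central differences of the
        analytic gradient)."""
        m = theta.size
        H = np.empty((m, m))
        for i in range(m):
            h = 1e-5 * max(1.0, abs(theta[i]))
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            _, gp = self.nloglik(tp)
            _, gm = self.nloglik(tm)
            H[i] = (gp - gm) / (2.0 * h)
        H = 0.5 * (H + H.T)
        try:
            cov = linalg.inv(H)
            return np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except linalg.LinAlgError:
            return np.full(m, np.nan)


def fit_variant_model(
    categories: pd.DataFrame,
    dosage: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    start_params: np.ndarray | None = None,
) -> LatentRegressionResults:
    """Per-variant latent-mediated association fit.

    The SNP dosage (and covariates, if given) predict the latent factor
    behind the four category scores; ``results.effect("dosage")`` is the
    GWAS (beta, se, z, p).
    """
    dosage = np.asarray(dosage, dtype=float)
    if dosage.ndim != 1 or dosage.size != len(categories):
        raise ValueError("dosage must be a vector matching the subjects")
    exog = pd.DataFrame({"dosage": dosage}, index=categories.index)
    if covariates is not None:
        exog = pd.concat([exog, covariates], axis=1)
    model = LatentRegressionModel(categories, exog)
    return model.fit(start_params=start_params)
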