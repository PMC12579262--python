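"""One-factor confirmatory model for cognitive test batteries.

General cognitive function (g) is modelled as a single latent factor with
variance fixed to 1: observed test scores satisfy
``x = mu + lambda * g + e`` with ``Var(e) = diag(psi)``, implied covariance
``Sigma = lambda lambda' + diag(psi)``.  Estimation is casewise maximum
likelihood, which is full-information ML (FIML) in the presence of missing
data; listwise deletion followed by the same casewise likelihood gives
complete-case ML.  Factor scores use the regression (Thomson) method, and
are oriented so higher scores mean better performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "OneFactorModel",
    "OneFactorResults",
    "fit_indices",
    "ConvergenceError",
    "IdentificationError",
]


class IdentificationError(ValueError):
    """The model is not identified for the given battery."""


class ConvergenceError(RuntimeError):
    """Optimization failed; carries the objective trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# Casewise (FIML) likelihood machinery
# ---------------------------------------------------------------------------

def _patterns(data: np.ndarray):
    """Group rows by missingness pattern; drop all-missing rows."""
    obs = np.isfinite(data)
    keep = obs.any(axis=1)
    data = data[keep]
    obs = obs[keep]
    out = []
    codes = obs @ (1 << np.arange(obs.shape[1]))
    for code in np.unique(codes):
        rows = codes == code
        o = np.flatnonzero(obs[rows][0])
        out.append((o, data[np.ix_(rows, o)]))
    return out


def _neg2_loglik_and_grad(theta: np.ndarray, patterns, p: int):
    mu = theta[:p]
    lam = theta[p : 2 * p]
    psi = np.exp(theta[2 * p :])
    sigma = np.outer(lam, lam) + np.diag(psi)

    f = 0.0
    g_sigma = np.zeros((p, p))
    g_mu = np.zeros(p)
    for o, block in patterns:
        m = block.shape[0]
        sub = sigma[np.ix_(o, o)]
        chol = np.linalg.cholesky(sub)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        d = block - mu[o]
        z = np.linalg.solve(chol, d.T)          # chol^-1 d'
        quad = float(np.sum(z * z))
        f += m * (len(o) * np.log(2 * np.pi) + logdet) + quad
        inv = np.linalg.inv(sub)
        s_star = d.T @ d
        gs = m * inv - inv @ s_star @ inv
        g_sigma[np.ix_(o, o)] += gs
        g_mu[o] += -2.0 * inv @ d.sum(axis=0)

    g_lam = 2.0 * g_sigma @ lam
    g_psi = np.diag(g_sigma) * psi              # chain rule through log psi
    return f, np.concatenate([g_mu, g_lam, g_psi])


def _saturated_em(data: np.ndarray, tol: float = 1e-10, max_iter: int = 2000):
    """ML (mu, Sigma) of a multivariate normal with missing data, via EM."""
    obs = np.isfinite(data)
    data = data[obs.any(axis=1)]
    obs = np.isfinite(data)
    n, p = data.shape
    mu = np.nanmean(data, axis=0)
    filled = np.where(obs, data, mu)
    sigma = np.cov(filled, rowvar=False, ddof=0) + 1e-6 * np.eye(p)
    if np.all(obs):
        return mu, np.cov(data, rowvar=False, ddof=0)
    patterns = {}
    codes = obs @ (1 << np.arange(p))
    for code in np.unique(codes):
        rows = np.flatnonzero(codes == code)
        patterns[code] = (np.flatnonzero(obs[rows[0]]), rows)
    for _ in range(max_iter):
        ex = np.zeros((n, p))
        exx = np.zeros((p, p))
        for o, rows in patterns.values():
            miss = np.setdiff1d(np.arange(p), o)
            x_o = data[np.ix_(rows, o)]
            if miss.size == 0:
                ex[rows] = x_o
                exx += x_o.T @ x_o
                continue
            s_oo = sigma[np.ix_(o, o)]
            s_mo = sigma[np.ix_(miss, o)]
            reg = s_mo @ np.linalg.inv(s_oo)
            cond_mean = mu[miss] + (x_o - mu[o]) @ reg.T
            cond_cov = sigma[np.ix_(miss, miss)] - reg @ s_mo.T
            ex[np.ix_(rows, o)] = x_o
            ex[np.ix_(rows, miss)] = cond_mean
            block = np.zeros((p, p))
            block[np.ix_(o, o)] = x_o.T @ x_o
            block[np.ix_(o, miss)] = x_o.T @ cond_mean
            block[np.ix_(miss, o)] = block[np.ix_(o, miss)].T
            block[np.ix_(miss, miss)] = cond_mean.T @ cond_mean + len(rows) * cond_cov
            exx += block
        mu_new = ex.mean(axis=0)
        sigma_new = exx / n - np.outer(mu_new, mu_new)
        delta = max(np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max())
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            break
    return mu, sigma


def _gaussian_loglik(data: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    total = 0.0
    for o, block in _patterns(data):
        m = block.shape[0]
        sub = sigma[np.ix_(o, o)]
        chol = np.linalg.cholesky(sub)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        d = block - mu[o]
        z = np.linalg.solve(chol, d.T)
        total += -0.5 * (m * (len(o) * np.log(2 * np.pi) + logdet) + np.sum(z * z))
    return total


# ---------------------------------------------------------------------------
# Fit indices
# ---------------------------------------------------------------------------

def fit_indices(
    chi2_model: float,
    df_model: int,
    chi2_baseline: float,
    df_baseline: int,
    n_subjects: int,
    srmr: float,
) -> dict[str, float]:
    """CFI, TLI, RMSEA from chi-square statistics (SRMR passed through).

    CFI = 1 - max(chi2_m - df_m, 0) / max(chi2_b - df_b, chi2_m - df_m, 0);
    TLI from chi2/df ratios; RMSEA = sqrt(max(chi2_m - df_m, 0) /
    (df_m (n - 1))).
    """
    if n_subjects <= 1:
        raise ValueError("n_subjects must exceed 1")
    dm = chi2_model - df_model
    db = chi2_baseline - df_baseline
    denom = max(db, dm, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(dm, 0.0) / denom
    cfi = float(np.clip(cfi, 0.0, 1.0))
    if df_model > 0 and df_baseline > 0 and chi2_baseline / df_baseline != 1.0:
        tli = (chi2_baseline / df_baseline - chi2_model / df_model) / (
            chi2_baseline / df_baseline - 1.0
        )
    else:
        tli = 1.0
    rmsea = (
        float(np.sqrt(max(dm, 0.0) / (df_model * (n_subjects - 1))))
        if df_model > 0
        else 0.0
    )
    return {"CFI": cfi, "TLI": float(tli), "RMSEA": rmsea, "SRMR": float(srmr)}


def _srmr(sample_cov: np.ndarray, implied: np.ndarray) -> float:
    d = np.sqrt(np.diag(sample_cov))
    resid = (sample_cov - implied) / np.outer(d, d)
    iu = np.triu_indices_from(resid)
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class OneFactorModel:
    """One-factor measurement model over a battery of test scores.

    Parameters
    ----------
    test_scores : DataFrame or (n, p) array
        Missing entries as NaN.
    estimator : {"fiml", "complete_case"}
        "fiml" uses every observed entry casewise; "complete_case" first
        drops subjects with any missing test.
    """

    MIN_TESTS = 3
    MIN_SUBJECTS = 50

    def __init__(self, test_scores, estimator: str = "fiml"):
        if isinstance(test_scores, pd.DataFrame):
            self.test_names = list(test_scores.columns)
            data = test_scores.to_numpy(dtype=float)
        else:
            data = np.asarray(test_scores, dtype=float)
            self.test_names = [f"test_{j}" for j in range(data.shape[1])]
        if estimator not in ("fiml", "complete_case"):
            raise ValueError("estimator must be 'fiml' or 'complete_case'")
        if data.ndim != 2 or data.shape[1] < self.MIN_TESTS:
            raise IdentificationError(
                "a one-factor model needs at least 3 indicators"
            )
        if estimator == "complete_case":
            data = data[np.isfinite(data).all(axis=1)]
        if data[np.isfinite(data).any(axis=1)].shape[0] < self.MIN_SUBJECTS:
            raise ValueError("need at least 50 subjects with any data")
        self.estimator = estimator
        self.data = data

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, tests: list[str] | None = None, **kw):
        return cls(frame[tests] if tests else frame, **kw)

    def fit(self, maxiter: int = 500, gtol: float = 1e-8) -> "OneFactorResults":
        data = self.data
        n, p = data[np.isfinite(data).any(axis=1)].shape[0], data.shape[1]
        patterns = _patterns(data)

        # start values: principal axis on the pairwise-complete correlations
        frame = pd.DataFrame(data)
        corr = frame.corr(min_periods=2).to_numpy()
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        w, v = np.linalg.eigh(corr)
        lam0 = v[:, -1] * np.sqrt(max(w[-1], 0.5))
        if lam0.mean() < 0:
            lam0 = -lam0
        lam0 = np.clip(lam0, -0.95, 0.95)
        sd = np.sqrt(np.nanvar(data, axis=0, ddof=0))
        sd[~np.isfinite(sd) | (sd == 0)] = 1.0
        lam0 = lam0 * sd
        psi0 = np.clip(sd**2 - lam0**2, 1e-3, None)
        theta0 = np.concatenate([np.nanmean(data, axis=0), lam0, np.log(psi0)])

        trace: list[float] = []

        def objective(theta):
            f, g = _neg2_loglik_and_grad(theta, patterns, p)
            return f, g

        def callback(theta):
            trace.append(_neg2_loglik_and_grad(theta, patterns, p)[0])

        bounds = [(None, None)] * (2 * p) + [(np.log(1e-6), np.log(1e6))] * p
        res = optimize.minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            callback=callback,
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-14},
        )
        grad_norm = float(np.max(np.abs(res.jac)))
        if not res.success and grad_norm > 1e-4:
            raise ConvergenceError(
                f"one-factor fit did not converge: {res.message}", trace
            )

        mu = res.x[:p]
        lam = res.x[p : 2 * p]
        psi = np.exp(res.x[2 * p :])
        if lam.mean() < 0:  # sign convention: mean loading positive
            lam = -lam
        loglik = -0.5 * res.fun

        # saturated and baseline models for chi-square / indices
        mu_sat, sigma_sat = _saturated_em(data)
        ll_sat = _gaussian_loglik(data, mu_sat, sigma_sat)
        sigma_base = np.diag(np.diag(sigma_sat))
        # independence baseline: per-variable ML over observed entries
        mu_base = np.zeros(p)
        var_base = np.zeros(p)
        for j in range(p):
            col = data[:, j]
            col = col[np.isfinite(col)]
            mu_base[j] = col.mean()
            var_base[j] = col.var(ddof=0)
        ll_base = _gaussian_loglik(data, mu_base, np.diag(var_base))

        chi2 = max(2.0 * (ll_sat - loglik), 0.0)
        chi2_base = max(2.0 * (ll_sat - ll_base), 0.0)
        df = p * (p + 1) // 2 - 2 * p
        df_base = p * (p - 1) // 2
        implied = np.outer(lam, lam) + np.diag(psi)
        srmr = _srmr(sigma_sat, implied)
        indices = fit_indices(chi2, df, chi2_base, df_base, n, srmr)

        return OneFactorResults(
            model=self,
            loadings=lam,
            uniquenesses=psi,
            means=mu,
            loglik=loglik,
            chi_square=chi2,
            df=df,
            chi_square_baseline=chi2_base,
            df_baseline=df_base,
            indices=indices,
            n_subjects=n,
            n_iterations=res.nit,
            gradient_norm=grad_norm,
            converged=True,
            objective_trace=trace,
            sample_cov=sigma_sat,
        )


@dataclass
class OneFactorResults:
    """Fitted one-factor model: estimates, fit and factor scoring."""

    model: OneFactorModel
    loadings: np.ndarray
    uniquenesses: np.ndarray
    means: np.ndarray
    loglik: float
    chi_square: float
    df: int
    chi_square_baseline: float
    df_baseline: int
    indices: dict[str, float]
    n_subjects: int
    n_iterations: int
    gradient_norm: float
    converged: bool
    objective_trace: list[float]
    sample_cov: np.ndarray

    factor_variance: float = 1.0

    @property
    def heywood(self) -> np.ndarray:
        """Flag uniquenesses at (or effectively at) the zero boundary."""
        return self.uniquenesses < 1e-4

    @property
    def implied_cov(self) -> np.ndarray:
        return np.outer(self.loadings, self.loadings) + np.diag(self.uniquenesses)

    def factor_scores(self, test_scores=None) -> np.ndarray:
        """Regression-method (Thomson) g scores; NaN for empty subjects.

        For subjects with missing tests, the score uses the observed
        submatrix.  Scores are oriented to correlate positively with the
        per-subject mean of standardized test scores (higher = better).
        """
        if test_scores is None:
            data = self.model.data
        elif isinstance(test_scores, pd.DataFrame):
            data = test_scores.to_numpy(dtype=float)
        else:
            data = np.asarray(test_scores, dtype=float)
        sigma = self.implied_cov
        lam = self.loadings
        n = data.shape[0]
        scores = np.full(n, np.nan)
        obs = np.isfinite(data)
        codes = obs @ (1 << np.arange(data.shape[1]))
        for code in np.unique(codes):
            rows = np.flatnonzero(codes == code)
            o = np.flatnonzero(obs[rows[0]])
            if o.size == 0:
                continue
            weights = np.linalg.solve(sigma[np.ix_(o, o)], lam[o])
            scores[rows] = (data[np.ix_(rows, o)] - self.means[o]) @ weights

        sd = np.sqrt(np.diag(self.sample_cov))
        z = (data - self.means) / sd
        with np.errstate(invalid="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                row_mean = np.nanmean(np.where(obs, z, np.nan), axis=1)
        ok = np.isfinite(scores) & np.isfinite(row_mean)
        if ok.sum() >= 3 and np.std(scores[ok]) > 0 and np.std(row_mean[ok]) > 0:
            if np.corrcoef(scores[ok], row_mean[ok])[0, 1] < 0:
                scores = -scores
        return scores

    def summary(self) -> str:
        lines = [
            "One-factor model (casewise ML)",
            f"  n subjects: {self.n_subjects}   tests: {len(self.loadings)}",
            f"  log-likelihood: {self.loglik:.3f}   chi2({self.df}) = {self.chi_square:.3f}",
            "  "
            + "  ".join(f"{k}={v:.3f}" for k, v in self.indices.items()),
            f"  {'test':<12}{'loading':>10}{'uniqueness':>12}",
        ]
        for name, l, u in zip(self.model.test_names, self.loadings, self.uniquenesses):
            flag = "  (Heywood)" if u < 1e-4 else ""
            lines.append(f"  {name:<12}{l:>10.4f}{u:>12.4f}{flag}")
        return "\n".join(lines)
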