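"""Per-vertex random-effects meta-analysis and FDR control.

Cohort standardized betas are pooled with inverse-variance weights
``1 / (se^2 + tau^2)``; the between-cohort variance tau^2 is estimated by
the DerSimonian-Laird closed form or by a REML fixed-point iteration (both
truncated at zero).  Everything is vectorised over vertices: the per-vertex
arithmetic is identical to the scalar formulas applied in a loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .surface import VertexMap

__all__ = [
    "RandomEffectsMeta",
    "MetaResults",
    "MetaRegression",
    "MetaRegressionResults",
    "meta_random_effects",
    "meta_moderator",
    "fdr_bh",
]


def fdr_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def _dl_tau2(betas, ses, obs=None):
    """DerSimonian-Laird tau2 and Q; ``obs`` masks available cohorts."""
    if obs is None:
        obs = np.ones(betas.shape, dtype=bool)
    w = np.where(obs, 1.0 / np.where(obs, ses, 1.0) ** 2, 0.0)
    b = np.where(obs, betas, 0.0)
    sw = w.sum(axis=0)
    mu_fe = (w * b).sum(axis=0) / sw
    q = (w * np.where(obs, betas - mu_fe, 0.0) ** 2).sum(axis=0)
    k = obs.sum(axis=0)
    c = sw - (w**2).sum(axis=0) / sw
    tau2 = np.maximum(0.0, (q - (k - 1)) / c)
    return tau2, q


def _reml_score(tau2, betas, s2, obs):
    """Restricted-likelihood score in tau2 (zero at the REML estimate)."""
    w = np.where(obs, 1.0 / (np.where(obs, s2, 1.0) + tau2), 0.0)
    sw = w.sum(axis=0)
    mu = (w * np.where(obs, betas, 0.0)).sum(axis=0) / sw
    r = np.where(obs, betas - mu, 0.0)
    w2 = w * w
    return (w2 * r * r).sum(axis=0) - sw + w2.sum(axis=0) / sw


def _reml_tau2(betas, ses, obs=None, tol=1e-12, max_iter=200):
    """REML tau2 by safeguarded bisection on the restricted-likelihood score.

    The score is positive below the optimum and negative above it; tau2 is
    truncated at zero when the score at zero is non-positive.
    """
    if obs is None:
        obs = np.ones(betas.shape, dtype=bool)
    s2 = ses**2
    nv = betas.shape[1]
    tau2 = np.zeros(nv)
    active = _reml_score(tau2, betas, s2, obs) > 0
    if not active.any():
        return tau2
    lo = np.zeros(nv)
    spread = np.where(obs, betas, 0.0).var(axis=0).max()
    hi = np.full(nv, spread + np.where(obs, s2, 0.0).max() + 1.0)
    # expand the bracket where needed
    for _ in range(60):
        bad = active & (_reml_score(hi, betas, s2, obs) > 0)
        if not bad.any():
            break
        hi[bad] *= 2.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        pos = _reml_score(mid, betas, s2, obs) > 0
        lo = np.where(active & pos, mid, lo)
        hi = np.where(active & ~pos, mid, hi)
        if np.max(hi - lo) < tol:
            break
    tau2[active] = (0.5 * (lo + hi))[active]
    return tau2


class RandomEffectsMeta:
    """Random-effects pooling of k cohort estimates, per vertex.

    Parameters
    ----------
    betas, ses : (k,) or (k, V) arrays
        Cohort standardized effect sizes and their standard errors.
    method : {"REML", "DL", "FE"}
        tau^2 estimator ("FE" forces tau^2 = 0).
    knapp_hartung : bool
        Use the Knapp-Hartung variance adjustment and a t reference
        distribution instead of the default Wald z.

    A non-finite beta or SE marks that cohort as missing at that vertex:
    the vertex is pooled over the available cohorts if at least two remain,
    otherwise all outputs are NaN there.
    """

    def __init__(self, betas, ses, method: str = "REML", knapp_hartung: bool = False):
        betas = np.atleast_1d(np.asarray(betas, dtype=float))
        ses = np.atleast_1d(np.asarray(ses, dtype=float))
        self._scalar = betas.ndim == 1
        if betas.ndim == 1:
            betas = betas[:, None]
            ses = ses[:, None]
        if betas.shape != ses.shape:
            raise ValueError("betas and ses must have the same shape")
        if betas.shape[0] < 2:
            raise ValueError("meta-analysis needs k >= 2 cohorts")
        obs = np.isfinite(betas) & np.isfinite(ses)
        if np.any(obs & (ses <= 0)):
            raise ValueError("all standard errors must be positive")
        self.betas, self.ses, self.method = betas, ses, method
        self.obs = obs
        self.knapp_hartung = knapp_hartung

    def fit(self) -> "MetaResults":
        betas, ses, obs = self.betas, self.ses, self.obs
        k_v = obs.sum(axis=0)
        usable = k_v >= 2
        if not usable.any():
            raise ValueError("no vertex has two or more valid cohorts")
        mask = obs & usable[None, :]
        b = np.where(mask, betas, 0.0)
        s = np.where(mask, ses, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            tau2_dl, q = _dl_tau2(b, s, mask)
        tau2_dl = np.where(usable, np.nan_to_num(tau2_dl), np.nan)
        if self.method == "DL":
            tau2 = tau2_dl
        elif self.method == "FE":
            tau2 = np.where(usable, 0.0, np.nan)
        else:
            tau2 = np.where(usable, _reml_tau2(b, s, obs=mask), np.nan)
        w = np.where(mask, 1.0 / (s**2 + np.nan_to_num(tau2)), 0.0)
        sw = w.sum(axis=0)
        sw = np.where(usable, sw, np.nan)
        beta = (w * b).sum(axis=0) / sw
        se = np.sqrt(1.0 / sw)
        with np.errstate(invalid="ignore"):
            if self.knapp_hartung:
                scale = (w * np.where(mask, betas - beta, 0.0) ** 2).sum(axis=0) / (
                    k_v - 1
                )
                se = se * np.sqrt(np.maximum(scale, 1.0))
                p = 2.0 * stats.t.sf(np.abs(beta / se), k_v - 1)
            else:
                p = 2.0 * stats.norm.sf(np.abs(beta / se))
        q = np.where(usable, q, np.nan)
        out = MetaResults(
            beta=beta, se=se, p=p, tau2=tau2, q_het=q, k=betas.shape[0],
            method=self.method, scalar=self._scalar, k_per_vertex=k_v,
        )
        return out


@dataclass
class MetaResults:
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    tau2: np.ndarray
    q_het: np.ndarray
    k: int
    method: str
    scalar: bool = False
    k_per_vertex: np.ndarray | None = None

    def fdr_q(self, valid_mask: np.ndarray | None = None) -> np.ndarray:
        """BH-adjusted p over the family of valid vertices of this map."""
        p = self.p
        if valid_mask is None:
            valid_mask = np.isfinite(p)
        q = np.full(p.shape, np.nan)
        q[valid_mask] = fdr_bh(p[valid_mask])
        return q

    def as_maps(self, valid_mask: np.ndarray | None = None) -> dict[str, VertexMap]:
        if valid_mask is None:
            valid_mask = np.isfinite(self.beta)
        mk = lambda v, name: VertexMap(
            np.where(valid_mask, v, np.nan), valid_mask.copy(), name=name
        )
        return {
            "beta": mk(self.beta, "beta_meta"),
            "se": mk(self.se, "se_meta"),
            "p": mk(self.p, "p_meta"),
            "fdr_q": mk(self.fdr_q(valid_mask), "fdr_q"),
            "tau2": mk(self.tau2, "tau2"),
            "q_het": mk(self.q_het, "q_het"),
        }

    def summary(self) -> str:
        b, t = np.atleast_1d(self.beta), np.atleast_1d(self.tau2)
        return "\n".join(
            [
                f"Random-effects meta-analysis ({self.method}), k = {self.k},"
                f" {b.size} vertex/vertices",
                f"  beta: mean = {np.nanmean(b):.4f}, range ="
                f" [{np.nanmin(b):.4f}, {np.nanmax(b):.4f}]",
                f"  tau2: mean = {np.nanmean(t):.6f};"
                f" vertices with tau2 > 0: {int((t > 0).sum())}",
            ]
        )


def meta_random_effects(betas, ses, method: str = "REML"):
    """Scalar convenience wrapper: returns (beta, se, p, tau2, q_het)."""
    res = RandomEffectsMeta(betas, ses, method=method).fit()
    return (
        float(res.beta[0]),
        float(res.se[0]),
        float(res.p[0]),
        float(res.tau2[0]),
        float(res.q_het[0]),
    )


# ---------------------------------------------------------------------------
# Moderator meta-regression
# ---------------------------------------------------------------------------

class MetaRegression:
    """Mixed-effects meta-regression with one cohort-level moderator.

    Weighted least squares with weights ``1/(se^2 + tau^2)``; tau^2 is
    re-estimated under the moderator model by the method of moments on the
    weighted residual heterogeneity (with the hat-matrix trace correction).
    """

    def __init__(self, betas, ses, moderator):
        betas = np.atleast_1d(np.asarray(betas, dtype=float))
        ses = np.atleast_1d(np.asarray(ses, dtype=float))
        self._scalar = betas.ndim == 1
        if betas.ndim == 1:
            betas = betas[:, None]
            ses = ses[:, None]
        moderator = np.asarray(moderator, dtype=float)
        k = betas.shape[0]
        if moderator.shape != (k,):
            raise ValueError("moderator must have one value per cohort")
        if k < 3:
            raise ValueError("meta-regression with intercept+slope needs k >= 3")
        if np.ptp(moderator) == 0:
            raise ValueError("moderator is constant")
        if np.any(ses <= 0):
            raise ValueError("all standard errors must be positive")
        self.betas, self.ses, self.moderator = betas, ses, moderator

    def fit(self) -> "MetaRegressionResults":
        y, s2 = self.betas, self.ses**2
        k, nv = y.shape
        x = np.column_stack([np.ones(k), self.moderator])
        p = 2

        # FE-weighted residual heterogeneity, vertex by vertex (vectorized)
        w = 1.0 / s2
        tau2 = np.empty(nv)
        q_e = np.empty(nv)
        for v in range(nv):
            wv = np.diag(w[:, v])
            xtwx = x.T @ wv @ x
            h = x @ np.linalg.solve(xtwx, x.T @ wv)
            r = y[:, v] - h @ y[:, v]
            q_e[v] = float(r @ (w[:, v] * r))
            c = w[:, v].sum() - np.trace(
                np.linalg.solve(xtwx, x.T @ (w[:, v, None] ** 2 * x))
            )
            tau2[v] = max(0.0, (q_e[v] - (k - p)) / c)

        slope = np.empty(nv)
        se = np.empty(nv)
        intercept = np.empty(nv)
        for v in range(nv):
            wv = 1.0 / (s2[:, v] + tau2[v])
            xtwx = x.T @ (wv[:, None] * x)
            cov = np.linalg.inv(xtwx)
            coef = cov @ (x.T @ (wv * y[:, v]))
            intercept[v], slope[v] = coef
            se[v] = np.sqrt(cov[1, 1])
        pval = 2.0 * stats.norm.sf(np.abs(slope / se))
        return MetaRegressionResults(
            slope=slope, se=se, p=pval, intercept=intercept, tau2=tau2,
            q_resid=q_e, k=k, scalar=self._scalar,
        )


@dataclass
class MetaRegressionResults:
    slope: np.ndarray
    se: np.ndarray
    p: np.ndarray
    intercept: np.ndarray
    tau2: np.ndarray
    q_resid: np.ndarray
    k: int
    scalar: bool = False

    def summary(self) -> str:
        return (
            f"Meta-regression, k = {self.k}: slope mean = {np.nanmean(self.slope):.4f},"
            f" median p = {np.nanmedian(self.p):.4f}"
        )


def meta_moderator(betas, ses, moderator):
    """Scalar convenience wrapper: returns (slope, se, p)."""
    res = MetaRegression(betas, ses, moderator).fit()
    return float(res.slope[0]), float(res.se[0]), float(res.p[0])
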