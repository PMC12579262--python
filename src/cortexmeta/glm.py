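"""Mass-univariate linear models at every cortical vertex.

At each vertex v an ordinary least-squares model
``y_v = b0 + b * focal + covariates`` is fitted and the focal slope is
standardized to the correlation scale,
``beta_std = b * SD(focal) / SD(y_v)``, with the SDs computed on the
analysis sample after listwise deletion.  With no covariates the
standardized slope equals the Pearson correlation.  The standardized SE is
the raw SE rescaled by the same factor, which leaves t and p invariant to
affine rescaling of either variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .surface import VertexMap

__all__ = [
    "VertexWiseGLM",
    "VertexWiseGLMResults",
    "AssociationMap",
    "standardize_coefficient",
    "DesignError",
]


class DesignError(ValueError):
    """The design matrix is unusable (rank deficiency, too few rows)."""


def standardize_coefficient(b: float, sd_x: float, sd_y: float) -> float:
    """Rescale a raw slope to the correlation scale: ``b * sd_x / sd_y``."""
    if not (sd_x > 0) or not (sd_y > 0):
        raise ValueError("standard deviations must be positive")
    return b * sd_x / sd_y


def _build_design(focal: np.ndarray, covariates: pd.DataFrame | None):
    """Assemble [intercept, focal, dummy-coded covariates]; return names."""
    cols = [np.ones_like(focal), focal]
    names = ["intercept", "focal"]
    if covariates is not None and covariates.shape[1] > 0:
        enc = pd.get_dummies(covariates, drop_first=True, dtype=float)
        for name in enc.columns:
            cols.append(enc[name].to_numpy(dtype=float))
            names.append(str(name))
    return np.column_stack(cols), names


class VertexWiseGLM:
    """OLS of subjects x vertices morphometry on a focal predictor.

    Parameters
    ----------
    morphometry : (n, V) array
        One measure, subjects in rows.  NaN columns (e.g. the medial wall)
        are flagged invalid, not fitted.
    focal : (n,) array-like
        The predictor whose standardized slope is mapped (g, age, sex ...).
    covariates : DataFrame, optional
        Nuisance columns; categoricals are dummy-coded with a first-level
        reference.
    """

    def __init__(
        self,
        morphometry: np.ndarray,
        focal,
        covariates: pd.DataFrame | None = None,
        focal_name: str = "focal",
        measure_name: str = "measure",
    ):
        self.y = np.asarray(morphometry, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("morphometry must be (subjects, vertices)")
        self.focal = np.asarray(focal, dtype=float)
        if self.focal.shape != (self.y.shape[0],):
            raise ValueError("focal length must match the subject dimension")
        if covariates is not None and len(covariates) != self.y.shape[0]:
            raise ValueError("covariates must match the subject dimension")
        self.covariates = covariates
        self.focal_name = focal_name
        self.measure_name = measure_name

    def fit(self) -> "VertexWiseGLMResults":
        x, names = _build_design(self.focal, self.covariates)
        # listwise deletion on the model frame
        frame_ok = np.isfinite(x).all(axis=1)
        x = x[frame_ok]
        y = self.y[frame_ok]
        n, p = x.shape
        if n <= p + 2:
            raise DesignError(f"need more than p+2={p + 2} subjects, have {n}")

        # rank check with a named culprit
        sds = x[:, 1:].std(axis=0)
        for name, sd in zip(names[1:], sds):
            if sd == 0:
                raise DesignError(f"constant design column: {name}")
        if np.linalg.matrix_rank(x) < p:
            q, r = np.linalg.qr(x)
            bad = names[int(np.argmin(np.abs(np.diag(r))))]
            raise DesignError(f"rank-deficient design; offending column: {bad}")

        valid = np.isfinite(y).all(axis=0)
        sd_y = np.full(y.shape[1], np.nan)
        sd_y[valid] = y[:, valid].std(axis=0, ddof=1)
        valid &= sd_y > 0

        xtx_inv = np.linalg.inv(x.T @ x)
        beta = np.full((p, y.shape[1]), np.nan)
        beta[:, valid] = xtx_inv @ (x.T @ y[:, valid])
        resid = y[:, valid] - x @ beta[:, valid]
        dof = n - p
        sigma2 = np.sum(resid * resid, axis=0) / dof

        se_raw = np.full(y.shape[1], np.nan)
        se_raw[valid] = np.sqrt(sigma2 * xtx_inv[1, 1])
        b = beta[1]
        sd_x = x[:, 1].std(ddof=1)
        beta_std = np.full(y.shape[1], np.nan)
        se_std = np.full(y.shape[1], np.nan)
        beta_std[valid] = b[valid] * sd_x / sd_y[valid]
        se_std[valid] = se_raw[valid] * sd_x / sd_y[valid]
        t = np.full(y.shape[1], np.nan)
        t[valid] = b[valid] / se_raw[valid]
        pval = np.full(y.shape[1], np.nan)
        pval[valid] = 2.0 * stats.t.sf(np.abs(t[valid]), dof)

        mk = lambda vals, name, units="": VertexMap(vals, valid.copy(), name=name, units=units)
        return VertexWiseGLMResults(
            beta_std=mk(beta_std, f"beta_{self.focal_name}_{self.measure_name}"),
            se_std=mk(se_std, "se_std"),
            t_value=mk(t, "t"),
            p_value=mk(pval, "p"),
            beta_raw=mk(b * np.where(valid, 1.0, np.nan), "beta_raw"),
            n_subjects=n,
            df_resid=dof,
            focal_name=self.focal_name,
            measure_name=self.measure_name,
            covariate_names=names[2:],
        )


@dataclass
class AssociationMap:
    """Standardized association of one focal predictor with one measure."""

    beta_std: VertexMap
    se_std: VertexMap
    t_value: VertexMap
    p_value: VertexMap
    beta_raw: VertexMap
    n_subjects: int
    df_resid: int
    focal_name: str
    measure_name: str
    covariate_names: list[str]

    def summary(self) -> str:
        b = self.beta_std.valid_values()
        return "\n".join(
            [
                f"Vertex-wise OLS: {self.measure_name} ~ {self.focal_name}"
                + (f" + {' + '.join(self.covariate_names)}" if self.covariate_names else ""),
                f"  n = {self.n_subjects}, residual df = {self.df_resid},"
                f" valid vertices = {b.size}",
                f"  standardized beta: mean = {b.mean():.4f}, SD = {b.std(ddof=1):.4f},"
                f" range = [{b.min():.4f}, {b.max():.4f}]",
            ]
        )


# Results class is the AssociationMap; alias for the Model/Results idiom.
VertexWiseGLMResults = AssociationMap
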