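"""Allometric scaling of local cortical surface area.

Per vertex, the natural-log vertex area is regressed on the natural-log
total surface area across subjects; the slope is the allometric exponent
(1 = isometry, > 1 = disproportionate enlargement in bigger brains) and is
invariant to a consistent change of area units.  Standardized slopes can be
pooled across cohorts with :class:`~cortexmeta.meta.RandomEffectsMeta`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import VertexWiseGLM
from .meta import MetaResults, RandomEffectsMeta
from .surface import VertexMap

__all__ = ["AllometricScaling", "AllometricScalingResults", "meta_allometry"]

logger = logging.getLogger(__name__)


class AllometricScaling:
    """Per-vertex log-log regression of vertex area on total surface area."""

    def __init__(
        self,
        vertex_area: np.ndarray,
        total_area: np.ndarray,
        covariates: pd.DataFrame | None = None,
    ):
        vertex_area = np.asarray(vertex_area, dtype=float)
        total_area = np.asarray(total_area, dtype=float)
        if vertex_area.ndim != 2:
            raise ValueError("vertex_area must be (subjects, vertices)")
        if total_area.shape != (vertex_area.shape[0],):
            raise ValueError("total_area must have one value per subject")
        if vertex_area.shape[0] < 10:
            raise ValueError("allometric scaling needs at least 10 subjects")
        if np.any(total_area <= 0):
            raise ValueError("total areas must be positive")
        if np.ptp(np.log(total_area)) == 0:
            raise ValueError("total area is constant across subjects")
        self.vertex_area = vertex_area
        self.total_area = total_area
        self.covariates = covariates

    def fit(self) -> "AllometricScalingResults":
        bad = ~np.all(self.vertex_area > 0, axis=0) | ~np.all(
            np.isfinite(self.vertex_area), axis=0
        )
        if bad.any():
            logger.info("allometry: %d vertices invalidated (non-positive area)", bad.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            log_area = np.where(
                bad[None, :], np.nan, np.log(np.clip(self.vertex_area, 1e-300, None))
            )
        glm = VertexWiseGLM(
            log_area,
            np.log(self.total_area),
            covariates=self.covariates,
            focal_name="log_total_area",
            measure_name="log_vertex_area",
        ).fit()
        return AllometricScalingResults(
            slope=VertexMap(
                glm.beta_raw.values, glm.beta_raw.valid_mask.copy(),
                name="allometric_slope",
            ),
            slope_std=VertexMap(
                glm.beta_std.values, glm.beta_std.valid_mask.copy(),
                name="allometric_slope_std",
            ),
            se=glm.se_std,
            n_subjects=glm.n_subjects,
            n_invalid=int(bad.sum()),
            glm=glm,
        )


@dataclass
class AllometricScalingResults:
    slope: VertexMap
    slope_std: VertexMap
    se: VertexMap
    n_subjects: int
    n_invalid: int
    glm: object

    def summary(self) -> str:
        s = self.slope.valid_values()
        return "\n".join(
            [
                f"Allometric scaling, n = {self.n_subjects},"
                f" invalid vertices = {self.n_invalid}",
                f"  slope: mean = {s.mean():.4f}, SD = {s.std(ddof=1):.4f},"
                f" range = [{s.min():.4f}, {s.max():.4f}]",
            ]
        )


def meta_allometry(
    cohort_results: list[AllometricScalingResults], method: str = "REML"
) -> MetaResults:
    """Pool standardized allometric slopes across cohorts per vertex."""
    if len(cohort_results) < 2:
        raise ValueError("meta-analysis needs at least 2 cohorts")
    betas = np.stack([r.slope_std.values for r in cohort_results])
    ses = np.stack([r.se.values for r in cohort_results])
    return RandomEffectsMeta(betas, ses, method=method).fit()
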