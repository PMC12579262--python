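"""Spatial map-to-map statistics: Pearson correlation, spin permutation
inference, and within-region correlation decomposition.

The spin test preserves the spatial autocorrelation of a cortical map under
the null by applying uniformly random 3D rotations to its values over the
registered sphere: each target vertex takes the value of the nearest
rotated source vertex.  p-values use the add-one permutation formula, so
the smallest attainable p with S spins is 1/(S+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .meta import fdr_bh
from .surface import SurfaceMesh, VertexMap

__all__ = [
    "SpinEnsemble",
    "SpatialCorrelation",
    "spatial_pearson",
    "generate_spins",
    "spin_test",
    "within_region_corr",
    "covariance_decomposition",
    "bh_family",
]

UNKNOWN_REGION = -1


def spatial_pearson(map_a: VertexMap, map_b: VertexMap) -> tuple[float, int]:
    """Pearson r over the intersection of the two valid masks."""
    if map_a.n_vertices != map_b.n_vertices:
        raise ValueError("maps are bound to different meshes")
    joint = map_a.valid_mask & map_b.valid_mask
    n_used = int(joint.sum())
    if n_used < 3:
        raise ValueError("fewer than 3 jointly valid vertices")
    a = map_a.values[joint]
    b = map_b.values[joint]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance over the joint mask")
    return float(np.corrcoef(a, b)[0, 1]), n_used


# ---------------------------------------------------------------------------
# Spin ensembles
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform rotation from a normalized 4D Gaussian quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _assignment_for_rotation(mesh: SurfaceMesh, rotation: np.ndarray) -> np.ndarray:
    """Index of the source vertex whose rotated position is nearest each target.

    For bilateral meshes the right hemisphere receives the x-mirrored
    rotation, and assignments stay within hemisphere.
    """
    sphere = mesh.sphere_coords
    out = np.empty(mesh.n_vertices, dtype=np.int64)
    if mesh.hemisphere is None:
        groups = [np.arange(mesh.n_vertices)]
        rotations = [rotation]
    else:
        mirror = np.diag([-1.0, 1.0, 1.0])
        left = np.flatnonzero(mesh.hemisphere == "L")
        right = np.flatnonzero(mesh.hemisphere == "R")
        groups = [left, right]
        rotations = [rotation, mirror @ rotation @ mirror]
    for idx, rot in zip(groups, rotations):
        if idx.size == 0:
            continue
        tree = cKDTree(sphere[idx] @ rot.T)  # rotated source positions
        _, nearest = tree.query(sphere[idx])
        out[idx] = idx[nearest]
    return out


@dataclass
class SpinEnsemble:
    """Cached spin permutations: per spin, source vertex per target vertex."""

    n_spins: int
    seed: int
    vertex_assignment: np.ndarray  # (n_spins, V) int
    rotation_log: np.ndarray       # (n_spins, 3, 3)

    def __post_init__(self) -> None:
        if self.vertex_assignment.shape[0] != self.n_spins:
            raise ValueError("assignment table does not match n_spins")


def generate_spins(mesh: SurfaceMesh, n_spins: int = 1000, seed: int = 0) -> SpinEnsemble:
    """Draw ``n_spins`` uniformly random rotations and cache assignments.

    The rotation stream is a seeded counter-based generator (Philox), so
    regenerating with the same seed reproduces the table exactly.
    """
    if mesh.sphere_coords is None:
        raise ValueError("mesh has no spherical registration")
    if n_spins < 1:
        raise ValueError("n_spins must be positive")
    rng = np.random.Generator(np.random.Philox(int(seed)))
    assignments = np.empty((n_spins, mesh.n_vertices), dtype=np.int64)
    rotations = np.empty((n_spins, 3, 3))
    for s in range(n_spins):
        rot = _random_rotation(rng)
        rotations[s] = rot
        assignments[s] = _assignment_for_rotation(mesh, rot)
    return SpinEnsemble(n_spins, int(seed), assignments, rotations)


# ---------------------------------------------------------------------------
# Spin test
# ---------------------------------------------------------------------------

@dataclass
class SpatialCorrelation:
    """A map-pair spatial correlation with permutation inference."""

    r: float
    p_spin: float
    n_vertices_used: int
    n_spins: int
    q_bh: float | None = None
    per_region_r: pd.DataFrame | None = None
    null_r: np.ndarray | None = field(default=None, repr=False)


def _masked_pearson_rows(values: np.ndarray, valid: np.ndarray, b: np.ndarray):
    """Row-wise Pearson r of ``values`` against ``b`` under row-wise masks."""
    v = np.where(valid, values, 0.0)
    bb = np.where(valid, b[None, :], 0.0)
    n = valid.sum(axis=1)
    sv, sb = v.sum(axis=1), bb.sum(axis=1)
    svv, sbb = (v * v).sum(axis=1), (bb * bb).sum(axis=1)
    svb = (v * bb).sum(axis=1)
    cov = svb - sv * sb / n
    var_v = svv - sv * sv / n
    var_b = sbb - sb * sb / n
    with np.errstate(invalid="ignore", divide="ignore"):
        return cov / np.sqrt(var_v * var_b)


def spin_test(
    map_a: VertexMap,
    map_b: VertexMap,
    ensemble: SpinEnsemble,
    spin_which: str = "A",
) -> SpatialCorrelation:
    """Two-sided spin-permutation test of the spatial correlation of A and B.

    One map is spun over the sphere; null correlations are computed against
    the fixed map over target vertices whose spun *source* lies in the valid
    mask (masked sources are dropped pairwise per spin).
    ``p_spin = (1 + #{|r_s| >= |r_obs|}) / (1 + n_spins)``.
    """
    if spin_which not in ("A", "B"):
        raise ValueError("spin_which must be 'A' or 'B'")
    if ensemble.vertex_assignment.shape[1] != map_a.n_vertices:
        raise ValueError("ensemble is bound to a different mesh")
    if ensemble.n_spins < 100:
        warnings.warn("fewer than 100 spins gives a coarse p-value", stacklevel=2)

    r_obs, n_used = spatial_pearson(map_a, map_b)
    spun, fixed = (map_a, map_b) if spin_which == "A" else (map_b, map_a)

    asg = ensemble.vertex_assignment
    spun_vals = spun.values[asg]                       # (S, V)
    valid = spun.valid_mask[asg] & fixed.valid_mask[None, :]
    null_r = _masked_pearson_rows(spun_vals, valid, np.nan_to_num(fixed.values))
    finite = np.isfinite(null_r)
    if not finite.any() or np.allclose(null_r[finite], null_r[finite][0]):
        raise ValueError("degenerate spin null distribution")
    exceed = int(np.sum(np.abs(null_r[finite]) >= abs(r_obs)))
    p_spin = (1.0 + exceed) / (1.0 + ensemble.n_spins)
    return SpatialCorrelation(
        r=r_obs, p_spin=p_spin, n_vertices_used=n_used,
        n_spins=ensemble.n_spins, null_r=null_r,
    )


def bh_family(correlations: list[SpatialCorrelation]) -> list[SpatialCorrelation]:
    """Fill ``q_bh`` across a declared family of spin correlations."""
    q = fdr_bh(np.array([c.p_spin for c in correlations]))
    for c, qv in zip(correlations, q):
        c.q_bh = float(qv)
    return correlations


# ---------------------------------------------------------------------------
# Within-region decomposition
# ---------------------------------------------------------------------------

def within_region_corr(
    map_a: VertexMap,
    map_b: VertexMap,
    parcellation: np.ndarray,
    min_vertices: int = 25,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Pearson r of two maps within each parcellation region.

    Regions with fewer than ``min_vertices`` jointly valid vertices are
    reported with ``r`` missing (NaN), never silently dropped.  Returns the
    per-region table and counts of positive/negative regional correlations.
    """
    parcellation = np.asarray(parcellation)
    if parcellation.shape != (map_a.n_vertices,):
        raise ValueError("parcellation must label every vertex")
    joint = map_a.valid_mask & map_b.valid_mask
    rows = []
    for region in np.unique(parcellation):
        if region == UNKNOWN_REGION:
            continue
        sel = (parcellation == region) & joint
        n = int(sel.sum())
        if n < min_vertices:
            rows.append({"region": region, "n_vertices": n, "r": np.nan})
            continue
        a, b = map_a.values[sel], map_b.values[sel]
        if a.std() == 0 or b.std() == 0:
            rows.append({"region": region, "n_vertices": n, "r": np.nan})
            continue
        rows.append(
            {"region": region, "n_vertices": n, "r": float(np.corrcoef(a, b)[0, 1])}
        )
    table = pd.DataFrame(rows)
    if table.empty or table["r"].notna().sum() == 0:
        raise ValueError("no region meets the min_vertices requirement")
    summary = {
        "n_positive": int((table["r"] > 0).sum()),
        "n_negative": int((table["r"] < 0).sum()),
        "n_missing": int(table["r"].isna().sum()),
    }
    return table, summary


def covariance_decomposition(
    map_a: VertexMap, map_b: VertexMap, parcellation: np.ndarray
) -> dict:
    """Exact decomposition of the total covariance into within + between.

    With ML (divide-by-N) covariances over the joint mask:

    ``Cov_total(A, B) = sum_g (N_g / N) Cov_within_g(A, B)
    + Cov_between(region means, weighted by N_g / N)``

    This identity is what lets opposite-signed within-region correlations
    cancel at cortex level.
    """
    parcellation = np.asarray(parcellation)
    joint = map_a.valid_mask & map_b.valid_mask & (parcellation != UNKNOWN_REGION)
    a, b, lab = map_a.values[joint], map_b.values[joint], parcellation[joint]
    n = a.size
    total = float(np.mean(a * b) - a.mean() * b.mean())
    within = 0.0
    means = []
    weights = []
    for region in np.unique(lab):
        sel = lab == region
        ng = int(sel.sum())
        ag, bg = a[sel], b[sel]
        within += ng / n * float(np.mean(ag * bg) - ag.mean() * bg.mean())
        means.append((ag.mean(), bg.mean()))
        weights.append(ng / n)
    means = np.asarray(means)
    weights = np.asarray(weights)
    mean_a = float(weights @ means[:, 0])
    mean_b = float(weights @ means[:, 1])
    between = float(weights @ (means[:, 0] * means[:, 1]) - mean_a * mean_b)
    return {
        "total": total,
        "within": within,
        "between": between,
        "region_means": means,
        "region_weights": weights,
    }
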