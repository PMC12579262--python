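"""Synthetic multi-cohort cortical data with known ground truth.

Everything downstream of data collection in a vertex-wise brain-cognition
study is generated here: spatially autocorrelated cortical fields,
geodesic-Voronoi parcellations, cohorts of subject x vertex morphometry
driven by a latent general-cognition factor (g) plus age/sex/site effects,
allometrically scaling vertex areas, and low-rank-plus-noise stacks of
"neurobiological" maps.  All generators are pure functions of their inputs
and a seed.

The morphometry generator emulates *already-smoothed* surface data, i.e.
what a FreeSurfer qcache-style pipeline hands to the group analysis:
per-subject residual fields are smooth random fields at ``noise_fwhm_mm``
and effects are injected on the standardized (correlation) scale, so the
configured effect maps are directly the expected standardized betas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .surface import (
    SurfaceMesh,
    VertexMap,
    smooth_matrix,
    smoothed_noise_sd,
    vertex_areas,
)

__all__ = [
    "CohortConfig",
    "CohortDataset",
    "simulate_autocorrelated_map",
    "simulate_parcellation",
    "simulate_cohort",
    "simulate_map_stack",
    "simulate_area_cohort",
    "simple_structure_loadings",
    "default_cohort_config",
    "write_cohort",
]

UNKNOWN_REGION = -1

#: Default cognitive battery loadings; a battery of five tests spanning the
#: usual range of g saturations.
DEFAULT_LOADINGS = (0.8, 0.7, 0.6, 0.5, 0.4)


def _rng(seed: int) -> np.random.Generator:
    # Philox is counter-based: streams are reproducible and shardable.
    return np.random.Generator(np.random.Philox(int(seed)))


# ---------------------------------------------------------------------------
# Random fields and parcellations
# ---------------------------------------------------------------------------

def simulate_autocorrelated_map(
    mesh: SurfaceMesh, fwhm_mm: float, seed: int, name: str = "field"
) -> VertexMap:
    """Smooth Gaussian random field, standardized over the cortex mask.

    An i.i.d. standard-normal field is diffused to the requested FWHM and
    re-standardized to mean 0, SD 1 over the cortex mask.  Deterministic
    given (mesh, fwhm, seed).
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    rng = _rng(seed)
    raw = rng.standard_normal(mesh.n_vertices)
    sm = smooth_matrix(raw[None, :], mesh, fwhm_mm, mesh.cortex_mask)[0]
    m = mesh.cortex_mask
    sm = sm - sm[m].mean()
    sd = sm[m].std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate field (zero variance over mask)")
    sm = sm / sd
    values = np.where(m, sm, np.nan)
    return VertexMap(values, m.copy(), name=name)


def simulate_parcellation(mesh: SurfaceMesh, n_regions: int, seed: int) -> np.ndarray:
    """Geodesic-Voronoi region labels from randomly seeded centroids.

    Every cortex vertex receives exactly one label in ``0..n_regions-1``;
    non-cortex vertices get :data:`UNKNOWN_REGION`.  Distances are shortest
    paths along mesh edges restricted to the cortex mask, so each region is
    connected in the mesh graph.
    """
    cortex = np.flatnonzero(mesh.cortex_mask)
    if not (1 <= n_regions <= cortex.size):
        raise ValueError("n_regions must be between 1 and the masked vertex count")
    rng = _rng(seed)
    centroids = rng.choice(cortex, size=n_regions, replace=False)

    e = mesh.edges
    keep = mesh.cortex_mask[e[:, 0]] & mesh.cortex_mask[e[:, 1]]
    e = e[keep]
    w = mesh.edge_lengths[keep]
    from scipy import sparse

    graph = sparse.csr_matrix(
        (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
        shape=(mesh.n_vertices, mesh.n_vertices),
    )
    dist = dijkstra(graph, directed=False, indices=centroids)
    labels = np.full(mesh.n_vertices, UNKNOWN_REGION, dtype=np.int64)
    labels[cortex] = np.argmin(dist[:, cortex], axis=0)
    return labels


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Generating configuration for one cohort.

    ``test_uniquenesses`` defaults to ``1 - loading**2`` so test scores are
    standardized under the one-factor model.  Effect maps are on the
    standardized-beta scale; ``between_cohort_tau`` is the SD of the
    cohort-level deviation added to the g effect at every vertex.
    """

    n_subjects: int
    test_loadings: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_LOADINGS))
    test_uniquenesses: np.ndarray | None = None
    effect_map_g: VertexMap | None = None
    effect_map_age: VertexMap | None = None
    effect_map_sex: VertexMap | None = None
    site_effect: float = 0.15
    n_sites: int = 2
    age_mean: float = 63.0
    age_sd: float = 8.0
    age_range: tuple[float, float] = (44.0, 84.0)
    sex_proportion_female: float = 0.53
    noise_fwhm_mm: float = 20.0
    between_cohort_tau: float = 0.03
    missingness_rate: float = 0.1
    measures: tuple[str, ...] = ("volume",)
    seed: int = 0

    def __post_init__(self) -> None:
        self.test_loadings = np.asarray(self.test_loadings, dtype=np.float64)
        if np.any(np.abs(self.test_loadings) >= 1):
            raise ValueError("test loadings must satisfy |lambda| < 1")
        if self.test_uniquenesses is None:
            self.test_uniquenesses = 1.0 - self.test_loadings**2
        self.test_uniquenesses = np.asarray(self.test_uniquenesses, dtype=np.float64)
        if self.test_uniquenesses.shape != self.test_loadings.shape:
            raise ValueError("uniquenesses must match loadings")
        if np.any(self.test_uniquenesses <= 0):
            raise ValueError("uniquenesses must be positive")
        if not (0 <= self.missingness_rate < 1):
            raise ValueError("missingness_rate must be in [0, 1)")
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be at least 10")


@dataclass
class CohortDataset:
    """Subjects x vertices morphometry plus covariates and test scores."""

    morphometry: dict[str, np.ndarray]
    covariates: pd.DataFrame
    test_scores: pd.DataFrame
    truth: dict | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)


def _orthogonalize(target: np.ndarray, reference: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Gram-Schmidt on the masked vertex vectors, preserving the target SD."""
    t = target[mask] - target[mask].mean()
    r = reference[mask] - reference[mask].mean()
    sd = t.std()
    t = t - (t @ r) / (r @ r) * r
    t = t / t.std() * sd
    out = np.full_like(target, np.nan)
    out[mask] = t
    return out


def default_cohort_config(
    mesh: SurfaceMesh,
    n_subjects: int,
    seed: int,
    *,
    g_effect_sd: float = 0.05,
    g_effect_mean: float = 0.05,
    age_effect_mean: float = -0.35,
    age_effect_sd: float = 0.2,
    sex_effect_mean: float = 0.3,
    sex_effect_sd: float = 0.15,
    effect_fwhm_mm: float = 10.0,
    **kwargs,
) -> CohortConfig:
    """Build a config with freshly generated effect maps.

    The g-effect map has the configured spatial mean and SD; age and sex
    effect maps are made orthogonal to it (and to each other) by
    Gram-Schmidt over the cortex mask, so covariate-adjustment tests have a
    known answer.  Defaults reflect adult morphometry studies: age and sex
    effects substantially larger than cognition effects.  Each map is
    clipped to a realistic correlation-scale magnitude (|beta| <= 0.3 for
    g, 0.65 for age, 0.5 for sex) so the per-vertex explained variance
    stays below 1.
    """
    m = mesh.cortex_mask
    base = 900_000 + int(seed)
    g_map = simulate_autocorrelated_map(mesh, effect_fwhm_mm, base, name="beta_g")
    g_vals = np.clip(g_map.values * g_effect_sd + g_effect_mean, -0.3, 0.3)

    age0 = simulate_autocorrelated_map(mesh, effect_fwhm_mm, base + 1).values
    age_vals = _orthogonalize(age0 * age_effect_sd, g_vals, m) + age_effect_mean
    age_vals = np.clip(age_vals, -0.65, 0.65)

    sex0 = simulate_autocorrelated_map(mesh, effect_fwhm_mm, base + 2).values
    sex_vals = _orthogonalize(sex0 * sex_effect_sd, g_vals, m)
    sex_vals = np.clip(_orthogonalize(sex_vals, age_vals, m) + sex_effect_mean, -0.5, 0.5)

    return CohortConfig(
        n_subjects=n_subjects,
        effect_map_g=VertexMap(np.where(m, g_vals, np.nan), m.copy(), name="beta_g"),
        effect_map_age=VertexMap(np.where(m, age_vals, np.nan), m.copy(), name="beta_age"),
        effect_map_sex=VertexMap(np.where(m, sex_vals, np.nan), m.copy(), name="beta_sex"),
        seed=seed,
        **kwargs,
    )


def simulate_cohort(mesh: SurfaceMesh, config: CohortConfig) -> CohortDataset:
    """Generate one cohort under the latent-factor + standardized-beta model.

    Latent ``g_i ~ N(0, 1)``; test scores ``x_ij = lambda_j g_i +
    sqrt(psi_j) eps_ij`` with completely-at-random missingness.  Per-vertex
    morphometry is built on the standardized scale:

    ``y_iv = (beta_v + delta_v) g_i + beta_age,v age_z + beta_sex,v sex_z
    + beta_site site_z + sqrt(1 - R2_v) e_iv``

    where ``delta_v ~ N(0, tau^2)`` is the cohort-level deviation and
    ``e_iv`` is a unit-variance smooth residual field, so the expected
    sample standardized beta at vertex v equals ``beta_v + delta_v``.
    """
    rng = _rng(config.seed)
    n = config.n_subjects
    nv = mesh.n_vertices
    mask = mesh.cortex_mask

    for name in ("effect_map_g", "effect_map_age", "effect_map_sex"):
        vm = getattr(config, name)
        if vm is not None:
            vm.bound_to(mesh)

    # latent factor and cognitive battery
    g = rng.standard_normal(n)
    lam = config.test_loadings
    psi = config.test_uniquenesses
    scores = g[:, None] * lam[None, :] + rng.standard_normal((n, lam.size)) * np.sqrt(psi)
    if config.missingness_rate > 0:
        miss = rng.random((n, lam.size)) < config.missingness_rate
        scores = np.where(miss, np.nan, scores)
    test_scores = pd.DataFrame(scores, columns=[f"test_{j}" for j in range(lam.size)])

    # covariates
    lo, hi = config.age_range
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), lo, hi)
    sex = (rng.random(n) < config.sex_proportion_female).astype(int)  # 1 = female
    site = rng.integers(0, config.n_sites, n)
    head = rng.normal(0.0, 5.0, (n, 3))
    time_lag = np.clip(rng.normal(65.0, 38.0, n), 0, None)
    covariates = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "site": pd.Categorical([f"site_{s}" for s in site]),
            "head_x": head[:, 0],
            "head_y": head[:, 1],
            "head_z": head[:, 2],
            "time_lag": time_lag,
        }
    )

    def _zscore(x: np.ndarray) -> np.ndarray:
        sd = x.std(ddof=0)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    age_z = _zscore(age)
    sex_z = _zscore(sex.astype(float))
    site_z = _zscore(site.astype(float)) if config.n_sites > 1 else np.zeros(n)

    noise_sd = smoothed_noise_sd(mesh, config.noise_fwhm_mm, mask)
    truth_delta: dict[str, np.ndarray] = {}
    morphometry: dict[str, np.ndarray] = {}
    zeros = np.zeros(nv)
    beta_g0 = config.effect_map_g.values if config.effect_map_g is not None else zeros
    beta_age = config.effect_map_age.values if config.effect_map_age is not None else zeros
    beta_sex = config.effect_map_sex.values if config.effect_map_sex is not None else zeros
    beta_g0 = np.where(mask, np.nan_to_num(beta_g0), 0.0)
    beta_age = np.where(mask, np.nan_to_num(beta_age), 0.0)
    beta_sex = np.where(mask, np.nan_to_num(beta_sex), 0.0)

    for measure in config.measures:
        delta = (
            smooth_matrix(
                rng.standard_normal(nv)[None, :], mesh, config.noise_fwhm_mm, mask
            )[0]
            / noise_sd
            * config.between_cohort_tau
        )
        beta_g = beta_g0 + np.where(mask, delta, 0.0)
        r2 = beta_g**2 + beta_age**2 + beta_sex**2 + config.site_effect**2
        if np.any(r2[mask] >= 1):
            raise ValueError("configured effects leave non-positive residual variance")
        resid_scale = np.sqrt(np.clip(1.0 - r2, 0.0, None))
        noise = rng.standard_normal((n, nv))
        noise = smooth_matrix(noise, mesh, config.noise_fwhm_mm, mask) / noise_sd
        y = (
            g[:, None] * beta_g[None, :]
            + age_z[:, None] * beta_age[None, :]
            + sex_z[:, None] * beta_sex[None, :]
            + site_z[:, None] * config.site_effect
            + noise * resid_scale[None, :]
        )
        y[:, ~mask] = np.nan
        morphometry[measure] = y
        truth_delta[measure] = delta

    truth = {
        "config": config,
        "g": g,
        "delta": truth_delta,
        "age_z": age_z,
        "sex_z": sex_z,
    }
    return CohortDataset(morphometry, covariates, test_scores, truth)


# ---------------------------------------------------------------------------
# Map stacks (neurobiological profile analogue)
# ---------------------------------------------------------------------------

def simple_structure_loadings(
    n_maps: int, n_latent: int, primary: float = 0.8
) -> np.ndarray:
    """Block simple-structure loading matrix: each map loads on one latent."""
    if n_latent > n_maps:
        raise ValueError("n_latent cannot exceed n_maps")
    loadings = np.zeros((n_maps, n_latent))
    for i in range(n_maps):
        loadings[i, i % n_latent] = primary
    return loadings


def simulate_map_stack(
    mesh: SurfaceMesh,
    n_maps: int,
    n_latent: int,
    loading_matrix: np.ndarray | None = None,
    noise_sd: float = 0.3,
    fwhm_mm: float = 20.0,
    seed: int = 0,
    max_orthogonality_tries: int = 20,
) -> tuple[list[VertexMap], dict]:
    """Low-rank-plus-noise stack of co-registered maps with recorded truth.

    Latent spatial patterns are independent autocorrelated fields; a draw is
    regenerated if any pair correlates at |r| >= 0.1, so the recorded
    latents are mutually near-orthogonal.  Each output map is the
    loading-weighted latent sum plus smoothed noise.
    """
    if loading_matrix is None:
        loading_matrix = simple_structure_loadings(n_maps, n_latent)
    loading_matrix = np.asarray(loading_matrix, dtype=np.float64)
    if loading_matrix.shape != (n_maps, n_latent):
        raise ValueError("loading_matrix must be (n_maps, n_latent)")
    if n_latent > n_maps:
        raise ValueError("n_latent cannot exceed n_maps")

    mask = mesh.cortex_mask
    base = 700_000 + int(seed) * 1000
    for attempt in range(max_orthogonality_tries):
        latents = np.stack(
            [
                simulate_autocorrelated_map(mesh, fwhm_mm, base + attempt * 100 + k).values
                for k in range(n_latent)
            ]
        )
        lm = latents[:, mask]
        corr = np.corrcoef(lm) if n_latent > 1 else np.ones((1, 1))
        off = np.abs(corr[np.triu_indices(n_latent, 1)])
        if off.size == 0 or off.max() < 0.1:
            break
    else:
        raise RuntimeError("could not draw near-orthogonal latent patterns")

    rng = _rng(base + 99_999)
    maps = []
    for i in range(n_maps):
        vals = loading_matrix[i] @ latents
        if noise_sd > 0:
            noise = smooth_matrix(
                rng.standard_normal(mesh.n_vertices)[None, :], mesh, fwhm_mm, mask
            )[0]
            noise = noise - noise[mask].mean()
            noise = noise / noise[mask].std()
            vals = vals + noise * noise_sd
        vals = np.where(mask, vals, np.nan)
        maps.append(VertexMap(vals, mask.copy(), name=f"map_{i}"))
    truth = {"latents": latents, "loadings": loading_matrix, "seed": seed}
    return maps, truth


# ---------------------------------------------------------------------------
# Allometric area cohorts
# ---------------------------------------------------------------------------

def simulate_area_cohort(
    mesh: SurfaceMesh,
    n_subjects: int,
    exponent_map: VertexMap | None = None,
    log_scale_sd: float = 0.1,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Subject vertex areas with a programmable allometric exponent map.

    Subject i carries a brain-scale factor ``s_i = exp(t_i)``,
    ``t_i ~ N(0, log_scale_sd^2)``; vertex v's area is
    ``a_v * s_i**k_v * exp(noise)`` for template area ``a_v`` and exponent
    ``k_v``.  ``k_v = 1`` everywhere with zero noise is exact isometry.
    Returns (areas: n x V, total_area: n) with totals the realized row sums.
    """
    rng = _rng(seed)
    template = vertex_areas(mesh).values
    nv = mesh.n_vertices
    k = np.ones(nv) if exponent_map is None else np.nan_to_num(exponent_map.values, nan=1.0)
    t = rng.normal(0.0, log_scale_sd, n_subjects)
    log_area = (
        np.log(template)[None, :]
        + t[:, None] * k[None, :]
        + (rng.standard_normal((n_subjects, nv)) * noise_sd if noise_sd > 0 else 0.0)
    )
    areas = np.exp(log_area)
    return areas, areas.sum(axis=1)


# ---------------------------------------------------------------------------
# On-disk cohort representation
# ---------------------------------------------------------------------------

def write_cohort(dataset: CohortDataset, directory: str | Path) -> None:
    """Write a cohort as TSVs (one per measure) plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for measure, data in dataset.morphometry.items():
        pd.DataFrame(data).to_csv(
            directory / f"morphometry_{measure}.tsv", sep="\t", index=False,
            float_format="%.17g",
        )
    dataset.covariates.to_csv(directory / "covariates.tsv", sep="\t", index=False)
    dataset.test_scores.to_csv(
        directory / "test_scores.tsv", sep="\t", index=False, na_rep="NA"
    )
    sidecar: dict = {"n_subjects": dataset.n_subjects}
    if dataset.truth is not None:
        cfg = dataset.truth["config"]
        sidecar["config"] = {
            "n_subjects": cfg.n_subjects,
            "test_loadings": cfg.test_loadings.tolist(),
            "noise_fwhm_mm": cfg.noise_fwhm_mm,
            "between_cohort_tau": cfg.between_cohort_tau,
            "missingness_rate": cfg.missingness_rate,
            "measures": list(cfg.measures),
            "seed": cfg.seed,
        }
    (directory / "cohort.json").write_text(json.dumps(sidecar, indent=2))
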