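"""Shared fixtures: meshes, spin ensembles and simulated cohorts.

Everything is generated programmatically and session-scoped, so the
expensive objects (icospheres, smoothing operators, cohorts) are built
once per run.
"""

import numpy as np
import pytest

import cortexmeta as cm


@pytest.fixture(scope="session")
def ico3():
    return cm.build_icosphere(3)


@pytest.fixture(scope="session")
def ico4():
    return cm.build_icosphere(4)


@pytest.fixture(scope="session")
def ico5():
    return cm.build_icosphere(5)


@pytest.fixture(scope="session")
def spins200(ico4):
    return cm.generate_spins(ico4, n_spins=200, seed=11)


@pytest.fixture(scope="session")
def flat_cohort(ico4):
    """n=2000 cohort with a constant g effect of 0.15 and no heterogeneity."""
    mask = ico4.cortex_mask
    beta = cm.VertexMap(np.where(mask, 0.15, np.nan), mask.copy(), name="beta_g")
    config = cm.CohortConfig(
        n_subjects=2000,
        effect_map_g=beta,
        between_cohort_tau=0.0,
        missingness_rate=0.0,
        site_effect=0.0,
        seed=41,
    )
    return cm.simulate_cohort(ico4, config)


def measured_fwhm(mesh, smoothed_values, source_vertex, radius_mm=100.0):
    """Empirical FWHM: geodesic distance between half-height crossings of a
    bin-averaged point-source profile."""
    d = mesh.angular_distance(source_vertex) * radius_mm
    half = smoothed_values[source_vertex] / 2.0
    bins = np.arange(0.0, d.max(), 1.0)
    idx = np.digitize(d, bins)
    centers, profile = [], []
    for i in range(1, len(bins)):
        sel = idx == i
        if sel.any():
            centers.append(bins[i - 1] + 0.5)
            profile.append(smoothed_values[sel].mean())
    centers, profile = np.asarray(centers), np.asarray(profile)
    below = np.flatnonzero(profile < half)
    i = below[0]
    x0, x1, y0, y1 = centers[i - 1], centers[i], profile[i - 1], profile[i]
    return 2.0 * (x0 + (y0 - half) / (y0 - y1) * (x1 - x0))
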