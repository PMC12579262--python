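"""PCA over stacks of co-registered cortical maps, with varimax rotation.

A stack is the vertex x map matrix of z-scored values over the joint valid
mask, so PCA operates on the map-space correlation matrix.  Loadings are on
the correlation scale (eigenvector * sqrt(eigenvalue)); an orthogonal
varimax rotation redistributes variance across retained components while
preserving per-map communalities, and Tucker's congruence coefficient (an
uncentred cosine) compares loading or score vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .surface import VertexMap

__all__ = [
    "MapStack",
    "stack_maps",
    "MapPCA",
    "MapPCAResults",
    "varimax",
    "congruence",
]


@dataclass
class MapStack:
    """Vertices x maps matrix of z-scored values over the joint mask."""

    data: np.ndarray            # (n_valid, n_maps), z-scored columns
    joint_mask: np.ndarray      # (V,) bool
    map_names: list[str]
    scaling_record: np.ndarray  # (n_maps, 2): mean, SD used per map

    @property
    def n_maps(self) -> int:
        return self.data.shape[1]


def stack_maps(maps: list[VertexMap]) -> MapStack:
    """Stack maps on one mesh: intersect masks, z-score each column.

    Z-scoring (mean 0, SD 1 with ddof=1 over the joint mask) makes the
    subsequent PCA a correlation-matrix PCA; the per-map mean/SD used are
    recorded so scores can be mapped back.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps to stack")
    nv = maps[0].n_vertices
    joint = np.ones(nv, dtype=bool)
    for m in maps:
        if m.n_vertices != nv:
            raise ValueError("maps are bound to different meshes")
        joint &= m.valid_mask
    if int(joint.sum()) < len(maps):
        raise ValueError("joint mask smaller than the number of maps")
    cols = []
    scaling = []
    for m in maps:
        v = m.values[joint]
        mu, sd = v.mean(), v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero-variance map: {m.name or '<unnamed>'}")
        cols.append((v - mu) / sd)
        scaling.append((mu, sd))
    return MapStack(
        data=np.column_stack(cols),
        joint_mask=joint,
        map_names=[m.name or f"map_{i}" for i, m in enumerate(maps)],
        scaling_record=np.asarray(scaling),
    )


# ---------------------------------------------------------------------------
# Varimax and congruence
# ---------------------------------------------------------------------------

def varimax(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation maximizing the variance of squared loadings.

    SVD-based iteration with optional Kaiser (row) normalization.  Returns
    (rotated loadings, orthogonal rotation matrix).  A single column is
    returned unchanged with an identity rotation.
    """
    load = np.asarray(loadings, dtype=float)
    p, k = load.shape
    if k == 1:
        return load.copy(), np.eye(1)
    comm = np.sqrt((load**2).sum(axis=1))
    work = load / comm[:, None] if normalize else load.copy()
    rotation = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        z = work @ rotation
        b = work.T @ (z**3 - z @ np.diag((z**2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(b)
        rotation = u @ vt
        d_new = s.sum()
        if d_new - d_old < tol * max(d_new, 1.0):
            break
        d_old = d_new
    rotated = load @ rotation
    return rotated, rotation


def congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence phi = a.b / sqrt((a.a)(b.b)) — an uncentred cosine."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("inputs must be equal-length vectors of length >= 2")
    na, nb = np.sqrt(a @ a), np.sqrt(b @ b)
    if na == 0 or nb == 0:
        raise ValueError("congruence undefined for a zero vector")
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class MapPCA:
    """Principal components of a map stack (correlation-matrix PCA)."""

    def __init__(self, stack: MapStack, n_components: int | None = None):
        if not np.all(np.isfinite(stack.data)):
            raise ValueError("stack contains non-finite values")
        m = stack.n_maps
        if n_components is None:
            n_components = m
        if not (1 <= n_components <= m):
            raise ValueError("n_components must be between 1 and the number of maps")
        self.stack = stack
        self.n_components = n_components

    def fit(self, rotate: str | None = None) -> "MapPCAResults":
        """Eigendecompose the map correlation matrix; optionally varimax-rotate.

        Components are ordered by decreasing variance, and each is oriented
        so that its largest-|loading| map loads positively (a deterministic
        sign convention).
        """
        if rotate not in (None, "none", "varimax"):
            raise ValueError("rotate must be None or 'varimax'")
        x = self.stack.data
        n = x.shape[0]
        corr = (x.T @ x) / (n - 1)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval = np.clip(eigval[order], 0.0, None)
        eigvec = eigvec[:, order]

        k = self.n_components
        loadings = eigvec[:, :k] * np.sqrt(eigval[:k])
        rotation = np.eye(k)
        if rotate == "varimax" and k >= 2:
            loadings, rotation = varimax(loadings)
            # re-order rotated components by explained variance
            ss = (loadings**2).sum(axis=0)
            order_r = np.argsort(ss)[::-1]
            loadings = loadings[:, order_r]
            rotation = rotation[:, order_r]
        # deterministic sign convention
        for j in range(k):
            imax = int(np.argmax(np.abs(loadings[:, j])))
            if loadings[imax, j] < 0:
                loadings[:, j] = -loadings[:, j]
                rotation[:, j] = -rotation[:, j]

        return MapPCAResults(
            stack=self.stack,
            loadings=loadings,
            eigenvalues=eigval,
            rotation=rotation,
            rotated=rotate == "varimax" and k >= 2,
            eigvec=eigvec[:, :k],
        )


@dataclass
class MapPCAResults:
    stack: MapStack
    loadings: np.ndarray       # (n_maps, k)
    eigenvalues: np.ndarray    # full spectrum, descending
    rotation: np.ndarray       # (k, k) orthogonal
    rotated: bool
    eigvec: np.ndarray         # unrotated eigenvectors for the retained k

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def variance_explained_pct(self) -> np.ndarray:
        """Per-component % of total variance (full spectrum sums to 100).

        For a rotated solution the retained components' shares are the sums
        of squared rotated loadings over the total variance (= n_maps for a
        correlation-matrix PCA).
        """
        total = self.stack.n_maps
        if not self.rotated:
            return self.eigenvalues / total * 100.0
        ss = (self.loadings**2).sum(axis=0)
        return ss / total * 100.0

    @property
    def communalities(self) -> np.ndarray:
        """Per-map sum of squared loadings over retained components."""
        return (self.loadings**2).sum(axis=1)

    def scores(self) -> list[VertexMap]:
        """Component score maps by regression of the stack on the loadings."""
        lam = self.loadings
        coef = np.linalg.solve(lam.T @ lam, lam.T)    # (k, n_maps)
        f = self.stack.data @ coef.T                  # (n_valid, k)
        maps = []
        nv = self.stack.joint_mask.size
        for j in range(self.n_components):
            vals = np.full(nv, np.nan)
            vals[self.stack.joint_mask] = f[:, j]
            maps.append(
                VertexMap(vals, self.stack.joint_mask.copy(), name=f"PC{j + 1}")
            )
        return maps

    def reconstruct(self) -> np.ndarray:
        """Reconstruction of the stack from the retained components."""
        coef = np.linalg.solve(self.loadings.T @ self.loadings, self.loadings.T)
        return (self.stack.data @ coef.T) @ self.loadings.T

    def congruence_with(self, reference: np.ndarray) -> np.ndarray:
        """Best-matching |congruence| per column against reference loadings."""
        ref = np.asarray(reference, dtype=float)
        out = np.empty(self.n_components)
        for j in range(self.n_components):
            out[j] = max(
                abs(congruence(self.loadings[:, j], ref[:, i]))
                for i in range(ref.shape[1])
            )
        return out

    def summary(self) -> str:
        pct = self.variance_explained_pct[: self.n_components]
        lines = [
            f"PCA over {self.stack.n_maps} maps"
            + (" (varimax-rotated)" if self.rotated else ""),
            f"  vertices used: {int(self.stack.joint_mask.sum())}",
            "  component variance (%): "
            + ", ".join(f"PC{j + 1}={v:.1f}" for j, v in enumerate(pct)),
            f"  retained {self.n_components} components explain"
            f" {pct.sum():.1f}% of the variance",
        ]
        return "\n".join(lines)
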