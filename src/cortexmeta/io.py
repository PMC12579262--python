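"""File formats and provenance for the pipeline.

Per-vertex maps travel either as FreeSurfer "curv" files (new-format binary:
3-byte magic ``0xFF 0xFF 0xFF``, big-endian int32 vertex count, face count
and values-per-vertex (= 1), then big-endian float32 values) or as
one-column TSVs with a header.  The curv writer always emits big-endian
data regardless of host endianness; the curv/annot readers are implemented
here byte by byte and are cross-checked against nibabel in the test suite.
Surface geometry I/O delegates to nibabel.  Every output can be paired with
a JSON provenance sidecar carrying the configuration echo, seeds and input
hashes needed to regenerate it.
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import dataclass, field, fields
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from nibabel.freesurfer import io as fsio

from .surface import SurfaceMesh, VertexMap

__all__ = [
    "FormatError",
    "read_vertex_map",
    "write_vertex_map",
    "read_mesh",
    "write_mesh",
    "read_parcellation",
    "write_parcellation_tsv",
    "RunConfig",
    "write_sidecar",
    "sha256_file",
]

UNKNOWN_REGION = -1
_CURV_MAGIC = b"\xff\xff\xff"
_MISSING_TOKEN = "NA"


class FormatError(ValueError):
    """A file does not parse as the declared format."""


# ---------------------------------------------------------------------------
# Per-vertex maps
# ---------------------------------------------------------------------------

def _read_curv(path: Path) -> np.ndarray:
    raw = path.read_bytes()
    if raw[:3] != _CURV_MAGIC:
        raise FormatError(f"{path}: bad curv magic at byte 0: {raw[:3]!r}")
    if len(raw) < 15:
        raise FormatError(f"{path}: truncated curv header at byte {len(raw)}")
    vnum, fnum, vals_per = struct.unpack(">iii", raw[3:15])
    if vals_per != 1:
        raise FormatError(f"{path}: values-per-vertex {vals_per} != 1 at byte 11")
    expected = 15 + 4 * vnum
    if len(raw) < expected:
        raise FormatError(
            f"{path}: truncated payload at byte {len(raw)} (need {expected})"
        )
    values = np.frombuffer(raw[15:expected], dtype=">f4").astype(np.float64)
    return values


def _write_curv(path: Path, values: np.ndarray) -> None:
    payload = _CURV_MAGIC + struct.pack(">iii", values.size, 0, 1)
    payload += np.asarray(values, dtype=">f4").tobytes()
    path.write_bytes(payload)


def read_vertex_map(
    path: str | Path,
    fmt: str | None = None,
    mesh: SurfaceMesh | None = None,
    name: str = "",
) -> VertexMap:
    """Read a per-vertex map from curv or TSV.

    Curv values are all-valid unless NaN; the TSV missing token ("NA") maps
    to an invalid vertex.  If a mesh is given, a vertex-count mismatch is an
    error rather than a silent truncation.
    """
    path = Path(path)
    fmt = fmt or ("tsv" if path.suffix == ".tsv" else "curv")
    if fmt == "curv":
        values = _read_curv(path)
    elif fmt == "tsv":
        frame = pd.read_csv(
            path, sep="\t", na_values=[_MISSING_TOKEN], float_precision="round_trip"
        )
        if frame.shape[1] != 1:
            raise FormatError(f"{path}: vertex-map TSV must have exactly one column")
        values = frame.iloc[:, 0].to_numpy(dtype=float)
    else:
        raise ValueError("fmt must be 'curv' or 'tsv'")
    if mesh is not None and values.size != mesh.n_vertices:
        raise FormatError(
            f"{path}: {values.size} values but mesh has {mesh.n_vertices} vertices"
        )
    return VertexMap(values, np.isfinite(values), name=name or path.stem)


def write_vertex_map(vmap: VertexMap, path: str | Path, fmt: str | None = None) -> None:
    """Write a map as curv (big-endian binary) or one-column TSV."""
    path = Path(path)
    fmt = fmt or ("tsv" if path.suffix == ".tsv" else "curv")
    values = np.where(vmap.valid_mask, vmap.values, np.nan)
    if fmt == "curv":
        _write_curv(path, values)
    elif fmt == "tsv":
        pd.DataFrame({vmap.name or "value": values}).to_csv(
            path, sep="\t", index=False, na_rep=_MISSING_TOKEN, float_format="%.17g"
        )
    else:
        raise ValueError("fmt must be 'curv' or 'tsv'")


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

_MESH_HEADER = "ctxmesh"


def write_mesh(mesh: SurfaceMesh, path: str | Path, fmt: str = "text") -> None:
    """Write a mesh: 'text' (documented plain format) or 'freesurfer' geometry.

    Text layout: a header line ``ctxmesh <n_vertices> <n_triangles>``, then
    one line per vertex (``x y z sx sy sz mask``: native mm coordinates,
    unit-sphere coordinates, cortex-mask flag), then one line per triangle
    (three 0-based vertex indices).  The FreeSurfer variant writes geometry
    only (coords + triangles).
    """
    path = Path(path)
    if fmt == "text":
        lines = [f"{_MESH_HEADER} {mesh.n_vertices} {mesh.n_triangles}"]
        for p, s, m in zip(mesh.vertex_coords, mesh.sphere_coords, mesh.cortex_mask):
            lines.append(
                " ".join(f"{v:.17g}" for v in (*p, *s)) + f" {int(m)}"
            )
        for t in mesh.triangles:
            lines.append(f"{t[0]} {t[1]} {t[2]}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "freesurfer":
        fsio.write_geometry(str(path), mesh.vertex_coords, mesh.triangles)
    else:
        raise ValueError("fmt must be 'text' or 'freesurfer'")


def read_mesh(path: str | Path, fmt: str = "text") -> SurfaceMesh:
    """Read a mesh written by :func:`write_mesh`.

    FreeSurfer geometry carries no spherical registration; the sphere
    coordinates are reconstructed by normalising the native coordinates,
    which is exact for the synthetic spheres used here.
    """
    path = Path(path)
    if fmt == "freesurfer":
        coords, faces = fsio.read_geometry(str(path))
        unit = coords / np.linalg.norm(coords, axis=1, keepdims=True)
        return SurfaceMesh(coords, faces, unit, np.ones(len(coords), bool))
    tokens = path.read_text().split("\n")
    header = tokens[0].split()
    if len(header) != 3 or header[0] != _MESH_HEADER:
        raise FormatError(f"{path}: bad mesh header line: {tokens[0]!r}")
    nv, nf = int(header[1]), int(header[2])
    if len(tokens) < 1 + nv + nf:
        raise FormatError(f"{path}: truncated mesh file")
    coords = np.empty((nv, 3))
    sphere = np.empty((nv, 3))
    mask = np.empty(nv, dtype=bool)
    for i in range(nv):
        parts = tokens[1 + i].split()
        if len(parts) != 7:
            raise FormatError(f"{path}: bad vertex line {i + 2}")
        coords[i] = [float(v) for v in parts[:3]]
        sphere[i] = [float(v) for v in parts[3:6]]
        mask[i] = bool(int(parts[6]))
    tris = np.empty((nf, 3), dtype=np.int64)
    for i in range(nf):
        tris[i] = [int(v) for v in tokens[1 + nv + i].split()]
    return SurfaceMesh(coords, tris, sphere, mask)


# ---------------------------------------------------------------------------
# Parcellations
# ---------------------------------------------------------------------------

def _read_annot(path: Path) -> tuple[np.ndarray, list[str]]:
    """Minimal reader for new-format (version 2) FreeSurfer .annot files."""
    raw = path.read_bytes()
    off = 0

    def take_int() -> int:
        nonlocal off
        if off + 4 > len(raw):
            raise FormatError(f"{path}: truncated annot at byte {off}")
        val = struct.unpack(">i", raw[off : off + 4])[0]
        off += 4
        return val

    vnum = take_int()
    data = np.frombuffer(raw[off : off + 8 * vnum], dtype=">i4").reshape(vnum, 2)
    off += 8 * vnum
    if take_int() == 0:
        raise FormatError(f"{path}: annot without a color table")
    version = take_int()
    if version != -2:
        raise FormatError(f"{path}: unsupported annot ctab version {version}")
    max_index = take_int()
    orig_len = take_int()
    off += orig_len
    n_entries = take_int()
    names = [""] * max_index
    codes = np.zeros(max_index, dtype=np.int64)
    for _ in range(n_entries):
        idx = take_int()
        name_len = take_int()
        names[idx] = raw[off : off + name_len].split(b"\x00")[0].decode()
        off += name_len
        r, g, b, _t = (take_int() for _ in range(4))
        codes[idx] = r + (g << 8) + (b << 16)
    labels = np.full(vnum, UNKNOWN_REGION, dtype=np.int64)
    code_to_id = {int(c): i for i, c in enumerate(codes)}
    vert_codes = data[:, 1]
    for code in np.unique(vert_codes):
        if code == 0:
            continue
        if int(code) not in code_to_id:
            raise FormatError(f"{path}: vertex label {code} absent from the color table")
        labels[vert_codes == code] = code_to_id[int(code)]
    return labels, names


def read_parcellation(
    path: str | Path, fmt: str | None = None, mesh: SurfaceMesh | None = None
) -> tuple[np.ndarray, dict[int, str]]:
    """Read region labels from .annot or TSV.

    Returns (per-vertex region id, id -> name table); "unknown"/medial-wall
    entries get the reserved id -1.  Duplicate region names are an error.
    """
    path = Path(path)
    fmt = fmt or ("tsv" if path.suffix == ".tsv" else "annot")
    if fmt == "annot":
        labels, names = _read_annot(path)
        table = {i: n for i, n in enumerate(names) if n and n != "unknown"}
        labels[np.isin(labels, [i for i, n in enumerate(names) if n == "unknown"])] = (
            UNKNOWN_REGION
        )
    elif fmt == "tsv":
        frame = pd.read_csv(path, sep="\t")
        required = {"vertex", "region_id", "region_name"}
        if not required.issubset(frame.columns):
            raise FormatError(f"{path}: parcellation TSV needs columns {sorted(required)}")
        frame = frame.sort_values("vertex")
        labels = frame["region_id"].to_numpy(dtype=np.int64)
        pairs = frame[["region_id", "region_name"]].drop_duplicates()
        if pairs["region_id"].duplicated().any():
            raise FormatError(f"{path}: a region id maps to multiple names")
        table = {
            int(i): str(n)
            for i, n in zip(pairs["region_id"], pairs["region_name"])
            if int(i) != UNKNOWN_REGION
        }
    else:
        raise ValueError("fmt must be 'annot' or 'tsv'")
    values = list(table.values())
    if len(set(values)) != len(values):
        raise FormatError(f"{path}: duplicate region names")
    if mesh is not None and labels.size != mesh.n_vertices:
        raise FormatError(
            f"{path}: {labels.size} labels but mesh has {mesh.n_vertices} vertices"
        )
    known = set(table) | {UNKNOWN_REGION}
    missing = set(np.unique(labels)) - known
    if missing:
        raise FormatError(f"{path}: vertex labels {sorted(missing)} absent from the table")
    return labels, table


def write_parcellation_tsv(
    labels: np.ndarray, path: str | Path, names: dict[int, str] | None = None
) -> None:
    labels = np.asarray(labels, dtype=np.int64)
    if names is None:
        names = {int(r): f"region_{r}" for r in np.unique(labels) if r != UNKNOWN_REGION}
    name_col = [
        names.get(int(r), "unknown") if r != UNKNOWN_REGION else "unknown"
        for r in labels
    ]
    pd.DataFrame(
        {"vertex": np.arange(labels.size), "region_id": labels, "region_name": name_col}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Configuration and provenance
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Stage parameters with strict key checking and full seed capture."""

    fwhm_mm: float = 20.0
    n_spins: int = 1000
    seed: int = 0
    meta_method: str = "REML"
    n_components: int = 4
    min_vertices: int = 25
    subdivision_level: int = 4
    radius_mm: float = 100.0

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_sidecar(
    output_path: str | Path,
    config: dict,
    inputs: list[str | Path] = (),
    extra: dict | None = None,
) -> Path:
    """Write ``<output>.json`` with config echo, seeds and input hashes."""
    from . import __version__

    sidecar = {
        "tool": "cortexmeta",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "inputs": {str(p): sha256_file(p) for p in inputs},
    }
    if extra:
        sidecar.update(extra)
    path = Path(str(output_path) + ".json")
    path.write_text(json.dumps(sidecar, indent=2, default=str))
    return path
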