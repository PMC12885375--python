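"""Volumes, triangle meshes, per-vertex maps: containers, I/O and geometry.

Conventions
-----------
* All surfaces live in world millimetres; voxel indices are 0-based and map
  to world space through the volume affine (index -> centre of the voxel).
* Mean curvature uses the cotangent Laplace-Beltrami operator with
  barycentric vertex areas.  Sign: positive where the surface bends against
  the outward normal (a unit sphere with outward normals has H = +1/r).
* Geodesic distances are graph shortest paths along mesh edges with
  Euclidean edge weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from nibabel import gifti
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "ScalarVolume",
    "SegmentedVolume",
    "TriangleMesh",
    "SurfaceMap",
    "FormatError",
    "TopologyError",
    "load_volume",
    "save_volume",
    "load_segmentation",
    "save_segmentation",
    "load_mesh",
    "save_mesh",
    "load_surface_map",
    "save_surface_map",
    "save_matrix",
    "load_matrix",
    "mesh_geometry",
    "geodesic_distances",
    "make_icosphere",
    "make_grid_mesh",
]


class FormatError(ValueError):
    """Raised for malformed or unsupported on-disk artefacts."""


class TopologyError(ValueError):
    """Raised for meshes with invalid connectivity."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ScalarVolume:
    """A 3D scalar feature volume with a voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"volume data must be 3D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is singular")
        if np.any(self.voxel_size <= 0):
            raise FormatError("voxel size must be strictly positive")

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length of a voxel along each axis, in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(indices)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class SegmentedVolume:
    """An integer label volume plus a role -> label-value mapping.

    Roles are a subset of {background, CSF, GM, WM, ventricle}.
    """

    labels: np.ndarray
    label_map: dict[str, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise FormatError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("segmentation labels must be integer typed")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def mask(self, role: str) -> np.ndarray:
        """Boolean mask of voxels carrying `role` (empty if role unmapped)."""
        if role not in self.label_map:
            return np.zeros(self.labels.shape, dtype=bool)
        return self.labels == self.label_map[role]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class TriangleMesh:
    """Triangle mesh in world mm with optional named per-vertex maps."""

    vertices: np.ndarray
    faces: np.ndarray
    vertex_maps: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise TopologyError("vertices must be V x 3")
        if self.vertices.shape[0] == 0:
            raise TopologyError("mesh has no vertices")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise TopologyError("faces must be F x 3")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise TopologyError("face indices out of range")
        uniq = np.unique(np.sort(self.faces, axis=1), axis=0)
        if self.faces.size and len(uniq) < len(self.faces):
            warnings.warn("mesh contains duplicated faces; preserved as-is", stacklevel=2)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same topology, new embedding."""
        return TriangleMesh(np.asarray(vertices, dtype=float), self.faces.copy())


@dataclass
class SurfaceMap:
    """Per-vertex scalar or label data tied to a mesh."""

    values: np.ndarray
    mesh_id: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise FormatError("surface map values must be 1D")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Volume I/O (NIfTI via nibabel)
# ---------------------------------------------------------------------------


def save_volume(path: str | Path, volume: ScalarVolume) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(volume.data, volume.affine)
    img.header.set_data_dtype(volume.data.dtype)
    nib.save(img, path)
    return path


def load_volume(path: str | Path) -> ScalarVolume:
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise FormatError(f"cannot read volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected 3D volume, got shape {data.shape}")
    if img.affine is None:
        raise FormatError("volume has no affine")
    return ScalarVolume(data=data, affine=np.asarray(img.affine))


def save_segmentation(path: str | Path, seg: SegmentedVolume) -> Path:
    """Write labels as NIfTI plus a YAML sidecar naming the label roles."""
    path = Path(path)
    img = nib.Nifti1Image(seg.labels, seg.affine)
    img.header.set_data_dtype(seg.labels.dtype)
    nib.save(img, path)
    sidecar = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    sidecar = sidecar.parent / (sidecar.name + ".labels.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"label_map": {k: int(v) for k, v in seg.label_map.items()}}, fh)
    return path


def load_segmentation(path: str | Path, label_map: dict[str, int] | None = None) -> SegmentedVolume:
    path = Path(path)
    vol = load_volume(path)
    data = vol.data
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise FormatError("segmentation volume contains non-integer values")
        data = np.round(data).astype(np.int32)
    if label_map is None:
        stem = path.name[: -len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
        sidecar = path.parent / (stem + ".labels.yaml")
        if not sidecar.exists():
            raise FormatError(f"no label_map given and sidecar {sidecar} missing")
        with open(sidecar) as fh:
            label_map = yaml.safe_load(fh)["label_map"]
    return SegmentedVolume(labels=data, label_map=dict(label_map), affine=vol.affine)


# ---------------------------------------------------------------------------
# Mesh and per-vertex map I/O (GIFTI via nibabel)
# ---------------------------------------------------------------------------


def save_mesh(path: str | Path, mesh: TriangleMesh) -> Path:
    """Write a GIFTI surface.  Coordinates are stored as float32 (the GIFTI
    standard does not admit float64); callers needing exact round trips
    should keep vertices float32-representable."""
    path = Path(path)
    img = gifti.GiftiImage()
    img.add_gifti_data_array(
        gifti.GiftiDataArray(mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET")
    )
    img.add_gifti_data_array(
        gifti.GiftiDataArray(mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE")
    )
    nib.save(img, path)
    return path


def load_mesh(path: str | Path) -> TriangleMesh:
    from nibabel.nifti1 import intent_codes

    img = nib.load(Path(path))
    verts = faces = None
    for da in img.darrays:
        if da.intent == intent_codes["NIFTI_INTENT_POINTSET"]:
            verts = np.asarray(da.data, dtype=float)
        elif da.intent == intent_codes["NIFTI_INTENT_TRIANGLE"]:
            faces = np.asarray(da.data, dtype=np.int64)
    if verts is None or faces is None:
        raise FormatError(f"{path}: not a surface GIFTI (needs pointset + triangle arrays)")
    return TriangleMesh(vertices=verts, faces=faces)


def save_surface_map(path: str | Path, smap: SurfaceMap) -> Path:
    path = Path(path)
    img = gifti.GiftiImage()
    values = smap.values
    if np.issubdtype(values.dtype, np.integer):
        da = gifti.GiftiDataArray(values.astype(np.int32), intent="NIFTI_INTENT_LABEL")
    else:
        da = gifti.GiftiDataArray(values.astype(np.float32), intent="NIFTI_INTENT_SHAPE")
    img.add_gifti_data_array(da)
    nib.save(img, path)
    return path


def load_surface_map(path: str | Path) -> SurfaceMap:
    img = nib.load(Path(path))
    if not img.darrays:
        raise FormatError(f"{path}: empty GIFTI data file")
    data = np.asarray(img.darrays[0].data)
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(float)
    return SurfaceMap(values=data.ravel())


def save_matrix(path: str | Path, matrix: np.ndarray, meta: dict | None = None) -> Path:
    """Dense matrix as whitespace-delimited text + JSON sidecar."""
    path = Path(path)
    np.savetxt(path, np.asarray(matrix))
    sidecar = path.parent / (path.stem + ".json")
    info = {"shape": list(np.asarray(matrix).shape)}
    info.update(meta or {})
    sidecar.write_text(json.dumps(info, indent=2))
    return path


def load_matrix(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(Path(path)))


# ---------------------------------------------------------------------------
# Mesh geometry
# ---------------------------------------------------------------------------


def vertex_adjacency(mesh: TriangleMesh) -> list[np.ndarray]:
    """1-ring neighbour indices per vertex (sorted, unique)."""
    return _adjacency_lists(mesh)


def _adjacency_lists(mesh: TriangleMesh) -> list[np.ndarray]:
    adj = adjacency_matrix(mesh).tocsr()
    return [adj.indices[adj.indptr[i]: adj.indptr[i + 1]] for i in range(mesh.n_vertices)]


def adjacency_matrix(mesh: TriangleMesh) -> sparse.csr_matrix:
    """Symmetric binary vertex adjacency."""
    f = mesh.faces
    i = np.concatenate([f[:, 0], f[:, 1], f[:, 2], f[:, 1], f[:, 2], f[:, 0]])
    j = np.concatenate([f[:, 1], f[:, 2], f[:, 0], f[:, 0], f[:, 1], f[:, 2]])
    data = np.ones(len(i), dtype=np.int8)
    adj = sparse.coo_matrix((data, (i, j)), shape=(mesh.n_vertices,) * 2).tocsr()
    adj.data[:] = 1
    return adj


def _face_normals_areas(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray]:
    v = mesh.vertices
    f = mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = cross / (2.0 * areas[:, None])
    return normals, areas


def mesh_geometry(mesh: TriangleMesh) -> dict:
    """Adjacency, barycentric vertex areas, angle-weighted vertex normals and
    cotangent mean curvature.

    Degenerate (zero-area) faces are excluded from area accumulation with a
    warning.
    """
    v, f = mesh.vertices, mesh.faces
    face_normals, face_areas = _face_normals_areas(mesh)
    degenerate = face_areas <= 1e-14
    if degenerate.any():
        warnings.warn(f"{degenerate.sum()} degenerate face(s) excluded from area accumulation", stacklevel=2)

    vertex_areas = np.zeros(mesh.n_vertices)
    good = ~degenerate
    for k in range(3):
        np.add.at(vertex_areas, f[good, k], face_areas[good] / 3.0)

    # area-weighted vertex normals
    normals = np.zeros_like(v)
    for k in range(3):
        np.add.at(normals, f[good, k], face_normals[good] * face_areas[good, None])
    norms = np.linalg.norm(normals, axis=1)
    nz = norms > 1e-14
    normals[nz] /= norms[nz, None]

    # cotangent Laplacian of position -> mean curvature vector
    lap = _cotangent_laplacian(mesh, good)
    lap_x = lap @ v  # area-integrated Laplace-Beltrami of position = -2 H n A
    # Voronoi (cotangent) areas normalize the operator; barycentric areas
    # overestimate curvature at low-degree vertices (icosahedron poles)
    w_offdiag = lap - sparse.diags(lap.diagonal())
    edge_sq = sparse.csr_matrix(
        (np.sum((v[w_offdiag.tocoo().row] - v[w_offdiag.tocoo().col]) ** 2, axis=1),
         (w_offdiag.tocoo().row, w_offdiag.tocoo().col)),
        shape=lap.shape,
    )
    voronoi = 0.25 * np.asarray(w_offdiag.multiply(edge_sq).sum(axis=1)).ravel()
    curv_area = np.where(voronoi > 1e-14, voronoi, vertex_areas)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_curvature = -np.einsum("ij,ij->i", lap_x, normals) / (2.0 * curv_area)
    mean_curvature[vertex_areas <= 1e-14] = np.nan

    return {
        "adjacency": _adjacency_lists(mesh),
        "adjacency_matrix": adjacency_matrix(mesh),
        "vertex_areas": vertex_areas,
        "normals": normals,
        "mean_curvature": mean_curvature,
    }


def _cotangent_laplacian(mesh: TriangleMesh, face_mask: np.ndarray) -> sparse.csr_matrix:
    """Sparse cotan operator L with (L x)_i = sum_j w_ij (x_j - x_i)."""
    v, f = mesh.vertices, mesh.faces[face_mask]
    n = mesh.n_vertices
    rows, cols, vals = [], [], []
    for k in range(3):
        i = f[:, k]
        j = f[:, (k + 1) % 3]
        o = f[:, (k + 2) % 3]  # vertex opposite edge (i, j)
        a = v[i] - v[o]
        b = v[j] - v[o]
        cross = np.linalg.norm(np.cross(a, b), axis=1)
        cross = np.maximum(cross, 1e-14)
        cot = np.einsum("ij,ij->i", a, b) / cross
        w = 0.5 * cot
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([w, w])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    W = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    diag = np.asarray(W.sum(axis=1)).ravel()
    return W - sparse.diags(diag)


def edge_graph(mesh: TriangleMesh) -> sparse.csr_matrix:
    """Sparse graph of mesh edges weighted by Euclidean length (mm)."""
    f = mesh.faces
    i = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    j = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    lengths = np.linalg.norm(mesh.vertices[i] - mesh.vertices[j], axis=1)
    g = sparse.coo_matrix((lengths, (i, j)), shape=(mesh.n_vertices,) * 2)
    g = g.maximum(g.T)
    return g.tocsr()


def geodesic_distances(mesh: TriangleMesh, sources: np.ndarray | list[int]) -> np.ndarray:
    """Graph-geodesic distance (mm) from the nearest source vertex.

    Disconnected vertices get +inf.
    """
    sources = np.atleast_1d(np.asarray(sources, dtype=int))
    if sources.size == 0:
        raise ValueError("need at least one source vertex")
    g = edge_graph(mesh)
    d = dijkstra(g, directed=False, indices=sources, min_only=True)
    return np.asarray(d)


def pairwise_geodesic_distances(mesh: TriangleMesh) -> np.ndarray:
    """Dense V x V graph-geodesic distance matrix (small meshes only)."""
    g = edge_graph(mesh)
    return dijkstra(g, directed=False)


# ---------------------------------------------------------------------------
# Mesh constructors
# ---------------------------------------------------------------------------

_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        [-1, _ICO_T, 0], [1, _ICO_T, 0], [-1, -_ICO_T, 0], [1, -_ICO_T, 0],
        [0, -1, _ICO_T], [0, 1, _ICO_T], [0, -1, -_ICO_T], [0, 1, -_ICO_T],
        [_ICO_T, 0, -1], [_ICO_T, 0, 1], [-_ICO_T, 0, -1], [-_ICO_T, 0, 1],
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def make_icosphere(subdivisions: int = 3, radius: float = 1.0, center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Icosahedron subdivision sphere with outward-wound faces.

    Coordinates are rounded through float32 so GIFTI round trips are exact.
    """
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1)[:, None]
    faces = _ICO_FACES.copy()
    for _ in range(subdivisions):
        edge_mid: dict[tuple[int, int], int] = {}
        new_faces = []
        verts_list = [verts]
        next_idx = len(verts)

        def midpoint(a: int, b: int) -> int:
            nonlocal next_idx
            key = (min(a, b), max(a, b))
            if key in edge_mid:
                return edge_mid[key]
            m = verts[a] + verts[b]
            m /= np.linalg.norm(m)
            verts_list.append(m[None, :])
            edge_mid[key] = next_idx
            next_idx += 1
            return edge_mid[key]

        for tri in faces:
            a, b, c = tri
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces.extend([[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]])
        verts = np.concatenate(verts_list, axis=0)
        faces = np.array(new_faces, dtype=np.int64)

    verts = verts * radius + np.asarray(center, dtype=float)
    verts = verts.astype(np.float32).astype(np.float64)
    return TriangleMesh(vertices=verts, faces=faces)


def make_grid_mesh(x: np.ndarray, y: np.ndarray, z: float) -> TriangleMesh:
    """Regular planar grid in the z = const plane, triangulated with +z normals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.full(nx * ny, float(z))])

    def vid(i, j):
        return i * ny + j

    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            # counter-clockwise when viewed from +z
            faces.append([a, b, c])
            faces.append([a, c, d])
    verts = verts.astype(np.float32).astype(np.float64)
    return TriangleMesh(vertices=verts, faces=np.array(faces, dtype=np.int64))
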