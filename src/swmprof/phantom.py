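"""Synthetic phantoms with analytic ground truth.

Two segmentation geometries are provided:

* **slab** — planar layers CSF | GM | WM | ventricle stacked along +z.  The
  Laplace potential between the GM/WM plane and the ventricular plane is
  linear in z, so every stage of the depth pipeline has a closed form.
* **shell** — concentric spheres (ventricle core, WM shell, GM shell, CSF
  rind).  The potential between radii a (ventricle wall, u=1) and b (GM/WM
  sphere, u=0) is u(r) = (1/r - 1/b) / (1/a - 1/b); field lines are radial,
  so streamline length equals radial offset b - r.

Label boundaries fall on voxel faces: a voxel belongs to the layer that
contains its centre.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from swmprof.geometry_io import (
    ScalarVolume,
    SegmentedVolume,
    SurfaceMap,
    TriangleMesh,
    make_grid_mesh,
    make_icosphere,
)
from swmprof.stats_context import ConnectivityMatrix

__all__ = [
    "PhantomSpec",
    "PhantomResult",
    "PlantedProfileSet",
    "make_slab_phantom",
    "make_shell_phantom",
    "make_depth_intensity_volume",
    "make_planted_gradient_profiles",
    "make_synthetic_connectome",
    "LABELS",
]

#: canonical label values used by all phantoms
LABELS = {"background": 0, "CSF": 1, "GM": 2, "WM": 3, "ventricle": 4}

#: voxel-size presets (mm): in-vivo-like and histology-like
VOXEL_PRESETS = {"invivo": 0.5, "histology": 0.2}


class PhantomConfigError(ValueError):
    """Raised for inconsistent phantom specifications."""


@dataclass
class PhantomSpec:
    """Geometry of a synthetic segmentation.

    ``layer_thicknesses`` is keyed by role; for the shell phantom the
    ventricle entry is the core *radius* and the others are shell
    thicknesses (mm).
    """

    kind: str = "slab"
    voxel_size: float = 0.5
    layer_thicknesses: dict[str, float] = field(
        default_factory=lambda: {"CSF": 2.0, "GM": 3.0, "WM": 6.0, "ventricle": 2.0}
    )
    lateral_extent: float = 16.0  # slab only: x/y extent in mm
    mesh_margin: float = 1.5  # slab only: mesh inset from lateral borders
    mesh_subdivisions: int = 3  # shell only: icosphere subdivision level
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("slab", "shell"):
            raise PhantomConfigError(f"unknown phantom kind {self.kind!r}")
        if self.voxel_size <= 0:
            raise PhantomConfigError("voxel_size must be positive")
        if any(t <= 0 for t in self.layer_thicknesses.values()):
            raise PhantomConfigError("layer thicknesses must be positive")

    @classmethod
    def shell_default(cls, voxel_size: float = 0.5, seed: int = 0) -> "PhantomSpec":
        return cls(
            kind="shell",
            voxel_size=voxel_size,
            layer_thicknesses={"ventricle": 14.0, "WM": 10.0, "GM": 3.0, "CSF": 1.5},
            seed=seed,
        )


@dataclass
class PhantomResult:
    """A phantom segmentation plus its analytic ground truth."""

    seg: SegmentedVolume
    gm_wm_mesh: TriangleMesh
    analytic_potential: Callable[[np.ndarray], np.ndarray]
    depth: np.ndarray  # signed depth below the GM/WM interface per voxel (mm)
    kind: str
    params: dict
    # signed distances (mm, positive into WM) to the u=0 ("low") and u=1
    # ("high") boundaries; exact sub-voxel geometry for the Laplace solver
    boundary_distance: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class PlantedProfileSet:
    """Depth profiles built as baseline(d) + s_v * modulation(d) + noise."""

    profiles: np.ndarray  # D x V
    gradient_truth: np.ndarray  # length V
    depths: np.ndarray  # length D (mm)
    baseline: Callable[[np.ndarray], np.ndarray]
    modulation: Callable[[np.ndarray], np.ndarray]
    noise_sd: float
    seed: int


def _centered_affine(voxel_size: float) -> np.ndarray:
    """Affine mapping voxel index i to the world centre (i + 0.5) * h."""
    h = voxel_size
    aff = np.diag([h, h, h, 1.0])
    aff[:3, 3] = h / 2.0
    return aff


def make_slab_phantom(spec: PhantomSpec | None = None, **kwargs) -> PhantomResult:
    """Planar-layer phantom: CSF | GM | WM | ventricle along +z.

    The GM/WM interface is the plane z = CSF + GM thickness; the analytic
    potential is depth / WM-thickness for depth in [0, WM].
    """
    spec = spec or PhantomSpec(**kwargs)
    if spec.kind != "slab":
        raise PhantomConfigError("spec.kind must be 'slab'")
    h = spec.voxel_size
    th = spec.layer_thicknesses
    for role in ("CSF", "GM", "WM", "ventricle"):
        if role not in th:
            raise PhantomConfigError(f"slab phantom needs a {role} thickness")
    if th["WM"] < 3.0:
        raise PhantomConfigError("WM thinner than 3 mm cannot hold the default 3 mm depth range")

    z_if = th["CSF"] + th["GM"]  # GM/WM interface plane (mm)
    z_vent = z_if + th["WM"]  # WM/ventricle plane
    z_total = z_vent + th["ventricle"]
    nz = int(round(z_total / h))
    nxy = int(round(spec.lateral_extent / h))
    if abs(nz * h - z_total) > 1e-9 or abs(nxy * h - spec.lateral_extent) > 1e-9:
        raise PhantomConfigError("layer thicknesses and extent must be voxel-size multiples")

    affine = _centered_affine(h)
    zc = (np.arange(nz) + 0.5) * h  # voxel-centre z coordinates
    labels_z = np.full(nz, LABELS["ventricle"], dtype=np.int16)
    labels_z[zc < z_vent] = LABELS["WM"]
    labels_z[zc < z_if] = LABELS["GM"]
    labels_z[zc < th["CSF"]] = LABELS["CSF"]
    labels = np.broadcast_to(labels_z, (nxy, nxy, nz)).copy()

    seg = SegmentedVolume(labels=labels, label_map=dict(LABELS), affine=affine)

    m = spec.mesh_margin
    grid = np.arange(m, spec.lateral_extent - m + 1e-9, h)
    mesh = make_grid_mesh(grid, grid, z_if)

    wm = th["WM"]

    def analytic_potential(depth):
        return np.clip(np.asarray(depth, dtype=float) / wm, 0.0, 1.0)

    depth = np.broadcast_to(zc - z_if, (nxy, nxy, nz)).copy()

    return PhantomResult(
        seg=seg,
        gm_wm_mesh=mesh,
        analytic_potential=analytic_potential,
        depth=depth,
        kind="slab",
        boundary_distance={"low": depth, "high": z_vent - np.broadcast_to(zc, (nxy, nxy, nz))},
        params={
            "voxel_size": h,
            "interface_z": z_if,
            "ventricle_z": z_vent,
            "wm_thickness": wm,
            "seed": spec.seed,
        },
    )


def make_shell_phantom(spec: PhantomSpec | None = None, **kwargs) -> PhantomResult:
    """Concentric-sphere phantom: ventricle core | WM | GM | CSF.

    analytic_potential is a function of *radius*:
    u(r) = (1/r - 1/b) / (1/a - 1/b), 0 at the GM/WM sphere r=b, 1 at the
    ventricle wall r=a.
    """
    spec = spec or PhantomSpec.shell_default(**kwargs)
    if spec.kind != "shell":
        raise PhantomConfigError("spec.kind must be 'shell'")
    h = spec.voxel_size
    th = spec.layer_thicknesses
    a = th.get("ventricle", 0.0)
    b = a + th.get("WM", 0.0)
    c = b + th.get("GM", 0.0)
    outer = c + th.get("CSF", 0.0)
    if not (0 < a < b < c <= outer):
        raise PhantomConfigError(f"shell radii must be monotone: a={a}, b={b}, c={c}, outer={outer}")

    half = outer + 1.5  # background margin (mm)
    n = 2 * int(np.ceil(half / h))
    affine = _centered_affine(h)
    center = np.full(3, n * h / 2.0)

    coords = (np.arange(n) + 0.5) * h
    dx = coords - center[0]
    r = np.sqrt(dx[:, None, None] ** 2 + dx[None, :, None] ** 2 + dx[None, None, :] ** 2)

    labels = np.zeros((n, n, n), dtype=np.int16)
    labels[r < outer] = LABELS["CSF"]
    labels[r < c] = LABELS["GM"]
    labels[r < b] = LABELS["WM"]
    labels[r < a] = LABELS["ventricle"]
    seg = SegmentedVolume(labels=labels, label_map=dict(LABELS), affine=affine)

    mesh = make_icosphere(subdivisions=spec.mesh_subdivisions, radius=b, center=center)

    denom = 1.0 / a - 1.0 / b

    def analytic_potential(radius):
        radius = np.asarray(radius, dtype=float)
        return np.clip((1.0 / radius - 1.0 / b) / denom, 0.0, 1.0)

    return PhantomResult(
        seg=seg,
        gm_wm_mesh=mesh,
        analytic_potential=analytic_potential,
        depth=b - r,  # radial offset below the GM/WM sphere
        kind="shell",
        boundary_distance={"low": b - r, "high": r - a},
        params={"voxel_size": h, "a": a, "b": b, "c": c, "outer": outer,
                "center": center.tolist(), "seed": spec.seed},
    )


def make_depth_intensity_volume(
    phantom: PhantomResult,
    profile_fn: Callable[[np.ndarray], np.ndarray],
    planted_map: SurfaceMap | np.ndarray | Callable[[np.ndarray], np.ndarray] | None = None,
    modulation_fn: Callable[[np.ndarray], np.ndarray] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    noise_smoothing_mm: float = 0.0,
) -> ScalarVolume:
    """Feature volume whose intensity is a pure function of depth below the
    GM/WM interface, optionally modulated by a planted regional map.

    intensity(voxel) = profile_fn(depth) + planted * modulation_fn(depth)
    + Gaussian noise.  A per-vertex planted map is extended into the volume
    by nearest GM/WM vertex (piecewise constant); a *callable* planted map
    is evaluated directly on voxel world coordinates, giving a spatially
    smooth regional effect.  ``noise_smoothing_mm`` > 0 makes the noise
    spatially correlated (Gaussian kernel, variance renormalized).
    """
    depth = phantom.depth
    data = np.asarray(profile_fn(depth), dtype=float)
    if data.shape != depth.shape:
        data = np.broadcast_to(data, depth.shape).astype(float)
    else:
        data = data.copy()

    if planted_map is not None:
        shape = phantom.seg.labels.shape
        idx = np.indices(shape).reshape(3, -1).T
        world = idx @ phantom.seg.affine[:3, :3].T + phantom.seg.affine[:3, 3]
        if callable(planted_map):
            planted_vox = np.asarray(planted_map(world), dtype=float).reshape(shape)
        else:
            planted = (
                planted_map.values
                if isinstance(planted_map, SurfaceMap)
                else np.asarray(planted_map, dtype=float)
            )
            if len(planted) != phantom.gm_wm_mesh.n_vertices:
                raise ValueError("planted map length must match the GM/WM mesh")
            tree = cKDTree(phantom.gm_wm_mesh.vertices)
            _, nearest = tree.query(world, workers=-1)
            planted_vox = planted[nearest].reshape(shape)
        mod = modulation_fn(depth) if modulation_fn is not None else np.ones_like(depth)
        data += planted_vox * mod

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=depth.shape)
        if noise_smoothing_mm > 0:
            sigma_vox = noise_smoothing_mm / phantom.params["voxel_size"]
            noise = gaussian_filter(noise, sigma_vox)
            noise *= noise_sd / max(noise.std(), 1e-12)
        data += noise

    return ScalarVolume(data=data, affine=phantom.seg.affine.copy())


def make_planted_gradient_profiles(
    n_vertices: int,
    depths: np.ndarray | int,
    noise_sd: float = 0.0,
    seed: int = 0,
    gradient_truth: np.ndarray | None = None,
    baseline: Callable[[np.ndarray], np.ndarray] | None = None,
    modulation: Callable[[np.ndarray], np.ndarray] | None = None,
) -> PlantedProfileSet:
    """Depth x vertex profile set with a planted regional gradient.

    Default construction uses phase-shifting cosine/sine components so the
    *rank* structure of a profile varies smoothly with the planted score:
    p_v(d) = cos(pi t) + s_v sin(pi t) + noise, t = normalized depth.
    Scores are centred and linear in vertex index unless supplied.
    """
    if n_vertices < 50:
        raise ValueError("need at least 50 vertices")
    if np.isscalar(depths):
        depths = np.arange(int(depths), dtype=float) * 0.2
    depths = np.asarray(depths, dtype=float)
    if len(depths) < 5:
        raise ValueError("need at least 5 depths")

    span = depths[-1] - depths[0]
    t = (depths - depths[0]) / (span if span > 0 else 1.0)

    if baseline is None:
        baseline = lambda d: np.cos(np.pi * (d - depths[0]) / (span if span > 0 else 1.0))  # noqa: E731
    if modulation is None:
        modulation = lambda d: np.sin(np.pi * (d - depths[0]) / (span if span > 0 else 1.0))  # noqa: E731

    if gradient_truth is None:
        # +-3x the modulation amplitude: strong enough that the planted
        # axis dominates rank correlations at the default noise levels
        s = np.linspace(-3.0, 3.0, n_vertices)
    else:
        s = np.asarray(gradient_truth, dtype=float)
        if len(s) != n_vertices:
            raise ValueError("gradient_truth length mismatch")

    rng = np.random.default_rng(seed)
    profiles = baseline(depths)[:, None] + s[None, :] * modulation(depths)[:, None]
    if noise_sd > 0:
        profiles = profiles + rng.normal(0.0, noise_sd, size=profiles.shape)

    return PlantedProfileSet(
        profiles=profiles,
        gradient_truth=s,
        depths=depths,
        baseline=baseline,
        modulation=modulation,
        noise_sd=noise_sd,
        seed=seed,
    )


def make_synthetic_connectome(
    n: int,
    strength_truth: np.ndarray,
    model: str = "fc",
    seed: int = 0,
    noise: float = 0.1,
) -> ConnectivityMatrix:
    """Symmetric zero-diagonal connectome whose expected node strength is
    monotone in ``strength_truth``.

    fc: r_ij = tanh(t_i t_j + noise), entries in (-1, 1).
    sc: Poisson streamline counts with rate proportional to t_i t_j
        (deterministic rates when noise == 0).
    """
    t = np.asarray(strength_truth, dtype=float)
    if len(t) != n:
        raise ValueError("strength_truth length mismatch")
    if np.any(t < 0):
        raise ValueError("strength_truth must be nonnegative")
    tmax = t.max()
    tn = t / tmax if tmax > 0 else np.ones(n)
    rng = np.random.default_rng(seed)

    latent = 0.8 * np.outer(tn, tn)
    if model == "fc":
        eps = rng.normal(0.0, noise, size=(n, n)) if noise > 0 else np.zeros((n, n))
        eps = (eps + eps.T) / np.sqrt(2.0)
        values = np.tanh(latent + eps)
        kind = "fc"
    elif model == "sc":
        lam = 50.0 * np.outer(tn, tn)
        if noise > 0:
            upper = rng.poisson(lam)
            values = np.triu(upper, 1)
            values = values + values.T
            values = values.astype(float)
        else:
            values = lam
        kind = "sc"
    else:
        raise ValueError(f"unknown connectome model {model!r}")

    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(values=values, kind=kind)
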