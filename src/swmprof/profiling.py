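"""Depth-wise intensity profiling on surface stacks.

Assembles depth x vertex profile matrices by trilinear sampling, repairs
outliers with Tukey fences, computes per-depth distribution moments,
smooths per-surface maps with an iterative uniform kernel, and regresses
curvature effects out of profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from swmprof.geometry_io import ScalarVolume, SurfaceMap, TriangleMesh, adjacency_matrix
from swmprof.laplace_swm import SurfaceStack

__all__ = [
    "IntensityProfileMatrix",
    "RegistrationError",
    "sample_volume_to_stack",
    "repair_outliers_tukey",
    "tukey_fences",
    "compute_moments",
    "smooth_surface_map",
    "smooth_profiles",
    "regress_out_curvature",
]


class RegistrationError(ValueError):
    """Raised when a volume and a surface stack disagree on world space."""


@dataclass
class IntensityProfileMatrix:
    """Depth x vertex feature intensities for one subject and modality.

    Rows are ordered by depth (negative = intracortical, 0 = GM/WM
    interface, positive = SWM); columns follow the seed-mesh vertices.
    """

    values: np.ndarray
    depths: np.ndarray
    modality: str = ""
    valid: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("profile values must be 2D (depth x vertex)")
        if len(self.depths) != self.values.shape[0]:
            raise ValueError("one depth per profile row required")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise ValueError("valid flags must match value shape")

    @property
    def n_depths(self) -> int:
        return self.values.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.depths, name="depth_mm"))

    def drop_shallowest(self) -> "IntensityProfileMatrix":
        """Remove the outermost row (partial-volume guard at the CSF/GM side)."""
        return IntensityProfileMatrix(
            values=self.values[1:],
            depths=self.depths[1:],
            modality=self.modality,
            valid=self.valid[1:],
            provenance=dict(self.provenance),
        )


def sample_volume_to_stack(
    stack: SurfaceStack,
    volume: ScalarVolume,
    modality: str = "",
    affine_tolerance: float = 1e-4,
) -> IntensityProfileMatrix:
    """Trilinearly sample a feature volume at every surface of a stack.

    Vertex positions are mapped to voxel coordinates through the inverse
    affine; positions outside the volume and vertices flagged invalid in
    the stack yield NaN.
    """
    stack_affine = stack.provenance.get("affine")
    if stack_affine is not None:
        if np.max(np.abs(np.asarray(stack_affine) - volume.affine)) > affine_tolerance:
            raise RegistrationError("volume affine disagrees with the stack's source affine")

    inv = np.linalg.inv(volume.affine)
    vol = np.asarray(volume.data, dtype=float)
    rows = []
    for mesh in stack.meshes:
        vox = mesh.vertices @ inv[:3, :3].T + inv[:3, 3]
        vals = map_coordinates(vol, vox.T, order=1, mode="constant", cval=np.nan)
        rows.append(vals)
    values = np.asarray(rows)
    values[~stack.valid] = np.nan
    return IntensityProfileMatrix(
        values=values,
        depths=stack.depths,
        modality=modality,
        valid=np.isfinite(values) & stack.valid,
        provenance={"interpolation": "trilinear", "stack": dict(stack.provenance)},
    )


def tukey_fences(values: np.ndarray, k: float = 1.5) -> tuple[float, float]:
    """[Q1 - k IQR, Q3 + k IQR] with linearly interpolated quartiles
    (numpy's default, the 'type 7' convention)."""
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


def repair_outliers_tukey(
    smap: SurfaceMap | np.ndarray,
    mesh: TriangleMesh,
    region_mask: SurfaceMap | np.ndarray | None = None,
    k: float = 1.5,
) -> SurfaceMap:
    """Replace Tukey outliers inside a region by iterated 1-ring neighbour
    interpolation; vertices with no valid neighbour fall back to the region
    median.  Non-outliers are never altered."""
    vals = np.array(smap.values if isinstance(smap, SurfaceMap) else smap, dtype=float)
    if len(vals) != mesh.n_vertices:
        raise ValueError("map length must match mesh")
    if region_mask is None:
        region = np.ones(len(vals), dtype=bool)
    else:
        region = np.asarray(
            region_mask.values if isinstance(region_mask, SurfaceMap) else region_mask
        ).astype(bool)
    if not region.any():
        raise ValueError("region mask is empty")

    in_region = region & np.isfinite(vals)
    if not in_region.any():
        raise ValueError("no finite values in the region")
    lo, hi = tukey_fences(vals[in_region], k=k)
    flagged = in_region & ((vals < lo) | (vals > hi))
    if flagged.sum() == in_region.sum():
        raise ValueError("all values in the region are outliers")

    adj = adjacency_matrix(mesh)
    good = in_region & ~flagged
    out = vals.copy()
    pending = flagged.copy()
    # iterate to closure: each pass fills outliers adjacent to a valid value
    while pending.any():
        donor = np.where(~pending & np.isfinite(out), out, 0.0)
        donor_ok = (~pending & np.isfinite(out)).astype(float)
        nb_sum = adj @ donor
        nb_cnt = adj @ donor_ok
        fill = pending & (nb_cnt > 0)
        if not fill.any():
            out[pending] = np.median(vals[good])  # isolated outliers
            break
        out[fill] = nb_sum[fill] / nb_cnt[fill]
        pending &= ~fill
    return SurfaceMap(values=out, mesh_id=getattr(smap, "mesh_id", ""), units=getattr(smap, "units", ""))


def _row_moments(row: np.ndarray) -> tuple[float, float, float, float, int]:
    x = row[np.isfinite(row)]
    n = len(x)
    if n < 4:
        return np.nan, np.nan, np.nan, np.nan, n
    mean = x.mean()
    d = x - mean
    m2 = np.mean(d**2)
    sd = x.std(ddof=1)
    if m2 <= 0:
        warnings.warn("zero variance: skewness/kurtosis undefined", stacklevel=3)
        return mean, sd, np.nan, np.nan, n
    g1 = np.mean(d**3) / m2**1.5
    g2 = np.mean(d**4) / m2**2 - 3.0
    return mean, sd, g1, g2, n


def compute_moments(profiles: IntensityProfileMatrix | np.ndarray, depths=None) -> pd.DataFrame:
    """Per-depth moments across valid vertices: mean, sample SD (ddof=1),
    Fisher-Pearson skewness g1 = m3/m2^1.5, excess kurtosis g2 = m4/m2^2 - 3.

    Statistics over fewer than 4 valid vertices are NaN.
    """
    if isinstance(profiles, IntensityProfileMatrix):
        values = np.where(profiles.valid, profiles.values, np.nan)
        depths = profiles.depths
    else:
        values = np.asarray(profiles, dtype=float)
        depths = np.arange(values.shape[0]) if depths is None else np.asarray(depths)
    recs = [_row_moments(row) for row in values]
    out = pd.DataFrame(recs, columns=["mean", "sd", "skewness", "kurtosis", "n_valid"])
    out.insert(0, "depth_mm", depths)
    return out


def smooth_surface_map(
    smap: SurfaceMap | np.ndarray,
    mesh: TriangleMesh,
    iterations: int = 5,
    relaxation: float = 0.5,
) -> SurfaceMap:
    """Iterative uniform-kernel smoothing:
    v <- (1 - relaxation) v + relaxation * mean(1-ring neighbours).

    NaN vertices are excluded from neighbour means and stay NaN; isolated
    vertices are unchanged.
    """
    vals = np.array(smap.values if isinstance(smap, SurfaceMap) else smap, dtype=float)
    if len(vals) != mesh.n_vertices:
        raise ValueError("map length must match mesh")
    adj = adjacency_matrix(mesh)
    v = vals.copy()
    for _ in range(iterations):
        finite = np.isfinite(v)
        nb_sum = adj @ np.where(finite, v, 0.0)
        nb_cnt = adj @ finite.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            nb_mean = nb_sum / nb_cnt
        upd = finite & (nb_cnt > 0)
        v = np.where(upd, (1.0 - relaxation) * v + relaxation * nb_mean, v)
    return SurfaceMap(values=v, mesh_id=getattr(smap, "mesh_id", ""), units=getattr(smap, "units", ""))


def smooth_profiles(
    profiles: IntensityProfileMatrix,
    mesh: TriangleMesh,
    iterations: int = 5,
    relaxation: float = 0.5,
) -> IntensityProfileMatrix:
    """Smooth each depth row separately on the seed mesh topology."""
    rows = [
        smooth_surface_map(row, mesh, iterations=iterations, relaxation=relaxation).values
        for row in np.where(profiles.valid, profiles.values, np.nan)
    ]
    values = np.asarray(rows)
    prov = dict(profiles.provenance)
    prov["smoothing"] = {"iterations": iterations, "relaxation": relaxation}
    return IntensityProfileMatrix(
        values=values,
        depths=profiles.depths,
        modality=profiles.modality,
        valid=np.isfinite(values),
        provenance=prov,
    )


def regress_out_curvature(
    profiles: IntensityProfileMatrix,
    curvature: SurfaceMap | np.ndarray,
) -> tuple[IntensityProfileMatrix, pd.DataFrame]:
    """Per depth, ordinary least squares of intensity on curvature; output
    keeps residuals plus the fitted intercept (mean level preserved).

    Returns the corrected profiles and a per-depth slope/intercept table.
    """
    curv = np.asarray(curvature.values if isinstance(curvature, SurfaceMap) else curvature, dtype=float)
    if len(curv) != profiles.n_vertices:
        raise ValueError("curvature length must match profile vertices")
    values = np.where(profiles.valid, profiles.values, np.nan)
    out = values.copy()
    fits = []
    for i, row in enumerate(values):
        ok = np.isfinite(row) & np.isfinite(curv)
        if ok.sum() < 3:
            fits.append((np.nan, np.nan))
            continue
        c = curv[ok]
        if np.ptp(c) < 1e-15:
            warnings.warn("constant curvature: correction is the identity", stacklevel=2)
            fits.append((0.0, float(np.mean(row[ok]))))
            continue
        slope, intercept = np.polyfit(c, row[ok], 1)
        out[i, ok] = row[ok] - slope * c
        fits.append((float(slope), float(intercept)))
    table = pd.DataFrame(fits, columns=["slope", "intercept"])
    table.insert(0, "depth_mm", profiles.depths)
    prov = dict(profiles.provenance)
    prov["curvature_correction"] = "ols per depth"
    return (
        IntensityProfileMatrix(
            values=out,
            depths=profiles.depths,
            modality=profiles.modality,
            valid=np.isfinite(out),
            provenance=prov,
        ),
        table,
    )
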