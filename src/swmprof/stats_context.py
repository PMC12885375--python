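"""Connectivity strength, spatial association and spin permutation inference.

Spin tests rotate one map on a spherical registration mesh with uniform
random rotations (Haar measure, det +1) and reassign values by nearest
original vertex; p-values are two-sided on |rho| with the +1 correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from swmprof.geometry_io import SurfaceMap, TriangleMesh

__all__ = [
    "ConnectivityMatrix",
    "SpinResult",
    "fc_strength",
    "sc_strength",
    "short_range_mask",
    "spin_test",
    "correlate_maps",
    "lowess_trend",
]

_R_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric vertex x vertex connectivity with a zero diagonal.

    kind 'fc' holds correlation coefficients in (-1, 1); kind 'sc' holds
    nonnegative streamline weights.
    """

    values: np.ndarray
    kind: str = "fc"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if self.kind not in ("fc", "sc"):
            raise ValueError(f"unknown connectivity kind {self.kind!r}")
        if self.kind == "sc" and np.any(v < 0):
            raise ValueError("sc weights must be nonnegative")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class SpinResult:
    """Observed Spearman rho, its rotation null and the permutation p."""

    r_observed: float
    null: np.ndarray
    p_spin: float
    n_perm: int
    seed: int
    extras: dict = field(default_factory=dict)


def fc_strength(fc: ConnectivityMatrix) -> SurfaceMap:
    """Node strength: sum over the row of |Fisher z| (|arctanh r|).

    Off-diagonal correlations at |r| >= 1 are clipped with a warning.
    """
    if fc.kind != "fc":
        raise ValueError("fc_strength requires an fc matrix")
    r = fc.values.copy()
    off = ~np.eye(fc.n, dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        import warnings

        warnings.warn("off-diagonal |r| >= 1 clipped before Fisher transform", stacklevel=2)
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.abs(np.arctanh(r))
    np.fill_diagonal(z, 0.0)
    return SurfaceMap(values=z.sum(axis=1), units="|z|")


def sc_strength(sc: ConnectivityMatrix) -> SurfaceMap:
    """Node strength: ln(1 + row sum of streamline weights).

    The +1 guard keeps isolated nodes finite (at strength 0); it is a
    monotone rescaling, so rank-based downstream statistics are unaffected.
    """
    if sc.kind != "sc":
        raise ValueError("sc_strength requires an sc matrix")
    w = sc.values
    if np.any(w < 0):
        raise ValueError("negative streamline weight")
    s = w.sum(axis=1) - np.diag(w)
    return SurfaceMap(values=np.log1p(s), units="ln(1+streamlines)")


def short_range_mask(
    sc: ConnectivityMatrix, geodesic: np.ndarray, threshold: float = 35.0
) -> ConnectivityMatrix:
    """Zero out connections at geodesic distance >= threshold (strictly
    shorter connections are retained)."""
    d = np.asarray(geodesic, dtype=float)
    if d.shape != sc.values.shape:
        raise ValueError("distance matrix shape mismatch")
    values = np.where(d < threshold, sc.values, 0.0)
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(values=values, kind=sc.kind)


def _valid_pair(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.isfinite(a) & np.isfinite(b)


def correlate_maps(
    map_a: SurfaceMap | np.ndarray,
    map_b: SurfaceMap | np.ndarray,
    split: SurfaceMap | np.ndarray | None = None,
    min_class_size: int = 10,
) -> dict:
    """NaN-aware Spearman rho, overall and optionally per split class."""
    a = np.asarray(map_a.values if isinstance(map_a, SurfaceMap) else map_a, dtype=float)
    b = np.asarray(map_b.values if isinstance(map_b, SurfaceMap) else map_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("map lengths differ")
    ok = _valid_pair(a, b)
    rho = stats.spearmanr(a[ok], b[ok]).statistic if ok.sum() >= 3 else np.nan
    out = {"rho": float(rho)}
    if split is not None:
        s = np.asarray(split.values if isinstance(split, SurfaceMap) else split)
        per_class = {}
        for cls in np.unique(s[np.isfinite(s.astype(float))]):
            sel = ok & (s == cls)
            if sel.sum() < min_class_size:
                import warnings

                warnings.warn(f"class {cls}: fewer than {min_class_size} valid vertices", stacklevel=2)
                per_class[cls] = np.nan
            else:
                per_class[cls] = float(stats.spearmanr(a[sel], b[sel]).statistic)
        out["per_class"] = per_class
    return out


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform rotation from QR of a Gaussian matrix, det fixed to +1."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def spin_test(
    map_a: SurfaceMap | np.ndarray,
    map_b: SurfaceMap | np.ndarray,
    sphere: TriangleMesh,
    n_perm: int = 1000,
    seed: int = 0,
) -> SpinResult:
    """Spin permutation test of Spearman(map_a, map_b).

    map_a is rotated on the spherical registration mesh; values are
    reassigned by nearest original vertex.  Two-sided p on |rho|.
    """
    a = np.asarray(map_a.values if isinstance(map_a, SurfaceMap) else map_a, dtype=float)
    b = np.asarray(map_b.values if isinstance(map_b, SurfaceMap) else map_b, dtype=float)
    coords = sphere.vertices - sphere.vertices.mean(axis=0)
    radii = np.linalg.norm(coords, axis=1)
    rmean = radii.mean()
    if rmean <= 0 or (radii.max() - radii.min()) / rmean > 0.02:
        raise ValueError("registration mesh is not spherical (radii vary > 1%)")
    if len(a) != sphere.n_vertices or len(b) != sphere.n_vertices:
        raise ValueError("map length must match the sphere vertex count")

    unit = coords / radii[:, None]
    tree = cKDTree(unit)
    ok = _valid_pair(a, b)
    r_obs = float(stats.spearmanr(a[ok], b[ok]).statistic)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        rot = random_rotation(rng)
        _, nearest = tree.query(unit @ rot.T, workers=1)
        a_rot = a[nearest]
        sel = _valid_pair(a_rot, b)
        null[p] = stats.spearmanr(a_rot[sel], b[sel]).statistic

    p_spin = (1.0 + np.sum(np.abs(null) >= abs(r_obs))) / (1.0 + n_perm)
    return SpinResult(r_observed=r_obs, null=null, p_spin=float(p_spin), n_perm=n_perm, seed=seed)


def lowess_trend(
    x: SurfaceMap | np.ndarray,
    y: SurfaceMap | np.ndarray,
    span: float = 2.0 / 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Locally weighted linear regression (tricube weights, one robustness
    iteration) evaluated at sorted x.  Returns (x_sorted, fitted)."""
    xv = np.asarray(x.values if isinstance(x, SurfaceMap) else x, dtype=float)
    yv = np.asarray(y.values if isinstance(y, SurfaceMap) else y, dtype=float)
    if len(xv) != len(yv):
        raise ValueError("x and y lengths differ")
    ok = _valid_pair(xv, yv)
    if ok.sum() < 20:
        raise ValueError("need at least 20 valid points")
    fit = _sm_lowess(yv[ok], xv[ok], frac=span, it=1, return_sorted=True)
    return fit[:, 0], fit[:, 1]
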