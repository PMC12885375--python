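"""Microstructural profile covariance (MPC) and diffusion-map gradients.

MPC: vertex profiles are rank-transformed over depths, residualized on the
rank-transformed cortex-wide mean profile, pairwise Pearson-correlated
(partial Spearman), clipped and Fisher-z transformed.

Gradients: the MPC is row-sparsified (top 10% by default), converted to a
normalized-angle affinity and embedded with diffusion maps (anisotropic
normalization alpha, diffusion-time-0 component scaling lambda/(1-lambda)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from swmprof.geometry_io import SurfaceMap
from swmprof.profiling import IntensityProfileMatrix

__all__ = [
    "MPCMatrix",
    "GradientSet",
    "compute_mpc",
    "row_sparsify",
    "affinity_normalized_angle",
    "diffusion_embedding",
    "variance_explained",
    "align_gradients",
]

_R_CLIP = 1.0 - 1e-7


@dataclass
class MPCMatrix:
    """V x V log-transformed partial rank correlations, zero diagonal."""

    values: np.ndarray
    mean_profile: np.ndarray
    clip: float = _R_CLIP
    flagged: np.ndarray | None = None  # vertices with degenerate profiles

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("MPC must be square")
        if self.flagged is None:
            self.flagged = ~np.all(np.isfinite(self.values), axis=1)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class GradientSet:
    """Diffusion-map embedding components ("gradients") of an affinity."""

    gradients: np.ndarray  # V x K
    eigenvalues: np.ndarray  # length K, nonincreasing
    variance_explained: np.ndarray  # fractions over retained components
    alpha: float
    sparsity: float | None = None
    provenance: dict = field(default_factory=dict)

    def gradient(self, k: int = 0) -> SurfaceMap:
        return SurfaceMap(values=self.gradients[:, k], units="a.u.")


def compute_mpc(profiles: IntensityProfileMatrix | np.ndarray) -> MPCMatrix:
    """Partial Spearman profile covariance with Fisher-z transform.

    Controls for the cortex-wide average profile on the rank scale (mean of
    the rank-transformed vertex profiles), which makes the matrix exactly
    invariant to monotone transforms of individual vertex profiles.
    Correlations are clipped to |r| <= 1 - 1e-7; diagonal is 0.  Vertices
    with constant or incomplete profiles get NaN rows/columns and are
    flagged.
    """
    x = profiles.values if isinstance(profiles, IntensityProfileMatrix) else np.asarray(profiles, dtype=float)
    d, v = x.shape
    if d < 3:
        raise ValueError("need at least 3 depths")
    if v < 3:
        raise ValueError("need at least 3 vertices")

    complete = np.all(np.isfinite(x), axis=0)
    varying = complete & (np.nanstd(x, axis=0) > 0)
    if not varying.any():
        raise ValueError("no usable vertex profiles")
    if not varying.all():
        warnings.warn(f"{np.sum(~varying)} degenerate vertex profile(s) NaN-flagged", stacklevel=2)

    ranks = np.full_like(x, np.nan)
    ranks[:, varying] = stats.rankdata(x[:, varying], axis=0)
    zr = ranks[:, varying].mean(axis=1)  # average profile on the rank scale

    # residualize rank profiles on [1, ranked mean profile]
    z = np.column_stack([np.ones(d), zr])
    beta, *_ = np.linalg.lstsq(z, np.where(np.isfinite(ranks), ranks, 0.0), rcond=None)
    resid = ranks - z @ beta

    # Pearson over residual columns = partial Spearman
    rc = resid[:, varying] - resid[:, varying].mean(axis=0)
    norms = np.linalg.norm(rc, axis=0)
    degenerate = norms < 1e-12
    norms[degenerate] = 1.0
    rcn = rc / norms
    r_sub = rcn.T @ rcn
    r_sub[degenerate, :] = np.nan
    r_sub[:, degenerate] = np.nan

    r = np.full((v, v), np.nan)
    idx = np.flatnonzero(varying)
    r[np.ix_(idx, idx)] = r_sub

    r = np.clip(r, -_R_CLIP, _R_CLIP)
    mpc = np.arctanh(r)
    np.fill_diagonal(mpc, 0.0)
    mpc = (mpc + mpc.T) / 2.0  # enforce exact symmetry

    flagged = ~varying
    flagged[np.flatnonzero(varying)[degenerate]] = True  # residual fully explained by mean
    return MPCMatrix(values=mpc, mean_profile=zr, flagged=flagged)


def row_sparsify(m: np.ndarray, sparsity: float = 0.9) -> np.ndarray:
    """Keep the top ceil((1 - sparsity) * V) entries per row, ties broken by
    lower column index; zero the rest."""
    m = np.asarray(m, dtype=float)
    v = m.shape[0]
    if not np.all(np.isfinite(m)):
        raise ValueError("sparsification requires a finite matrix (NaN-flagged vertices present?)")
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must be in [0, 1)")
    k = int(np.ceil((1.0 - sparsity) * v))
    out = np.zeros_like(m)
    order = np.argsort(-m, axis=1, kind="stable")  # stable: ties -> lower index first
    rows = np.repeat(np.arange(v), k)
    cols = order[:, :k].ravel()
    out[rows, cols] = m[rows, cols]
    return out


def affinity_normalized_angle(mpc: MPCMatrix | np.ndarray, sparsity: float = 0.9) -> np.ndarray:
    """Row-wise top-k sparsification followed by the normalized-angle
    (cosine-arc) kernel: a_ij = 1 - arccos(cos(x_i, x_j)) / pi.

    k = ceil((1 - sparsity) * V) entries are kept per row, ties broken by
    lower column index.  Diagonal is 1.
    """
    m = mpc.values if isinstance(mpc, MPCMatrix) else np.asarray(mpc, dtype=float)
    sparsified = row_sparsify(m, sparsity)
    norms = np.linalg.norm(sparsified, axis=1)
    zero_rows = np.flatnonzero(norms == 0)
    if zero_rows.size:
        raise ValueError(f"all-zero row(s) after sparsification at vertices {zero_rows.tolist()}")

    cos = (sparsified @ sparsified.T) / np.outer(norms, norms)
    ang = np.arccos(np.clip(cos, -1.0, 1.0))
    aff = 1.0 - ang / np.pi
    np.fill_diagonal(aff, 1.0)
    return aff


def diffusion_embedding(
    affinity: np.ndarray,
    alpha: float = 0.5,
    n_components: int = 10,
    sparsity: float | None = None,
) -> GradientSet:
    """Diffusion map embedding of a symmetric nonnegative affinity.

    Anisotropic normalization W = D^-alpha A D^-alpha, Markov operator
    P = row-normalized W; the trivial stationary eigenvector (eigenvalue 1)
    is dropped; component k is psi_k * lambda_k / (1 - lambda_k)
    (diffusion-time-0 scaling).  Component sign is fixed so the first
    loading above tolerance is positive.
    """
    a = np.asarray(affinity, dtype=float)
    v = a.shape[0]
    if a.ndim != 2 or a.shape[1] != v:
        raise ValueError("affinity must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    if np.any(a < 0):
        raise ValueError("affinity must be nonnegative")

    n_comp_graph, labels = connected_components(sparse.csr_matrix(a > 0), directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(labels)
        raise ValueError(f"affinity graph is disconnected: component sizes {sizes.tolist()}")

    deg = a.sum(axis=1)
    d_alpha = deg**-alpha
    w = a * np.outer(d_alpha, d_alpha)

    dw = w.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(dw)
    s = w * np.outer(inv_sqrt, inv_sqrt)  # symmetric conjugate of the Markov operator

    n_eig = min(n_components + 1, v)
    if v <= 1200:
        from scipy.linalg import eigh

        evals, evecs = eigh(s)
        evals, evecs = evals[::-1][:n_eig], evecs[:, ::-1][:, :n_eig]
    else:
        from scipy.sparse.linalg import eigsh

        evals, evecs = eigsh(s, k=n_eig, which="LA")
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]

    psi = evecs * inv_sqrt[:, None]  # right eigenvectors of P
    # normalize against the stationary distribution: psi_0 should be constant
    psi = psi / np.linalg.norm(psi, axis=0)

    # drop the trivial component: eigenvalue closest to 1 with ~constant loadings
    trivial = int(np.argmin(np.abs(evals - 1.0)))
    if np.ptp(psi[:, trivial]) > 1e-6 * max(1.0, np.abs(psi[:, trivial]).max()):
        warnings.warn("top eigenvector is not constant; dropping it as trivial anyway", stacklevel=2)
    keep = [i for i in range(len(evals)) if i != trivial][: n_components]

    lam = evals[keep]
    comps = psi[:, keep] * (lam / (1.0 - lam))[None, :]

    # deterministic sign: first loading with magnitude above tolerance positive
    for k in range(comps.shape[1]):
        col = comps[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            comps[:, k] = -col

    frac = lam / lam.sum() if lam.sum() > 0 else np.full(len(lam), np.nan)
    return GradientSet(
        gradients=comps,
        eigenvalues=lam,
        variance_explained=frac,
        alpha=alpha,
        sparsity=sparsity,
        provenance={"n_components": n_components, "scaling": "lambda/(1-lambda)"},
    )


def variance_explained(gset: GradientSet) -> np.ndarray:
    """Eigenvalue fractions over the retained non-trivial components."""
    lam = np.asarray(gset.eigenvalues, dtype=float)
    return lam / lam.sum()


def align_gradients(
    g_ref: SurfaceMap | np.ndarray, g_other: SurfaceMap | np.ndarray
) -> tuple[SurfaceMap, float]:
    """Resolve eigenvector sign ambiguity: flip g_other if its Pearson
    correlation with g_ref is negative; return the aligned map and r."""
    a = np.asarray(g_ref.values if isinstance(g_ref, SurfaceMap) else g_ref, dtype=float)
    b = np.asarray(g_other.values if isinstance(g_other, SurfaceMap) else g_other, dtype=float)
    if len(a) != len(b):
        raise ValueError("gradient maps must share vertex count")
    ok = np.isfinite(a) & np.isfinite(b)
    if np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
        raise ValueError("zero-variance gradient map")
    r = float(np.corrcoef(a[ok], b[ok])[0, 1])
    if r < 0:
        b = -b
        r = -r
    return SurfaceMap(values=b, units="a.u."), r
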