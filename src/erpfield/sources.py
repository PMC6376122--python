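"""Distributed EEG source localization on a concentric-sphere head model.

The forward model is the classical three-shell (brain / skull / scalp)
concentric-sphere conductor: for each spherical-harmonic order the radial
solution in every shell is ``A r^n + B r^-(n+1)``, matched for potential and
radial current at the interfaces, with zero current through the scalp
surface.  Dipole potentials follow from the Legendre expansion of the
source term, truncated at a configurable order.

The inverse is a distributed linear estimator with LAURA (Local
Auto-Regressive Average) regularization: a local autoregressive operator A
with inverse-squared-distance weights over the 26-neighborhood defines the
source-space metric M = (A^T A)^-1, and the estimator is
``G = M L^T (L M L^T + lambda^2 I)^-1``.  Group statistics contrast
RMS-normalized current-density magnitudes voxel-wise with paired t-tests,
keeping only clusters of contiguous significant solution points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse import coo_matrix, csc_matrix, identity
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

from .containers import EvokedMap
from .montage import ElectrodeMontage

__all__ = [
    "HeadModel",
    "SolutionGrid",
    "LeadField",
    "InverseOperator",
    "SourceEstimate",
    "VoxelCluster",
    "VoxelStatReport",
    "build_solution_grid",
    "compute_leadfield",
    "build_laura_operator",
    "apply_inverse",
    "rms_normalize",
    "voxelwise_ttest",
]


@dataclass(frozen=True)
class HeadModel:
    """Concentric three-shell conductor, radii as fractions of head radius."""

    radii: tuple[float, float, float] = (0.87, 0.92, 1.0)
    conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)
    n_terms: int = 60

    def __post_init__(self):
        r = self.radii
        if not (0 < r[0] < r[1] < r[2] == 1.0):
            raise ValueError("shell radii must increase strictly, outermost = 1")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")


@dataclass(frozen=True)
class SolutionGrid:
    """Cubic lattice of solution points inside the brain shell."""

    points: np.ndarray  # P x 3, head-radius units
    spacing: float
    neighbors: tuple  # tuple of int arrays, 26-neighborhood, symmetric

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class LeadField:
    """Forward gains, points x 3 dipole components x channels (average ref)."""

    gain: np.ndarray
    ch_names: tuple[str, ...]


@dataclass(frozen=True)
class InverseOperator:
    """LAURA inverse operator; ``apply`` maps a scalp vector to P x 3 currents."""

    Y: tuple  # per-component (P x C) arrays: M L^T
    gram_factor: object  # Cholesky factor of (L M L^T + lambda^2 I)
    lambda2: float

    def apply(self, scalp_map: np.ndarray) -> np.ndarray:
        v = np.asarray(scalp_map, dtype=float)
        v = v - v.mean()  # operator is built in average reference
        z = cho_solve(self.gram_factor, v)
        return np.stack([Yc @ z for Yc in self.Y], axis=1)


@dataclass(frozen=True)
class SourceEstimate:
    """Current-density vectors and magnitudes on the solution grid."""

    values: np.ndarray  # P x 3
    magnitudes: np.ndarray  # P
    participant: str = ""
    condition: str = ""
    window_ms: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class VoxelCluster:
    members: tuple[int, ...]
    size: int
    sign: int
    peak_t: float
    peak_point: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {"size": self.size, "sign": self.sign, "peak_t": self.peak_t,
                "peak_point": list(self.peak_point), "members": list(self.members)}


@dataclass(frozen=True)
class VoxelStatReport:
    t: np.ndarray
    p: np.ndarray
    critical_t: float
    clusters: tuple[VoxelCluster, ...]
    subthreshold_clusters: tuple[VoxelCluster, ...]

    def to_json_dict(self) -> dict:
        return {
            "critical_t": self.critical_t,
            "clusters": [c.to_dict() for c in self.clusters],
            "subthreshold_clusters": [c.to_dict() for c in self.subthreshold_clusters],
        }


def build_solution_grid(spacing: float, brain_radius: float = 0.85) -> SolutionGrid:
    """Regular cubic lattice clipped strictly inside the brain sphere.

    Point count approximates (4/3) pi (brain_radius / spacing)^3; fewer than
    30 points is treated as a degenerate configuration.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    m = int(np.floor(brain_radius / spacing))
    ax = np.arange(-m, m + 1)
    I, J, K = np.meshgrid(ax, ax, ax, indexing="ij")
    idx = np.c_[I.ravel(), J.ravel(), K.ravel()]
    pts = spacing * idx.astype(float)
    keep = np.linalg.norm(pts, axis=1) < brain_radius
    idx, pts = idx[keep], pts[keep]
    if len(pts) < 30:
        raise ValueError(f"grid too coarse: only {len(pts)} points inside the brain shell")
    lookup = {tuple(v): k for k, v in enumerate(idx)}
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    neighbors = []
    for v in idx:
        nb = [lookup[key] for o in offsets
              if (key := (v[0] + o[0], v[1] + o[1], v[2] + o[2])) in lookup]
        neighbors.append(np.array(sorted(nb), dtype=int))
    return SolutionGrid(points=pts, spacing=spacing, neighbors=tuple(neighbors))


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def _shell_transfer(head: HeadModel, n_max: int) -> np.ndarray:
    """Outer-surface factor O_n for a unit r^-(n+1) source term in the brain.

    Solves, per harmonic order n, the 5x5 interface system for the three
    shells with an insulating outer boundary, and returns the potential
    factor at r = 1.
    """
    r1, r2, _ = head.radii
    s1, s2, s3 = head.conductivities
    out = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        # unknowns: A1, A2, B2, A3, B3
        M = np.zeros((5, 5))
        rhs = np.zeros(5)
        # continuity of V at r1 (source term S r^-(n+1) moved to rhs)
        M[0] = [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0.0, 0.0]
        rhs[0] = -(r1 ** -(n + 1))
        # continuity of radial current at r1
        M[1] = [s1 * n * r1 ** (n - 1),
                -s2 * n * r1 ** (n - 1),
                s2 * (n + 1) * r1 ** -(n + 2), 0.0, 0.0]
        rhs[1] = s1 * (n + 1) * r1 ** -(n + 2)
        # continuity of V at r2
        M[2] = [0.0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))]
        # continuity of radial current at r2
        M[3] = [0.0, s2 * n * r2 ** (n - 1), -s2 * (n + 1) * r2 ** -(n + 2),
                -s3 * n * r2 ** (n - 1), s3 * (n + 1) * r2 ** -(n + 2)]
        # insulating outer boundary at r = 1
        M[4] = [0.0, 0.0, 0.0, n, -(n + 1)]
        sol = np.linalg.solve(M, rhs)
        out[n] = sol[3] + sol[4]  # A3 + B3 at r = 1 (source folded into B3)
    return out


def _legendre_pair(x: np.ndarray, n_max: int):
    """P_n(x) and P_n'(x) for n = 0..n_max, stacked along a new first axis."""
    P = np.empty((n_max + 1,) + x.shape)
    dP = np.empty_like(P)
    P[0] = 1.0
    dP[0] = 0.0
    if n_max >= 1:
        P[1] = x
        dP[1] = 1.0
    for n in range(1, n_max):
        P[n + 1] = ((2 * n + 1) * x * P[n] - n * P[n - 1]) / (n + 1)
        dP[n + 1] = dP[n - 1] + (2 * n + 1) * P[n] if n >= 1 else 3.0 * x
    return P, dP


def dipole_potential_homogeneous(dipole_pos, dipole_moment, electrodes,
                                 sigma: float = 0.33, n_terms: int = 200) -> np.ndarray:
    """Closed-form-limit potential of a dipole in a homogeneous unit sphere.

    Series with the exact single-sphere harmonic factor (2n+1)/n; used as the
    homogeneous-conductor reference for the multi-shell solver.
    """
    coeff = np.zeros(n_terms + 1)
    coeff[1:] = (2.0 * np.arange(1, n_terms + 1) + 1.0) / np.arange(1, n_terms + 1)
    return _dipole_series(dipole_pos, dipole_moment, electrodes, sigma, coeff)


def _dipole_series(dipole_pos, dipole_moment, electrodes, sigma_brain, O) -> np.ndarray:
    """Evaluate the dipole Legendre series with outer-surface factors ``O``."""
    r0 = np.asarray(dipole_pos, dtype=float)
    p = np.asarray(dipole_moment, dtype=float)
    E = np.asarray(electrodes, dtype=float)
    b = np.linalg.norm(r0)
    rhat = r0 / b if b > 0 else np.array([0.0, 0.0, 1.0])
    ehat = E / np.linalg.norm(E, axis=1, keepdims=True)
    cosg = np.clip(ehat @ rhat, -1.0, 1.0)
    n_max = len(O) - 1
    P, dP = _legendre_pair(cosg, n_max)
    ns = np.arange(n_max + 1, dtype=float)
    with np.errstate(divide="ignore"):
        bpow = np.where(ns >= 1, b ** (ns - 1), 0.0)
    if b == 0:
        bpow = np.zeros(n_max + 1)
        if n_max >= 1:
            bpow[1] = 1.0
    mr = p @ rhat
    mt_vec = ehat - cosg[:, None] * rhat[None, :]  # per electrode
    mt = mt_vec @ p
    V = np.zeros(len(E))
    for n in range(1, n_max + 1):
        V += O[n] * bpow[n] * (n * mr * P[n] + mt * dP[n])
    return V / (4.0 * np.pi * sigma_brain)


def compute_leadfield(grid: SolutionGrid, montage: ElectrodeMontage,
                      head: HeadModel = HeadModel()) -> LeadField:
    """Analytic three-shell gains for unit dipoles along x, y, z at each point.

    Electrode positions are taken as the montage's retained unit vectors
    (scalp surface); each gain column is average-referenced.
    """
    r_brain = head.radii[0]
    if np.any(np.linalg.norm(grid.points, axis=1) >= r_brain):
        raise ValueError("solution points must lie strictly inside the brain shell")
    E = montage.retained_positions()
    O = _shell_transfer(head, head.n_terms)
    n_max = head.n_terms
    # vectorized over points x electrodes
    b = np.linalg.norm(grid.points, axis=1)  # P
    rhat = np.where(b[:, None] > 0, grid.points / np.where(b[:, None] == 0, 1.0, b[:, None]),
                    np.array([0.0, 0.0, 1.0]))
    cosg = np.clip(rhat @ E.T, -1.0, 1.0)  # P x C
    P_, dP_ = _legendre_pair(cosg, n_max)  # (n+1) x P x C
    ns = np.arange(n_max + 1, dtype=float)
    bpow = np.zeros((n_max + 1, len(b)))
    nz = b > 0
    for n in range(1, n_max + 1):
        bpow[n, nz] = b[nz] ** (n - 1)
        bpow[n, ~nz] = 1.0 if n == 1 else 0.0
    # radial kernel a = sum O_n b^{n-1} n P_n ; tangential kernel g = sum O_n b^{n-1} P_n'
    a = np.einsum("n,np,npc->pc", O * ns, bpow, P_)
    g = np.einsum("n,np,npc->pc", O, bpow, dP_)
    # V = [a * rhat + g * (ehat - cosg*rhat)] . p / (4 pi sigma1)
    sigma1 = head.conductivities[0]
    gain = (
        a[:, :, None] * rhat[:, None, :]
        + g[:, :, None] * (E[None, :, :] - cosg[:, :, None] * rhat[:, None, :])
    ) / (4.0 * np.pi * sigma1)
    gain = np.transpose(gain, (0, 2, 1))  # P x 3 x C
    gain = gain - gain.mean(axis=2, keepdims=True)  # average reference
    return LeadField(gain=gain, ch_names=montage.retained)


# ---------------------------------------------------------------------------
# LAURA inverse
# ---------------------------------------------------------------------------


def _laura_matrix(grid: SolutionGrid, exponent: float) -> csc_matrix:
    rows, cols, vals = [], [], []
    pts = grid.points
    for i, nb in enumerate(grid.neighbors):
        if len(nb) == 0:
            rows.append(i)
            cols.append(i)
            vals.append(1.0)
            continue
        d = np.linalg.norm(pts[nb] - pts[i], axis=1)
        w = d ** (-exponent)
        rows.append(i)
        cols.append(i)
        vals.append((26.0 / len(nb)) * w.sum())
        rows.extend([i] * len(nb))
        cols.extend(nb.tolist())
        vals.extend((-w).tolist())
    return csc_matrix(coo_matrix((vals, (rows, cols)),
                                 shape=(grid.n_points, grid.n_points)))


def build_laura_operator(leadfield: LeadField, grid: SolutionGrid,
                         exponent: float = 2.0,
                         lambda_frac: float = 0.01) -> InverseOperator:
    """LAURA-regularized linear inverse operator.

    The local autoregressive matrix A (diagonal ``(26/|N_i|) sum_k d_ik^-e``,
    off-diagonal ``-d_ij^-e`` over the 26-neighborhood) defines the source
    metric ``M = (A^T A)^-1``, applied blockwise per Cartesian component; the
    operator is ``G = M L^T (L M L^T + lambda^2 I)^-1`` with
    ``lambda^2 = lambda_frac x mean diag(L M L^T)``.
    """
    if exponent <= 0:
        raise ValueError("LAURA weight exponent must be positive")
    if leadfield.gain.shape[0] != grid.n_points:
        raise ValueError("lead field and grid are inconsistent")
    A = _laura_matrix(grid, exponent)
    AtA = (A.T @ A).tocsc()
    try:
        lu = splu(AtA)
    except RuntimeError:  # singular; stabilize with a small ridge
        import logging

        logging.getLogger(__name__).warning("A^T A singular; adding ridge")
        lu = splu((AtA + 1e-8 * identity(grid.n_points, format="csc")).tocsc())
    C = leadfield.gain.shape[2]
    Y, LML = [], np.zeros((C, C))
    for comp in range(3):
        Lc = leadfield.gain[:, comp, :].T  # C x P
        Yc = lu.solve(Lc.T)  # P x C  (= M_c L_c^T)
        Y.append(Yc)
        LML += Lc @ Yc
    lam2 = lambda_frac * float(np.trace(LML)) / C
    factor = cho_factor(LML + lam2 * np.eye(C))
    return InverseOperator(Y=tuple(Y), gram_factor=factor, lambda2=lam2)


def apply_inverse(evoked: EvokedMap, window_ms, operator: InverseOperator) -> SourceEstimate:
    """Estimate sources from the time-averaged scalp map of a window.

    The evoked data are averaged over ``window_ms`` (a single scalp map per
    participant and condition), the operator is applied, and per-point
    magnitudes are the Euclidean norms of the current 3-vectors.
    """
    lo, hi = window_ms
    times = evoked.times_ms
    sel = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    if not sel.any():
        raise ValueError("empty source-estimation window")
    scalp = evoked.data[:, sel].mean(axis=1)
    values = operator.apply(scalp)
    return SourceEstimate(
        values=values, magnitudes=np.linalg.norm(values, axis=1),
        participant=evoked.participant, condition=evoked.condition,
        window_ms=(float(lo), float(hi)),
    )


def rms_normalize(estimate: SourceEstimate) -> SourceEstimate:
    """Scale magnitudes (and vectors) so the RMS over solution points is 1."""
    rms = float(np.sqrt(np.mean(estimate.magnitudes**2)))
    if rms == 0:
        raise ValueError("cannot normalize an all-zero estimate")
    return replace(estimate, values=estimate.values / rms,
                   magnitudes=estimate.magnitudes / rms)


def _contiguity_clusters(members: np.ndarray, grid: SolutionGrid) -> list:
    if len(members) == 0:
        return []
    index_of = {int(m): k for k, m in enumerate(members)}
    rows, cols = [], []
    for k, m in enumerate(members):
        for nb in grid.neighbors[int(m)]:
            j = index_of.get(int(nb))
            if j is not None and j > k:
                rows.append(k)
                cols.append(j)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)),
                       shape=(len(members), len(members)))
    n_comp, labels = connected_components(graph, directed=False)
    return [members[labels == c] for c in range(n_comp)]


def voxelwise_ttest(estimates_a, estimates_b, grid: SolutionGrid,
                    alpha: float = 0.01, min_cluster: int = 10) -> VoxelStatReport:
    """Voxel-wise paired t-test on normalized magnitudes with contiguity.

    Points with two-tailed p < alpha (|t| above the critical value, 2.88 for
    19 participants at alpha 0.01) are grouped by 26-neighborhood contiguity
    separately per sign; clusters of at least ``min_cluster`` points form the
    main report, smaller ones are listed separately as sub-threshold (the
    convention that a 9-point cluster misses a 10-point cut-off but is still
    reported).
    """
    pa = {e.participant: e for e in estimates_a}
    pb = {e.participant: e for e in estimates_b}
    if set(pa) != set(pb):
        raise ValueError("participant sets differ between conditions")
    pids = sorted(pa)
    n = len(pids)
    if n < 2:
        raise ValueError("need at least 2 participants")
    D = np.stack([pa[p].magnitudes - pb[p].magnitudes for p in pids])
    mean = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.nan_to_num(t, nan=0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    crit = float(stats.t.ppf(1.0 - alpha / 2.0, df=n - 1))

    main, sub = [], []
    for sign in (+1, -1):
        sig = np.flatnonzero(sign * t > crit)
        for members in _contiguity_clusters(sig, grid):
            tv = t[members]
            k = int(np.argmax(np.abs(tv)))
            cl = VoxelCluster(
                members=tuple(int(m) for m in members), size=len(members),
                sign=sign, peak_t=float(tv[k]),
                peak_point=tuple(float(x) for x in grid.points[members[k]]),
            )
            (main if len(members) >= min_cluster else sub).append(cl)
    key = lambda c: -abs(c.peak_t)
    return VoxelStatReport(t=t, p=p, critical_t=crit,
                           clusters=tuple(sorted(main, key=key)),
                           subthreshold_clusters=tuple(sorted(sub, key=key)))
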