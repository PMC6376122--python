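"""Sensor geometry: electrode montages on the unit sphere.

A high-density EEG net is modeled as labeled points on a unit sphere in the
head frame (+x right, +y anterior, +z superior).  The montage carries an
exclusion set (the outermost belt of a geodesic net is conventionally dropped
before analysis), a nine-region cluster map (anterior/central/posterior x
left/midline/right) used by the spatial-extent criterion of the
mass-univariate statistics, and an adjacency graph defined by an angular
threshold.

Bad-channel repair uses spherical-spline interpolation (Perrin et al. style):
the potential field is expanded in surface splines built from Legendre
polynomials and re-evaluated at the bad sites.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = [
    "ElectrodeMontage",
    "BUILTIN_LAYOUT",
    "PERIPHERAL_BELT",
    "CLUSTER_NAMES",
    "build_montage",
    "make_cap_montage",
    "apply_exclusion",
    "compute_adjacency",
    "assign_clusters",
    "interpolate_bad_channels",
]

#: Name of the built-in 129-channel geodesic layout (128 sensors + vertex).
BUILTIN_LAYOUT = "GSN-HydroCel-129"

#: The 19 peripheral channels of the outermost belt of the 128-channel
#: geodesic sensor net, conventionally discarded (channel reduction 128->110).
PERIPHERAL_BELT = frozenset(
    {
        "E43", "E48", "E49", "E56", "E63", "E68", "E73", "E81", "E88", "E94",
        "E99", "E107", "E113", "E119", "E120", "E125", "E126", "E127", "E128",
    }
)

CLUSTER_NAMES = ("AL", "AM", "AR", "CL", "CM", "CR", "PL", "PM", "PR")

#: Default angular threshold (degrees) defining electrode adjacency; chosen
#: so the retained 110-channel built-in montage has mean degree close to 6.
DEFAULT_ADJACENCY_DEG = 26.0

#: Default half-width of the midline / central bands of the 3x3 cluster
#: partition, in unit-sphere coordinates.
DEFAULT_MIDLINE_BAND = 0.25


@dataclass(frozen=True)
class ElectrodeMontage:
    """Labeled sensor geometry on the unit sphere.

    Attributes
    ----------
    labels : tuple of str
        Ordered channel names.
    positions : ndarray, shape (n_channels, 3)
        Unit-norm head-frame coordinates, row-aligned with ``labels``.
    excluded : frozenset of str
        Channels excluded from analysis (subset of ``labels``).
    clusters : dict
        Retained label -> one of the nine region codes ``AL..PR`` (empty for
        montages too small to partition).
    adjacency : frozenset of (str, str)
        Symmetric, irreflexive neighbor relation over retained labels,
        stored as sorted label pairs.
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    excluded: frozenset = frozenset()
    clusters: dict = field(default_factory=dict)
    adjacency: frozenset = frozenset()

    @property
    def retained(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if l not in self.excluded)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def position_of(self, label: str) -> np.ndarray:
        return self.positions[self.index(label)]

    def retained_positions(self) -> np.ndarray:
        keep = [i for i, l in enumerate(self.labels) if l not in self.excluded]
        return self.positions[keep]

    def neighbors(self, label: str) -> set:
        out = set()
        for a, b in self.adjacency:
            if a == label:
                out.add(b)
            elif b == label:
                out.add(a)
        return out

    def adjacency_matrix(self) -> np.ndarray:
        """Boolean adjacency matrix over retained labels (retained order)."""
        ret = self.retained
        idx = {l: i for i, l in enumerate(ret)}
        mat = np.zeros((len(ret), len(ret)), dtype=bool)
        for a, b in self.adjacency:
            if a in idx and b in idx:
                mat[idx[a], idx[b]] = True
                mat[idx[b], idx[a]] = True
        return mat

    def validate(self) -> None:
        """Raise ``ValueError`` if a structural invariant is violated."""
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("positions must lie on the unit sphere")
        if not self.excluded <= set(self.labels):
            raise ValueError("excluded set contains unknown labels")
        if self.clusters:
            missing = set(self.retained) - set(self.clusters)
            if missing:
                raise ValueError(f"cluster map misses labels: {sorted(missing)}")
        for a, b in self.adjacency:
            if a == b:
                raise ValueError("adjacency must be irreflexive")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": list(self.labels),
            "positions": self.positions.tolist(),
            "excluded": sorted(self.excluded),
            "clusters": dict(self.clusters),
            "adjacency": sorted(map(list, self.adjacency)),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ElectrodeMontage":
        d = json.loads(Path(path).read_text())
        return cls(
            labels=tuple(d["labels"]),
            positions=np.asarray(d["positions"], dtype=float),
            excluded=frozenset(d["excluded"]),
            clusters=dict(d["clusters"]),
            adjacency=frozenset(tuple(p) for p in d["adjacency"]),
        )


def _fit_sphere_center(points: np.ndarray) -> np.ndarray:
    """Least-squares center of the sphere best fitting ``points``."""
    A = np.c_[2.0 * points, np.ones(len(points))]
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


def _load_builtin() -> tuple[tuple[str, ...], np.ndarray]:
    import mne

    std = mne.channels.make_standard_montage(BUILTIN_LAYOUT)
    pos = std.get_positions()["ch_pos"]
    labels = tuple(pos)
    pts = np.array([pos[l] for l in labels], dtype=float)
    # head-frame coordinates are in meters; re-center on the best-fit sphere
    pts = pts - _fit_sphere_center(pts)
    return labels, pts


def _load_position_file(path: Path) -> tuple[tuple[str, ...], np.ndarray]:
    labels, rows = [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"expected 'label x y z', got: {line!r}")
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    return tuple(labels), np.asarray(rows, dtype=float)


def build_montage(
    layout_spec: str | Path = BUILTIN_LAYOUT,
    *,
    adjacency_deg: float = DEFAULT_ADJACENCY_DEG,
    midline_band: float = DEFAULT_MIDLINE_BAND,
) -> ElectrodeMontage:
    """Build a montage from the built-in layout name or a position text file.

    Position files are whitespace-delimited, one ``label x y z`` per line
    (.sfp style); every position is normalized to the unit sphere on load.
    Montages with at least 9 channels get the 3x3 cluster partition; smaller
    ones keep an empty cluster map.
    """
    if isinstance(layout_spec, str) and layout_spec == BUILTIN_LAYOUT:
        labels, pts = _load_builtin()
    else:
        labels, pts = _load_position_file(Path(layout_spec))

    if len(labels) != len(set(labels)):
        raise ValueError("duplicate channel labels in layout")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates in layout")
    if len(labels) < 3:
        raise ValueError("montage needs at least 3 channels")

    norms = np.linalg.norm(pts, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length position vector")
    pts = pts / norms[:, None]

    mont = ElectrodeMontage(labels=labels, positions=pts)
    mont = replace(mont, adjacency=compute_adjacency(mont, adjacency_deg))
    if len(labels) >= 9:
        mont = replace(mont, clusters=assign_clusters(mont, midline_band=midline_band))
    return mont


def make_cap_montage(n_channels: int, *, coverage_deg: float = 120.0) -> ElectrodeMontage:
    """Quasi-uniform spherical-cap layout (Fibonacci lattice), labels C1..Cn.

    A small synthetic stand-in for a real net, handy for examples and
    fast tests; the cap spans polar angles 0..``coverage_deg``.
    """
    if n_channels < 3:
        raise ValueError("need at least 3 channels")
    k = np.arange(n_channels)
    zmin = math.cos(math.radians(coverage_deg))
    z = 1.0 - (1.0 - zmin) * (k + 0.5) / n_channels
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pts = np.c_[r * np.cos(phi), r * np.sin(phi), z]
    labels = tuple(f"C{i+1}" for i in range(n_channels))
    mont = ElectrodeMontage(labels=labels, positions=pts)
    # denser caps need a tighter angular threshold to keep degree moderate
    spacing = math.degrees(2.0 * math.asin(min(1.0, math.sqrt(2.0 * (1.0 - zmin) / n_channels))))
    mont = replace(mont, adjacency=compute_adjacency(mont, max(10.0, 1.6 * spacing)))
    if n_channels >= 9:
        mont = replace(mont, clusters=assign_clusters(mont))
    return mont


def apply_exclusion(montage: ElectrodeMontage, excluded=PERIPHERAL_BELT) -> ElectrodeMontage:
    """Mark channels as excluded and recompute adjacency/clusters on the rest.

    The default exclusion set is the 19-channel peripheral belt, which takes
    the built-in 129-channel layout (vertex included) down to 110 analyzed
    channels.  Applying the same exclusion twice is a no-op.
    """
    excluded = frozenset(excluded)
    unknown = excluded - set(montage.labels)
    if unknown:
        raise ValueError(f"unknown labels in exclusion set: {sorted(unknown)}")
    out = replace(montage, excluded=excluded)
    out = replace(out, adjacency=compute_adjacency(out, DEFAULT_ADJACENCY_DEG))
    if len(out.retained) >= 9:
        out = replace(out, clusters=assign_clusters(out))
    else:
        out = replace(out, clusters={})
    return out


def compute_adjacency(montage: ElectrodeMontage, angular_threshold_deg: float = DEFAULT_ADJACENCY_DEG) -> frozenset:
    """Neighbor relation: central angle between retained sensors <= threshold."""
    if not 0.0 < angular_threshold_deg < 180.0:
        raise ValueError("angular threshold must be in (0, 180) degrees")
    ret = montage.retained
    pts = montage.retained_positions()
    cosang = np.clip(pts @ pts.T, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    pairs = set()
    n = len(ret)
    for i in range(n):
        for j in range(i + 1, n):
            if ang[i, j] <= angular_threshold_deg:
                pairs.add(tuple(sorted((ret[i], ret[j]))))
    return frozenset(pairs)


def assign_clusters(montage: ElectrodeMontage, *, midline_band: float = DEFAULT_MIDLINE_BAND) -> dict:
    """3x3 partition of retained channels by anterior-posterior and left-right.

    ``y > band`` anterior, ``y < -band`` posterior, else central; same bands
    on ``x`` for right/left/midline.  Every retained channel is assigned
    exactly one of AL, AM, AR, CL, CM, CR, PL, PM, PR.
    """
    ret = montage.retained
    if len(ret) < 9:
        raise ValueError("cluster partition needs at least 9 retained channels")
    pts = montage.retained_positions()
    out = {}
    for label, (x, y, _z) in zip(ret, pts):
        ap = "A" if y > midline_band else ("P" if y < -midline_band else "C")
        lr = "R" if x > midline_band else ("L" if x < -midline_band else "M")
        out[label] = ap + lr
    return out


# ---------------------------------------------------------------------------
# Spherical-spline interpolation (Perrin-style)
# ---------------------------------------------------------------------------

#: Spline smoothing order m, Legendre-series truncation, and ridge term of
#: the spline system -- conventional values for scalp-potential interpolation.
SPLINE_ORDER = 4
SPLINE_TERMS = 7
SPLINE_RIDGE = 1e-5


def _spline_g(cosang: np.ndarray, m: int = SPLINE_ORDER, n_terms: int = SPLINE_TERMS) -> np.ndarray:
    """g(x) = (1/4pi) sum_n (2n+1) / (n(n+1))^m  P_n(x), n = 1..n_terms."""
    coeffs = np.zeros(n_terms + 1)
    for n in range(1, n_terms + 1):
        coeffs[n] = (2 * n + 1) / (n * (n + 1)) ** m
    return npleg.legval(np.clip(cosang, -1.0, 1.0), coeffs) / (4.0 * np.pi)


def spline_interpolation_matrix(
    good_pos: np.ndarray, bad_pos: np.ndarray
) -> np.ndarray:
    """Matrix W such that ``v_bad = W @ v_good`` under the spherical spline."""
    k = len(good_pos)
    if k < 4:
        raise ValueError("need at least 4 good channels for spline interpolation")
    G = _spline_g(good_pos @ good_pos.T)
    G = G + SPLINE_RIDGE * np.eye(k)
    Gb = _spline_g(bad_pos @ good_pos.T)
    # bordered system [[G, 1], [1^T, 0]] enforces the zero-mean constraint
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = G
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    # columns of rhs select each good channel in turn -> W acts on any field
    rhs = np.zeros((k + 1, k))
    rhs[:k, :k] = np.eye(k)
    sol = np.linalg.solve(A, rhs)  # rows: spline weights c (k) then offset c0
    return Gb @ sol[:k] + sol[k][None, :]


def interpolate_bad_channels(epochs, montage: ElectrodeMontage, bad) -> "EpochsArray":
    """Replace bad-channel samples by spherical-spline estimates.

    Good channels are passed through bit-for-bit.  ``bad`` labels outside the
    epochs' channel set are ignored; an empty effective set returns the input
    unchanged.
    """
    bad = set(bad) & set(epochs.ch_names)
    if not bad:
        return epochs
    if bad >= set(epochs.ch_names):
        raise ValueError("cannot interpolate: all channels marked bad")
    good = [c for c in epochs.ch_names if c not in bad]
    if len(good) < 4:
        raise ValueError("need at least 4 good channels")
    gidx = [epochs.ch_names.index(c) for c in good]
    bidx = [epochs.ch_names.index(c) for c in sorted(bad)]
    gpos = np.array([montage.position_of(c) for c in good])
    bpos = np.array([montage.position_of(c) for c in sorted(bad)])
    W = spline_interpolation_matrix(gpos, bpos)
    data = epochs.data.copy()
    if data.ndim == 3:
        data[:, bidx, :] = np.einsum("bg,tgs->tbs", W, data[:, gidx, :])
    else:
        data[bidx] = W @ data[gidx]
    return replace(epochs, data=data)
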