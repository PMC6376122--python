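"""Mass-univariate point-wise paired statistics for ERP waveforms.

The analysis contrasts two conditions' per-participant trial averages with a
paired t-test at every electrode and time point, then prunes the significance
mask with two persistence criteria: effects must last at least 10 contiguous
samples (20 ms at 500 Hz) and must cover at least five adjacent electrodes
lying within the same scalp region (one of nine anterior/central/posterior x
left/midline/right clusters).  Multiple comparisons are additionally
controlled with a paired sign-flip randomization test on the participant
difference waves; when the number of participants is small enough the full
set of 2^n sign assignments is enumerated, otherwise a seeded sample is
drawn and the p-value uses the (count + 1) / (draws + 1) convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .montage import ElectrodeMontage

__all__ = [
    "TTestMap",
    "Effect",
    "SignificanceReport",
    "paired_t_map",
    "stack_differences",
    "temporal_persistence_filter",
    "spatial_extent_filter",
    "signflip_randomization",
    "summarize_effects",
]


@dataclass(frozen=True)
class TTestMap:
    """Point-wise paired t and two-tailed p maps (channels x samples)."""

    t: np.ndarray
    p: np.ndarray
    df: int
    comparison: str = ""


@dataclass(frozen=True)
class Effect:
    """One surviving spatio-temporal effect."""

    window_ms: tuple[float, float]
    electrodes: tuple[str, ...]
    peak_t: float
    peak_electrode: str
    peak_latency_ms: float
    regions: tuple[str, ...]
    survived_randomization: bool | None = None

    def to_dict(self) -> dict:
        d = {
            "window_start_ms": self.window_ms[0],
            "window_end_ms": self.window_ms[1],
            "electrodes": list(self.electrodes),
            "peak_t": self.peak_t,
            "peak_electrode": self.peak_electrode,
            "peak_latency_ms": self.peak_latency_ms,
            "regions": list(self.regions),
        }
        if self.survived_randomization is not None:
            d["survived_randomization"] = self.survived_randomization
        return d


@dataclass(frozen=True)
class SignificanceReport:
    """Surviving effects of one condition contrast."""

    comparison: str
    effects: tuple[Effect, ...] = ()

    def __len__(self) -> int:
        return len(self.effects)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_dict() for e in self.effects])

    def to_json_dict(self) -> dict:
        return {"comparison": self.comparison,
                "effects": [e.to_dict() for e in self.effects]}


def stack_differences(evoked_a, evoked_b) -> np.ndarray:
    """Participant-aligned difference waves, participants x channels x samples."""
    by_pid = {e.participant: e for e in evoked_b}
    if set(by_pid) != {e.participant for e in evoked_a}:
        raise ValueError("participant sets differ between conditions")
    diffs = []
    for ea in evoked_a:
        eb = by_pid[ea.participant]
        if ea.data.shape != eb.data.shape or ea.ch_names != eb.ch_names:
            raise ValueError("mismatched channel/time axes between conditions")
        diffs.append(ea.data - eb.data)
    return np.stack(diffs)


def _t_from_diffs(diffs: np.ndarray) -> np.ndarray:
    """Paired t over axis 0, with the 0/0 -> 0 and x/0 -> +-inf conventions."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_sd = sd == 0
    if np.any(zero_sd):
        t = np.where(zero_sd & (mean == 0), 0.0, t)
        t = np.where(zero_sd & (mean > 0), np.inf, t)
        t = np.where(zero_sd & (mean < 0), -np.inf, t)
    return t


def paired_t_map(evoked_a, evoked_b, comparison: str = "") -> TTestMap:
    """Point-wise paired t-test between two per-participant evoked lists.

    ``t = mean(diff) / (sd(diff)/sqrt(n))`` element-wise with df = n - 1 and
    two-tailed p from the t distribution.  Zero-variance points with nonzero
    mean yield ``t = +-inf`` (p = 0) and are flagged with a warning.
    """
    diffs = stack_differences(evoked_a, evoked_b)
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    t = _t_from_diffs(diffs)
    if np.any(np.isinf(t)):
        warnings.warn("zero-variance points produced infinite t", RuntimeWarning)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    if not comparison and evoked_a and evoked_b:
        comparison = f"{evoked_a[0].condition} vs {evoked_b[0].condition}"
    return TTestMap(t=t, p=p, df=n - 1, comparison=comparison)


def temporal_persistence_filter(mask: np.ndarray, min_samples: int = 10) -> np.ndarray:
    """Clear, per channel, runs of significance shorter than ``min_samples``.

    The default of 10 contiguous samples corresponds to a 20 ms persistence
    criterion at a 500 Hz sampling rate.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    for c in range(mask.shape[0]):
        row = mask[c]
        padded = np.r_[False, row, False]
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for s, e in zip(starts, ends):
            if e - s >= min_samples:
                out[c, s:e] = True
    return out


def _cluster_restricted_adjacency(montage: ElectrodeMontage) -> np.ndarray:
    """Adjacency over retained channels, keeping only same-cluster edges."""
    mat = montage.adjacency_matrix()
    ret = montage.retained
    if montage.clusters:
        for i, a in enumerate(ret):
            for j in range(i + 1, len(ret)):
                if mat[i, j] and montage.clusters.get(a) != montage.clusters.get(ret[j]):
                    mat[i, j] = mat[j, i] = False
    return mat


def spatial_extent_filter(mask: np.ndarray, montage: ElectrodeMontage,
                          min_channels: int = 5) -> np.ndarray:
    """Keep, per time sample, only groups of >= ``min_channels`` adjacent
    significant electrodes that share a scalp cluster.

    Significant channels are grouped into connected components of the
    montage adjacency graph restricted to same-cluster edges; smaller
    components are cleared.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != len(montage.retained):
        raise ValueError("mask channels do not match montage retained channels")
    adj = _cluster_restricted_adjacency(montage)
    out = np.zeros_like(mask)
    for s in range(mask.shape[1]):
        idx = np.flatnonzero(mask[:, s])
        if len(idx) < min_channels:
            continue
        sub = adj[np.ix_(idx, idx)]
        n_comp, labels = connected_components(coo_matrix(sub), directed=False)
        for comp in range(n_comp):
            members = idx[labels == comp]
            if len(members) >= min_channels:
                out[members, s] = True
    return out


def _sign_matrix(n: int, n_perm: int, rng: np.random.Generator):
    """All or sampled sign assignments, rows in {-1, +1}^n.

    Returns (signs, exhaustive_flag); exhaustive mode enumerates all 2^n
    assignments (the identity included).
    """
    if 2**n <= n_perm:
        bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
        return 2.0 * bits - 1.0, True
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2.0 - 1.0
    return signs, False


def signflip_randomization(diffs: np.ndarray, alpha: float = 0.01,
                           n_perm: int = 5000, min_samples: int = 10,
                           seed: int = 0):
    """Point-wise paired randomization test by participant sign flips.

    The statistic is the point-wise paired t of the (sign-flipped)
    difference waves.  With ``2^n <= n_perm`` the complete enumeration is
    used and p is the exact proportion of ``|t_perm| >= |t_obs|``; otherwise
    ``n_perm`` seeded draws give ``p = (count + 1) / (draws + 1)``.  The
    temporal persistence criterion is applied to the ``p < alpha`` mask.

    Returns ``(p_map, surviving_mask)``.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.default_rng(seed)
    signs, exhaustive = _sign_matrix(n, n_perm, rng)
    if not exhaustive and n_perm < 100:
        raise ValueError("use at least 100 permutations in sampled mode")

    shape = diffs.shape[1:]
    X = diffs.reshape(n, -1)
    sumsq = (X**2).sum(axis=0)
    t_obs = np.abs(_t_from_diffs(diffs).reshape(-1))
    count = np.zeros(X.shape[1])
    chunk = max(1, int(2e8 // (8 * X.shape[1])))
    for lo in range(0, len(signs), chunk):
        S = signs[lo : lo + chunk]
        mean = (S @ X) / n
        var = (sumsq[None, :] - n * mean**2) / (n - 1)
        var = np.clip(var, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = np.abs(mean) / np.sqrt(var / n)
        t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=np.inf)
        count += (t_perm >= t_obs[None, :] - 1e-12).sum(axis=0)
    if exhaustive:
        p = count / len(signs)
    else:
        # the observed statistic is its own draw under the null
        p = (count + 1.0) / (len(signs) + 1.0)
    p = p.reshape(shape)
    mask = temporal_persistence_filter(p < alpha, min_samples)
    return p, mask


def summarize_effects(mask: np.ndarray, tmap: TTestMap,
                      montage: ElectrodeMontage, rate: float, t0_ms: float,
                      randomization_mask: np.ndarray | None = None) -> SignificanceReport:
    """Merge a surviving mask into a report of spatio-temporal effects.

    Significant (channel, sample) points are grouped into connected
    components (adjacent in time on the same channel, or simultaneous on
    adjacent channels); each component is reported with its time window, its
    member electrodes and regions, and the peak |t| with electrode and
    latency.  Effects are sorted by onset.
    """
    mask = np.asarray(mask, dtype=bool)
    n_ch, n_s = mask.shape
    ret = montage.retained
    pts = np.flatnonzero(mask.reshape(-1))
    if len(pts) == 0:
        return SignificanceReport(comparison=tmap.comparison)
    index_of = {pt: k for k, pt in enumerate(pts)}
    adj = montage.adjacency_matrix()
    rows_, cols_ = [], []
    for k, pt in enumerate(pts):
        c, s = divmod(pt, n_s)
        if s + 1 < n_s and mask[c, s + 1]:
            rows_.append(k)
            cols_.append(index_of[pt + 1])
        for c2 in np.flatnonzero(adj[c]):
            if c2 > c and mask[c2, s]:
                rows_.append(k)
                cols_.append(index_of[c2 * n_s + s])
    graph = coo_matrix((np.ones(len(rows_)), (rows_, cols_)), shape=(len(pts), len(pts)))
    n_comp, labels = connected_components(graph, directed=False)

    effects = []
    for comp in range(n_comp):
        comp_pts = pts[labels == comp]
        chans = np.unique(comp_pts // n_s)
        samps = comp_pts % n_s
        tvals = tmap.t.reshape(-1)[comp_pts]
        k_peak = int(np.argmax(np.abs(tvals)))
        peak_pt = comp_pts[k_peak]
        pc, psamp = divmod(peak_pt, n_s)
        survived = None
        if randomization_mask is not None:
            survived = bool(randomization_mask.reshape(-1)[comp_pts].any())
        regions = sorted({montage.clusters.get(ret[c], "?") for c in chans}) if montage.clusters else []
        effects.append(Effect(
            window_ms=(t0_ms + samps.min() * 1000.0 / rate,
                       t0_ms + samps.max() * 1000.0 / rate),
            electrodes=tuple(ret[c] for c in chans),
            peak_t=float(tvals[k_peak]),
            peak_electrode=ret[pc],
            peak_latency_ms=t0_ms + psamp * 1000.0 / rate,
            regions=tuple(regions),
            survived_randomization=survived,
        ))
    effects.sort(key=lambda e: (e.window_ms[0], e.window_ms[1]))
    return SignificanceReport(comparison=tmap.comparison, effects=tuple(effects))
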