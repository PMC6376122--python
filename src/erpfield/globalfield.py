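"""Reference-free global electric-field statistics: GFP, DISS, TANOVA.

Global Field Power (GFP) is the spatial standard deviation of the scalp
potential at one time point; under the average reference it equals the RMS
over electrodes and indexes field *strength* (quantitative modulation of a
fixed generator configuration).  Global dissimilarity (DISS) is the RMS
difference between two maps each scaled to unit GFP; it ranges 0..2, is
invariant to field strength, and indexes *topographic* (qualitative,
generator-configuration) change, with the identity DISS^2 = 2 (1 - r) for r
the spatial Pearson correlation of the average-referenced maps.

Both indices are tested between paired conditions with label-exchange
randomization: per participant, swapping the two condition labels flips the
GFP difference sign (sign-flip null) and exchanges the maps entering the
group DISS (label-swap null).  Windows shorter than a 20 ms temporal
stability criterion are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pointwise import temporal_persistence_filter

__all__ = [
    "gfp",
    "diss",
    "SignificantWindow",
    "gfp_randomization_test",
    "tanova",
]


@dataclass(frozen=True)
class SignificantWindow:
    start_ms: float
    end_ms: float
    min_p: float

    def to_dict(self) -> dict:
        return {"start_ms": self.start_ms, "end_ms": self.end_ms, "min_p": self.min_p}


def gfp(maps: np.ndarray) -> np.ndarray | float:
    """Spatial standard deviation over channels (population convention).

    Accepts a channel vector (returns a scalar) or channels x samples
    (returns a series).  With average-referenced data this equals the RMS
    across electrodes.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] < 2:
        raise ValueError("GFP needs at least 2 channels")
    out = maps.std(axis=0, ddof=0)
    return float(out) if out.ndim == 0 else out


def diss(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Global dissimilarity between two maps (0 = identical shape, 2 = inverted).

    Both maps are average-referenced, scaled to unit GFP, and compared as
    sqrt(mean of squared differences).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    ga, gb = gfp(a), gfp(b)
    if ga == 0 or gb == 0:
        raise ValueError("DISS undefined for a zero-GFP map")
    return float(np.sqrt(np.mean((a / ga - b / gb) ** 2)))


def _windows_from_mask(mask: np.ndarray, p: np.ndarray, times_ms: np.ndarray):
    padded = np.r_[False, mask, False]
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    return [
        SignificantWindow(float(times_ms[s]), float(times_ms[e - 1]),
                          float(p[s:e].min()))
        for s, e in zip(starts, ends)
    ]


def _check_paired(evoked_a, evoked_b):
    by_pid = {e.participant: e for e in evoked_b}
    if set(by_pid) != {e.participant for e in evoked_a}:
        raise ValueError("participant sets differ between conditions")
    pairs = [(ea, by_pid[ea.participant]) for ea in evoked_a]
    for ea, eb in pairs:
        if ea.data.shape != eb.data.shape:
            raise ValueError("mismatched evoked shapes")
    return pairs


def _duration_samples(min_duration_ms: float, sfreq: float) -> int:
    return max(1, int(round(min_duration_ms * sfreq / 1000.0)))


def gfp_randomization_test(evoked_a, evoked_b, alpha: float = 0.01,
                           n_perm: int = 5000, min_duration_ms: float = 20.0,
                           seed: int = 0):
    """Point-wise randomization test on GFP strength differences.

    The statistic at each time point is |mean over participants of
    (GFP_A - GFP_B)|; the null exchanges condition labels per participant
    (equivalently flips difference signs), exhaustively when 2^n fits in
    ``n_perm``.  Returns ``(p_series, windows)`` with windows shorter than
    ``min_duration_ms`` discarded.
    """
    pairs = _check_paired(evoked_a, evoked_b)
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 participants")
    d = np.stack([gfp(ea.data) - gfp(eb.data) for ea, eb in pairs])  # n x T
    from .pointwise import _sign_matrix

    rng = np.random.default_rng(seed)
    signs, exhaustive = _sign_matrix(n, n_perm, rng)
    if not exhaustive and n_perm < 100:
        raise ValueError("use at least 100 permutations in sampled mode")
    obs = np.abs(d.mean(axis=0))
    stat = np.abs(signs @ d) / n  # draws x T
    count = (stat >= obs[None, :] - 1e-12).sum(axis=0)
    if exhaustive:
        p = count / len(signs)
    else:
        p = (count + 1.0) / (len(signs) + 1.0)
    mask = p < alpha
    min_run = _duration_samples(min_duration_ms, pairs[0][0].sfreq)
    mask = temporal_persistence_filter(mask[None, :], min_run)[0]
    windows = _windows_from_mask(mask, p, pairs[0][0].times_ms)
    return p, windows


def _normalized_stack(evokeds) -> np.ndarray:
    """Participant maps average-referenced and scaled to unit GFP per sample."""
    out = []
    for e in evokeds:
        x = e.data - e.data.mean(axis=0, keepdims=True)
        g = x.std(axis=0, ddof=0)
        g = np.where(g == 0, np.nan, g)
        out.append(x / g)
    return np.stack(out)  # n x C x T


def _group_diss(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    """DISS series between two groups of mean maps (... x C x T)."""
    a = mean_a - mean_a.mean(axis=-2, keepdims=True)
    b = mean_b - mean_b.mean(axis=-2, keepdims=True)
    ga = a.std(axis=-2, ddof=0)
    gb = b.std(axis=-2, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.sqrt(np.mean((a / ga[..., None, :] - b / gb[..., None, :]) ** 2, axis=-2))
    return d


def tanova(evoked_a, evoked_b, alpha: float = 0.01, n_perm: int = 5000,
           min_duration_ms: float = 20.0, seed: int = 0,
           normalize_first: bool = True):
    """Topographic analysis of variance between two paired conditions.

    The observed statistic per time point is the DISS between the two
    conditions' group-mean maps; by default each participant map is scaled
    to unit GFP before averaging (``normalize_first=False`` instead
    normalizes the group averages only).  The null exchanges the two
    condition labels within participants.  Samples where a group map has
    zero GFP are skipped (p = 1, flagged via NaN in the DISS series).

    Returns ``(diss_series, p_series, windows)``.
    """
    pairs = _check_paired(evoked_a, evoked_b)
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 participants")
    if normalize_first:
        A = _normalized_stack([ea for ea, _ in pairs])
        B = _normalized_stack([eb for _, eb in pairs])
    else:
        A = np.stack([ea.data for ea, _ in pairs])
        B = np.stack([eb.data for _, eb in pairs])
    n_, C, T = A.shape
    from .pointwise import _sign_matrix

    rng = np.random.default_rng(seed)
    signs, exhaustive = _sign_matrix(n, n_perm, rng)
    W = (signs + 1.0) / 2.0  # 1 = swap that participant's labels
    if not exhaustive and n_perm < 100:
        raise ValueError("use at least 100 permutations in sampled mode")

    D = (A - B).reshape(n, -1)
    SA = A.sum(axis=0).reshape(-1)
    SB = B.sum(axis=0).reshape(-1)
    obs = _group_diss(A.mean(axis=0), B.mean(axis=0))  # T
    obs_finite = np.nan_to_num(obs, nan=0.0)

    count = np.zeros(T)
    valid = np.isfinite(obs)
    chunk = max(1, int(2e8 // (8 * D.shape[1])))
    for lo in range(0, len(W), chunk):
        Wc = W[lo : lo + chunk]
        swapped = Wc @ D  # draws x (C*T)
        mean_a = (SA[None, :] - swapped) / n
        mean_b = (SB[None, :] + swapped) / n
        d_perm = _group_diss(mean_a.reshape(-1, C, T), mean_b.reshape(-1, C, T))
        d_perm = np.nan_to_num(d_perm, nan=np.inf)  # degenerate perms count as extreme
        count += (d_perm >= obs_finite[None, :] - 1e-12).sum(axis=0)
    if exhaustive:
        p = count / len(W)
    else:
        p = (count + 1.0) / (len(W) + 1.0)
    p = np.where(valid, p, 1.0)
    mask = p < alpha
    min_run = _duration_samples(min_duration_ms, pairs[0][0].sfreq)
    mask = temporal_persistence_filter(mask[None, :], min_run)[0]
    windows = _windows_from_mask(mask, p, pairs[0][0].times_ms)
    return obs, p, windows
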