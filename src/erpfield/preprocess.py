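"""Preprocessing: filtering, segmentation, trial rejection, referencing,
condition averaging, and the accepted-trial balance check.

The conventions mirror standard high-density ERP practice: zero-phase
band-pass filtering of continuous data (0.5-30 Hz with a 50 Hz notch),
segmentation into stimulus-locked epochs, peak-to-peak threshold rejection,
average referencing, and per-participant/per-condition trial averages over
the first 1200 ms after each face onset.  In the two-face paradigm the second
face onset follows the first by 4500 ms (1500 ms face + 3000 ms context shot).
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import signal, stats

from .containers import EpochsArray, EvokedMap

__all__ = [
    "FACE2_DELAY_MS",
    "bandpass_filter",
    "segment_epochs",
    "face2_onsets",
    "reject_trials",
    "rereference_average",
    "average_evoked",
    "trial_count_anova",
]

log = logging.getLogger(__name__)

#: Onset of the second face relative to the first (1500 ms Glance shot
#: followed by a 3000 ms Object shot).
FACE2_DELAY_MS = 4500.0


def _design_filters(low: float, high: float, notch: float | None, sfreq: float):
    nyq = sfreq / 2.0
    if not 0.0 < low < high < nyq:
        raise ValueError(f"invalid band edges ({low}, {high}) at rate {sfreq}")
    sos = signal.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")
    notch_ba = None
    if notch is not None:
        if not 0.0 < notch < nyq:
            raise ValueError("notch frequency outside (0, Nyquist)")
        notch_ba = signal.iirnotch(notch, Q=30.0, fs=sfreq)
    return sos, notch_ba


def bandpass_filter(data, sfreq: float | None = None, low: float = 0.5,
                    high: float = 30.0, notch: float | None = 50.0):
    """Zero-phase band-pass (+ optional notch) along the time axis.

    Accepts an ``EpochsArray``/``EvokedMap`` (rate taken from the container)
    or a plain channels x samples array with ``sfreq`` given.  Forward-
    backward application makes the net filter zero-phase.
    """
    if isinstance(data, (EpochsArray, EvokedMap)):
        out = bandpass_filter(data.data, data.sfreq, low, high, notch)
        return replace(data, data=out)
    if sfreq is None:
        raise ValueError("sfreq required for bare arrays")
    arr = np.asarray(data, dtype=float)
    sos, notch_ba = _design_filters(low, high, notch, sfreq)
    out = signal.sosfiltfilt(sos, arr, axis=-1)
    if notch_ba is not None:
        out = signal.filtfilt(*notch_ba, out, axis=-1)
    return out


def segment_epochs(continuous: np.ndarray, sfreq: float, event_samples,
                   tmin_ms: float, tmax_ms: float, *, ch_names=None,
                   participant: str = "P00", condition: str = "all",
                   lock: str = "Face_1") -> EpochsArray:
    """Slice continuous channels x samples data into event-locked epochs.

    Each epoch spans ``tmin_ms..tmax_ms`` inclusive relative to its event
    sample; the default analysis segmentation (-100, 6000) ms at 500 Hz gives
    3051 samples (6100 ms).  Events whose window leaves the recording are
    dropped with a log message.
    """
    continuous = np.asarray(continuous, dtype=float)
    if continuous.ndim != 2:
        raise ValueError("continuous data must be channels x samples")
    if tmax_ms <= tmin_ms:
        raise ValueError("empty epoch window")
    n_ch, n_samp = continuous.shape
    if ch_names is None:
        ch_names = tuple(f"CH{i+1}" for i in range(n_ch))
    i0 = int(round(tmin_ms * sfreq / 1000.0))
    i1 = int(round(tmax_ms * sfreq / 1000.0))
    epochs = []
    for ev in event_samples:
        a, b = ev + i0, ev + i1
        if a < 0 or b >= n_samp:
            log.warning("event at sample %d too close to recording edge; dropped", ev)
            continue
        epochs.append(continuous[:, a : b + 1])
    if not epochs:
        raise ValueError("no events with a complete epoch window")
    return EpochsArray(
        participant=participant, condition=condition,
        data=np.stack(epochs), sfreq=sfreq, tmin_ms=tmin_ms,
        ch_names=ch_names, lock=lock,
    )


def face2_onsets(face1_onsets, sfreq: float) -> np.ndarray:
    """Second-face onset samples derived from first-face onsets."""
    shift = int(round(FACE2_DELAY_MS * sfreq / 1000.0))
    return np.asarray(face1_onsets, dtype=int) + shift


def reject_trials(epochs_list, p2p_threshold: float = 200.0):
    """Peak-to-peak threshold rejection across a list of ``EpochsArray``.

    A trial is rejected iff any channel's peak-to-peak amplitude exceeds the
    threshold.  Returns the cleaned list and a DataFrame of accepted counts
    per participant x condition.  Surviving trials are untouched.
    """
    if p2p_threshold <= 0:
        raise ValueError("threshold must be positive")
    single = isinstance(epochs_list, EpochsArray)
    if single:
        epochs_list = [epochs_list]
    cleaned, rows = [], []
    for ep in epochs_list:
        p2p = ep.data.max(axis=2) - ep.data.min(axis=2)  # trials x channels
        keep = ~(p2p > p2p_threshold).any(axis=1)
        if not keep.any():
            raise ValueError(
                f"all trials rejected for {ep.participant}/{ep.condition}; "
                "review the peak-to-peak threshold"
            )
        rejected_pct = 100.0 * (1.0 - keep.mean())
        if rejected_pct > 22.0:
            log.warning("%s/%s: %.1f%% trials rejected (expected < 22%%)",
                        ep.participant, ep.condition, rejected_pct)
        cleaned.append(replace(ep, data=ep.data[keep]))
        rows.append({"participant": ep.participant, "condition": ep.condition,
                     "accepted": int(keep.sum()), "rejected": int((~keep).sum())})
    counts = pd.DataFrame(rows)
    if single:
        return cleaned[0], counts
    return cleaned, counts


def rereference_average(obj):
    """Subtract the instantaneous mean over channels (average reference).

    Idempotent; accepts ``EpochsArray``, ``EvokedMap`` or a bare array whose
    channel axis is the second-to-last one.
    """
    if isinstance(obj, (EpochsArray, EvokedMap)):
        return replace(obj, data=rereference_average(obj.data))
    arr = np.asarray(obj, dtype=float)
    if arr.shape[-2] < 2:
        raise ValueError("average reference needs at least 2 channels")
    return arr - arr.mean(axis=-2, keepdims=True)


def average_evoked(epochs: EpochsArray, window_ms=(0.0, 1200.0),
                   lock: str | None = None) -> EvokedMap:
    """Trial-average restricted to a window relative to a face onset.

    ``lock`` defaults to the epochs' own locking event.  When Face_2-locked
    averages are requested from Face_1-locked epochs the window is shifted by
    the 4500 ms face-to-face delay.
    """
    if epochs.n_trials < 1:
        raise ValueError("cannot average zero trials")
    lock = lock or epochs.lock
    shift = 0.0
    if lock != epochs.lock:
        if (epochs.lock, lock) == ("Face_1", "Face_2"):
            shift = FACE2_DELAY_MS
        elif (epochs.lock, lock) == ("Face_2", "Face_1"):
            shift = -FACE2_DELAY_MS
        else:
            raise ValueError(f"unknown lock pair {epochs.lock!r} -> {lock!r}")
    lo, hi = window_ms[0] + shift, window_ms[1] + shift
    times = epochs.times_ms
    sel = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    if not sel.any():
        raise ValueError("averaging window outside the epoch span")
    mean = epochs.data[:, :, sel].mean(axis=0)
    return EvokedMap(
        participant=epochs.participant, condition=epochs.condition,
        data=mean, sfreq=epochs.sfreq, tmin_ms=float(times[sel][0] - shift),
        ch_names=epochs.ch_names, lock=lock, n_trials=epochs.n_trials,
    )


def trial_count_anova(counts) -> tuple[float, tuple[int, int], float]:
    """One-way repeated-measures ANOVA on accepted-trial counts.

    ``counts`` is participants x conditions (array or wide DataFrame).  With
    n participants and k conditions the F statistic has (k-1, (k-1)(n-1))
    degrees of freedom -- (2, 36) for the 19 x 3 study layout.  Used to check
    that accepted-trial numbers do not differ across conditions.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least 2 participants x 2 conditions")
    if not np.all(np.isfinite(arr)):
        raise ValueError("missing cells in the count table")
    n, k = arr.shape
    # degenerate case: no between-condition variance at all -> F = 0 by
    # convention (the fitted model is singular there)
    ss_cond = n * ((arr.mean(axis=0) - arr.mean()) ** 2).sum()
    ss_tot = ((arr - arr.mean()) ** 2).sum()
    df1, df2 = k - 1, (k - 1) * (n - 1)
    if ss_cond <= 1e-12 * max(ss_tot, 1.0):
        return 0.0, (df1, df2), 1.0
    from statsmodels.stats.anova import AnovaRM

    long = pd.DataFrame({
        "participant": np.repeat(np.arange(n), k),
        "condition": np.tile(np.arange(k), n),
        "count": arr.ravel(),
    })
    try:
        res = AnovaRM(long, depvar="count", subject="participant",
                      within=["condition"]).fit()
        F = float(res.anova_table["F Value"].iloc[0])
    except Exception:  # zero within-variance degenerate case
        F = 0.0
    p = float(stats.f.sf(F, df1, df2))
    return F, (df1, df2), p
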