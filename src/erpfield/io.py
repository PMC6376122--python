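"""File I/O: HDF5 epoch containers, EDF continuous data, tables.

Epochs are stored in an HDF5 file with one group per participant/condition
carrying the data array and its metadata as attributes.  Continuous
recordings are read from EDF through MNE's native reader.  Design and rating
tables round-trip as TSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import pandas as pd

from .containers import EpochsArray

__all__ = [
    "save_epochs",
    "load_epochs",
    "read_edf_continuous",
    "write_table",
    "read_table",
]


def save_epochs(path: str | Path, epochs_list) -> None:
    """Write a list of ``EpochsArray`` to an HDF5 container."""
    if isinstance(epochs_list, EpochsArray):
        epochs_list = [epochs_list]
    with h5py.File(path, "w") as f:
        for ep in epochs_list:
            g = f.create_group(f"{ep.participant}/{ep.condition}")
            g.create_dataset("data", data=ep.data, compression="gzip", compression_opts=1)
            g.attrs["sfreq"] = ep.sfreq
            g.attrs["tmin_ms"] = ep.tmin_ms
            g.attrs["lock"] = ep.lock
            g.attrs["ch_names"] = list(ep.ch_names)


def load_epochs(path: str | Path) -> list:
    """Read every participant/condition group back into ``EpochsArray``s."""
    out = []
    with h5py.File(path, "r") as f:
        for pid in sorted(f):
            for cond in sorted(f[pid]):
                g = f[pid][cond]
                out.append(EpochsArray(
                    participant=pid, condition=cond, data=g["data"][()],
                    sfreq=float(g.attrs["sfreq"]), tmin_ms=float(g.attrs["tmin_ms"]),
                    ch_names=tuple(str(c) for c in g.attrs["ch_names"]),
                    lock=str(g.attrs["lock"]),
                ))
    return out


def read_edf_continuous(path: str | Path):
    """Read an EDF recording; returns ``(data_uv, sfreq, ch_names)``.

    Channel data are converted from MNE's SI volts to microvolts.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), tuple(raw.ch_names)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
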