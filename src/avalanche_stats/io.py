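"""Reading and writing the package's standard file formats.

Signals travel as CSV (one column per channel, header row = channel
labels, sampling rate on a ``# rate_hz=...`` comment line) or HDF5
(dataset ``signal`` shaped channels x samples, attribute ``rate_hz``).
Rasters are CSV with columns ``channel,time_s,amplitude_sd``; plain
numeric samples and spike-time lists are one value per line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .peaks import MultiChannelSignal, PeakRaster
from .tail import TailSample

__all__ = [
    "write_signal_csv", "read_signal_csv",
    "write_signal_hdf5", "read_signal_hdf5",
    "write_raster_csv", "read_raster_csv",
    "write_values", "read_values", "read_tail_sample",
]


def write_signal_csv(sig: MultiChannelSignal, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={sig.rate}\n")
        pd.DataFrame(sig.samples.T, columns=sig.labels).to_csv(fh, index=False)


def read_signal_csv(path: str | Path, rate: Optional[float] = None) -> MultiChannelSignal:
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# rate_hz="):
            rate = float(first.split("=", 1)[1])
            df = pd.read_csv(fh)
        else:
            if rate is None:
                raise ValueError("no rate comment in file; pass rate explicitly")
            fh.seek(0)
            df = pd.read_csv(fh)
    return MultiChannelSignal(df.to_numpy().T, rate, list(df.columns))


def write_signal_hdf5(sig: MultiChannelSignal, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("signal", data=sig.samples)
        ds.attrs["rate_hz"] = sig.rate
        ds.attrs["labels"] = [str(l) for l in sig.labels]


def read_signal_hdf5(path: str | Path) -> MultiChannelSignal:
    with h5py.File(path, "r") as f:
        ds = f["signal"]
        labels = [s.decode() if isinstance(s, bytes) else str(s)
                  for s in ds.attrs.get("labels", [])] or None
        return MultiChannelSignal(ds[()], float(ds.attrs["rate_hz"]), labels)


def write_raster_csv(raster: PeakRaster, path: str | Path) -> None:
    df = raster.events.copy()
    df["time_s"] = df.pop("time_index") / raster.rate
    df.rename(columns={"amplitude": "amplitude_sd"}, inplace=True)
    df[["channel", "time_s", "amplitude_sd"]].to_csv(path, index=False)


def read_raster_csv(
    path: str | Path, rate: float, n_samples: int,
    polarity: str = "negative", threshold: float = 0.0,
) -> PeakRaster:
    df = pd.read_csv(path)
    events = pd.DataFrame({
        "channel": df["channel"],
        "time_index": np.round(df["time_s"] * rate).astype(np.int64),
        "amplitude": df["amplitude_sd"],
    })
    return PeakRaster(events, rate, n_samples, polarity, threshold)  # type: ignore[arg-type]


def write_values(values: Sequence[float], path: str | Path) -> None:
    np.savetxt(path, np.asarray(values, dtype=float), fmt="%.12g")


def read_values(path: str | Path) -> np.ndarray:
    return np.atleast_1d(np.loadtxt(path, dtype=float))


def read_tail_sample(path: str | Path, mode: str = "continuous") -> TailSample:
    return TailSample(read_values(path), mode)  # type: ignore[arg-type]
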