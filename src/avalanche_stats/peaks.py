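"""Peak extraction from multichannel signals and avalanche construction.

The detection pipeline mirrors the standard LFP-avalanche workflow:
per-channel standardization, zero-phase high-pass filtering, detection of
threshold-exceeding deflections (one peak per supra-threshold run,
repositioned in the intact original signal), pooling of peaks across
channels into time bins, and clustering of consecutive occupied bins into
avalanches. Time-shuffled surrogate rasters preserve amplitudes and
per-channel counts while destroying temporal structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .tail import TailSample

__all__ = [
    "MultiChannelSignal",
    "PeakRaster",
    "AvalancheSample",
    "standardize",
    "highpass",
    "detect_peaks",
    "wave_triggered_average",
    "bin_and_cluster",
    "shuffle_times",
]

Polarity = Literal["negative", "positive"]


@dataclass(frozen=True)
class MultiChannelSignal:
    """Sampled continuous signals: ``samples`` is channels x time points."""

    samples: np.ndarray
    rate: float
    labels: Optional[Sequence[str]] = None

    def __post_init__(self):
        s = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        labels = self.labels
        if labels is None:
            labels = [f"ch{i}" for i in range(s.shape[0])]
        elif len(labels) != s.shape[0]:
            raise ValueError("one label per channel required")
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "labels", list(labels))

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass(frozen=True)
class PeakRaster:
    """Discrete threshold-crossing events per channel.

    ``events`` has columns ``channel`` (label), ``time_index`` (int sample
    index) and ``amplitude`` (positive magnitude in SD units), sorted by
    time within channel.
    """

    events: pd.DataFrame
    rate: float
    n_samples: int
    polarity: Polarity
    threshold: float

    def __post_init__(self):
        ev = self.events.sort_values(["channel", "time_index"], kind="stable")
        object.__setattr__(self, "events", ev.reset_index(drop=True))

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def times(self) -> np.ndarray:
        """Event times in seconds (pooled, unsorted across channels)."""
        return self.events["time_index"].to_numpy() / self.rate

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass(frozen=True)
class AvalancheSample:
    """Multiset of avalanche sizes from one binning of a raster."""

    sizes: np.ndarray
    bin_width: float
    mode: Literal["count", "amplitude"]

    def to_tail_sample(self) -> TailSample:
        mode = "discrete" if self.mode == "count" else "continuous"
        return TailSample(self.sizes, mode)


def standardize(sig: MultiChannelSignal) -> MultiChannelSignal:
    """Per-channel mean subtraction and division by the standard deviation."""
    s = sig.samples
    sd = s.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = [sig.labels[i] for i in np.where(sd[:, 0] == 0)[0]]
        raise ValueError(f"constant channel(s): {bad}")
    return replace(sig, samples=(s - s.mean(axis=1, keepdims=True)) / sd)


def highpass(
    sig: MultiChannelSignal, cutoff_hz: float, order: int = 4
) -> MultiChannelSignal:
    """Zero-phase Butterworth high-pass (applied forward-backward)."""
    nyq = sig.rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=sig.rate, output="sos")
    return replace(sig, samples=sps.sosfiltfilt(sos, sig.samples, axis=1))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, stop) index pairs."""
    d = np.diff(mask.astype(np.int8))
    starts = np.where(d == 1)[0] + 1
    stops = np.where(d == -1)[0] + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts.tolist(), stops.tolist()))


def detect_peaks(
    filtered: MultiChannelSignal,
    original: MultiChannelSignal,
    threshold: float,
    polarity: Polarity = "negative",
) -> PeakRaster:
    """Detect one peak per supra-threshold run of the filtered signal.

    Each maximal contiguous run of samples beyond ``-threshold`` (negative
    polarity) or ``+threshold`` (positive) in the filtered signal yields one
    event. The run span is extended to the nearest zero crossings of the
    filtered signal and the event is repositioned at the extremum of the
    *original* signal within that span; the recorded amplitude is the
    positive magnitude of that extremum, in SD units.
    """
    if filtered.samples.shape != original.samples.shape:
        raise ValueError("filtered and original signals must be aligned")
    if threshold <= 0:
        raise ValueError("threshold must be positive (SD units)")
    sign = -1.0 if polarity == "negative" else 1.0
    rows = []
    for c in range(filtered.n_channels):
        y = sign * filtered.samples[c]  # peaks are now positive exceedances
        orig = sign * original.samples[c]
        mask = y > threshold
        if not mask.any():
            continue
        runs = _runs(mask)
        for r, (start, stop) in enumerate(runs):
            # extend to the nearest zero crossing of the filtered signal,
            # but never into a neighbouring run's territory
            floor = runs[r - 1][1] if r > 0 else 0
            ceil = runs[r + 1][0] if r + 1 < len(runs) else y.size
            lo = start
            while lo > floor and y[lo - 1] > 0:
                lo -= 1
            hi = stop
            while hi < ceil and y[hi] > 0:
                hi += 1
            idx = lo + int(np.argmax(orig[lo:hi]))
            rows.append((filtered.labels[c], idx, abs(original.samples[c][idx])))
    events = pd.DataFrame(rows, columns=["channel", "time_index", "amplitude"])
    if len(events) == 0:
        events = pd.DataFrame(
            {"channel": pd.Series(dtype=object),
             "time_index": pd.Series(dtype=np.int64),
             "amplitude": pd.Series(dtype=float)}
        )
    return PeakRaster(
        events=events,
        rate=filtered.rate,
        n_samples=filtered.n_samples,
        polarity=polarity,
        threshold=threshold,
    )


def wave_triggered_average(
    raster: PeakRaster,
    spikes: np.ndarray,
    window: float,
    bin_width: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Average spike rate as a function of lag from each detected peak.

    Returns ``(lag_centers, rate_hz)`` where ``rate_hz[i]`` is the average
    spike count in lag bin ``i`` across all peaks, divided by the bin width.
    """
    if window <= 0 or bin_width <= 0:
        raise ValueError("window and bin_width must be positive")
    if raster.n_events == 0:
        raise ValueError("empty raster")
    spikes = np.sort(np.asarray(spikes, dtype=float))
    n_bins = max(1, int(round(2 * window / bin_width)))
    edges = np.linspace(-window, window, n_bins + 1)
    counts = np.zeros(n_bins)
    for t in raster.times:
        lo, hi = np.searchsorted(spikes, [t - window, t + window])
        if hi > lo:
            counts += np.histogram(spikes[lo:hi] - t, bins=edges)[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / (raster.n_events * bin_width)


def bin_and_cluster(
    raster: PeakRaster,
    bin_width: float,
    mode: Literal["count", "amplitude"] = "count",
) -> AvalancheSample:
    """Pool events across channels, bin time, and cluster into avalanches.

    Bins are half-open ``[k*D, (k+1)*D)``; an avalanche is a maximal run of
    consecutive non-empty bins. Its size is the number of member events
    (``count`` mode) or the sum of their amplitudes (``amplitude`` mode);
    every event belongs to exactly one avalanche.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if raster.n_events == 0:
        return AvalancheSample(np.empty(0), bin_width, mode)
    bins = np.floor(raster.times / bin_width).astype(np.int64)
    order = np.argsort(bins, kind="stable")
    bins_sorted = bins[order]
    amps = raster.events["amplitude"].to_numpy()[order]
    occupied, inverse = np.unique(bins_sorted, return_inverse=True)
    # avalanche id of each occupied bin: increments where a gap appears
    av_of_bin = np.concatenate(([0], np.cumsum(np.diff(occupied) > 1)))
    av_of_event = av_of_bin[inverse]
    n_av = av_of_bin[-1] + 1
    if mode == "count":
        sizes = np.bincount(av_of_event, minlength=n_av).astype(float)
    elif mode == "amplitude":
        sizes = np.bincount(av_of_event, weights=amps, minlength=n_av)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return AvalancheSample(sizes, bin_width, mode)


def shuffle_times(raster: PeakRaster, seed: int | np.random.Generator) -> PeakRaster:
    """Surrogate raster: event times redrawn i.i.d. uniformly over the
    recording; amplitudes and per-channel event counts preserved exactly."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ev = raster.events.copy()
    ev["time_index"] = rng.integers(0, raster.n_samples, size=len(ev))
    return replace(raster, events=ev)
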