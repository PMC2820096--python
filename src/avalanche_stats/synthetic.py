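"""Synthetic multichannel recordings and law-exact samples.

The original multisite LFP recordings this pipeline was designed around are
not publicly deposited, so every input is generated here: multichannel
signals whose negative deflections are event-driven (superposed
exponential-decay kernels at Poisson times, amplitudes from a configurable
law) plus white noise, together with unit spike trains whose rate
transiently increases around the planted negative events — reproducing the
peak/spike coupling that a wave-triggered average detects. Defaults mirror
the recordings' printed facts: 8 channels sampled at 250 Hz.

``make_tail_sample`` draws law-exact samples (continuous/discrete power
law, shifted exponential, geometric) for the tail-inference machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import signal as sps

from .peaks import MultiChannelSignal, PeakRaster
from .tail import TailFit, TailSample, sample_fitted

__all__ = ["LfpEmulationConfig", "make_lfp_dataset", "make_tail_sample"]

AmplitudeLaw = Literal["fixed", "exponential", "powerlaw"]


@dataclass(frozen=True)
class LfpEmulationConfig:
    """Configuration of the emulated multichannel recording.

    Each channel superposes negative-deflecting exponential-decay kernels
    (decay ``event_tau`` s) at Poisson event times of rate ``event_rate``,
    with amplitudes drawn from ``amplitude_law`` (scale ``amplitude_scale``;
    ``powerlaw`` uses exponent ``amplitude_alpha`` above ``amplitude_scale``)
    and a fraction ``negative_fraction`` of events deflecting negative (the
    rest positive). White noise of SD ``noise_sd`` is added. Unit spikes
    are inhomogeneous Poisson at ``spike_base_rate`` Hz, multiplied by
    ``spike_gain`` within ``spike_window`` s of each planted negative event.
    """

    n_channels: int = 8
    duration: float = 120.0
    rate: float = 250.0
    event_rate: float = 2.0
    amplitude_law: AmplitudeLaw = "exponential"
    amplitude_scale: float = 1.0
    amplitude_alpha: float = 2.5
    negative_fraction: float = 1.0
    event_tau: float = 0.02
    noise_sd: float = 0.2
    spike_base_rate: float = 5.0
    spike_gain: float = 5.0
    spike_window: float = 0.02

    def __post_init__(self):
        if min(self.duration, self.rate, self.event_rate, self.event_tau) <= 0:
            raise ValueError("rates and durations must be positive")
        if not 0 <= self.negative_fraction <= 1:
            raise ValueError("negative_fraction must lie in [0, 1]")
        if self.spike_gain < 1:
            raise ValueError("spike_gain must be >= 1")
        if self.noise_sd < 0 or self.amplitude_scale <= 0:
            raise ValueError("invalid amplitude/noise configuration")


def _draw_amplitudes(cfg: LfpEmulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.amplitude_law == "fixed":
        return np.full(n, cfg.amplitude_scale)
    if cfg.amplitude_law == "exponential":
        return cfg.amplitude_scale * rng.exponential(size=n)
    if cfg.amplitude_law == "powerlaw":
        u = rng.random(n)
        return cfg.amplitude_scale * (1.0 - u) ** (-1.0 / (cfg.amplitude_alpha - 1.0))
    raise ValueError(f"unknown amplitude law {cfg.amplitude_law!r}")


def make_lfp_dataset(
    cfg: LfpEmulationConfig, seed: int | np.random.Generator
) -> tuple[MultiChannelSignal, PeakRaster, list[np.ndarray]]:
    """Emulated recording: signal, ground-truth negative-event raster, and
    one spike-time array per channel.

    The ground-truth raster lists every planted negative event (sample
    index and amplitude); spikes on a channel are coupled to that channel's
    negative events through the rate gain.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_samp = int(round(cfg.duration * cfg.rate))
    dt = 1.0 / cfg.rate
    decay = math.exp(-dt / (cfg.event_tau))
    signals = np.empty((cfg.n_channels, n_samp))
    truth_rows = []
    spike_trains: list[np.ndarray] = []
    for c in range(cfg.n_channels):
        n_ev = rng.poisson(cfg.event_rate * cfg.duration)
        t_ev = np.sort(rng.uniform(0.0, cfg.duration, n_ev))
        amps = _draw_amplitudes(cfg, n_ev, rng)
        neg = rng.random(n_ev) < cfg.negative_fraction
        sign = np.where(neg, -1.0, 1.0)
        k = np.minimum((t_ev * cfg.rate).astype(np.int64), n_samp - 1)
        inj = np.zeros(n_samp)
        np.add.at(inj, k, sign * amps)
        signals[c] = sps.lfilter([1.0], [1.0, -decay], inj)
        if cfg.noise_sd > 0:
            signals[c] += cfg.noise_sd * rng.standard_normal(n_samp)
        for ki, ai in zip(k[neg], amps[neg]):
            truth_rows.append((f"ch{c}", int(ki), float(ai)))
        # spikes: thinning of a homogeneous process at the peak rate
        t_neg = t_ev[neg]
        max_rate = cfg.spike_base_rate * cfg.spike_gain
        n_cand = rng.poisson(max_rate * cfg.duration)
        t_cand = np.sort(rng.uniform(0.0, cfg.duration, n_cand))
        if t_neg.size:
            idx = np.searchsorted(t_neg, t_cand)
            near_next = np.where(idx < t_neg.size, t_neg[np.minimum(idx, t_neg.size - 1)] - t_cand, np.inf)
            near_prev = np.where(idx > 0, t_cand - t_neg[np.maximum(idx - 1, 0)], np.inf)
            boosted = np.minimum(near_next, near_prev) <= cfg.spike_window
        else:
            boosted = np.zeros(n_cand, dtype=bool)
        accept_p = np.where(boosted, 1.0, 1.0 / cfg.spike_gain)
        spike_trains.append(t_cand[rng.random(n_cand) < accept_p])
    signal = MultiChannelSignal(signals, cfg.rate, [f"ch{c}" for c in range(cfg.n_channels)])
    events = pd.DataFrame(truth_rows, columns=["channel", "time_index", "amplitude"])
    truth = PeakRaster(
        events=events, rate=cfg.rate, n_samples=n_samp,
        polarity="negative", threshold=0.0,
    )
    return signal, truth, spike_trains


def make_tail_sample(
    law: Literal["powerlaw", "exponential"],
    params: dict,
    n: int,
    seed: int | np.random.Generator,
    mode: Literal["continuous", "discrete"] = "continuous",
) -> TailSample:
    """Law-exact sample for the fitters.

    ``params`` holds ``x_min`` plus ``alpha`` (power law) or ``lam``
    (exponential); sampling is exact inverse-CDF (continuous laws,
    geometric) or an exact Hurwitz-zeta table (discrete power law).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    x_min = float(params.get("x_min", 1.0))
    if law == "powerlaw":
        param = float(params["alpha"])
        if mode == "continuous" and param <= 1:
            raise ValueError("continuous power law needs alpha > 1")
    elif law == "exponential":
        param = float(params["lam"])
        if param <= 0:
            raise ValueError("exponential rate must be positive")
    else:
        raise ValueError(f"unknown law {law!r}")
    proto = TailFit(
        law=law, mode=mode, param=param, x_min=x_min,
        n_tail=n, tail_fraction=1.0, log_likelihood=math.nan, ks=math.nan,
    )
    return sample_fitted(proto, n, seed)
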