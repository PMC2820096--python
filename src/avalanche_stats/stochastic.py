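"""Shot-noise and Ornstein-Uhlenbeck processes and their peak statistics.

Two stochastic null models for thresholded-signal avalanche analysis:

* **Shot noise** — exponential-decay kernels of amplitude ``w`` triggered at
  the event times of a Poisson process of intensity ``rate``; the process
  solves ``dX = -X/tau dt + w dN(t)``. Its local maxima occur exactly at
  the jump times, which conditional on the number of jumps in a window are
  uniform order statistics; the analytic peak and excursion-maximum tails
  are computed by seeded Monte-Carlo quadrature over that representation,
  with the Poisson series truncated at a controlled tail mass.

* **Ornstein-Uhlenbeck (OU)** — the diffusion limit of high-rate shot
  noise, ``dX = -X/tau dt + sigma dW``, stationary ``N(0, sigma^2 tau/2)``.
  Being nowhere differentiable it has no isolated maxima, so "peaks" reduce
  to level exceedances; these are derived from the law of the first hitting
  time, obtained by solving a second-kind Volterra integral equation built
  on the OU Gaussian transition density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate, signal as sps, special, stats

from .peaks import MultiChannelSignal

__all__ = [
    "ShotNoiseParams",
    "OUParams",
    "TailCurve",
    "simulate_shot_noise",
    "simulate_ou",
    "shotnoise_peak_tail",
    "shotnoise_excursion_tail",
    "ou_first_passage_cdf",
    "ou_peak_tail",
    "ou_excursion_tail",
]


@dataclass(frozen=True)
class ShotNoiseParams:
    """Poisson shot-noise parameters.

    ``rate`` is the intensity of each Poisson driver (events/s), ``jump``
    the amplitude deposited per event, ``tau`` the exponential decay
    constant (s), ``horizon`` the observation window (s) and
    ``n_processes`` the number of independent drivers (superposed; the
    analytic tails reduce them to one driver with the summed rate).
    """

    rate: float = 1.0
    jump: float = 1.0
    tau: float = 1.0
    horizon: float = 10.0
    n_processes: int = 1

    def __post_init__(self):
        if min(self.rate, self.jump, self.tau, self.horizon) < 0 or self.n_processes < 1:
            raise ValueError("invalid shot-noise parameters")

    @property
    def total_rate(self) -> float:
        return self.rate * self.n_processes


@dataclass(frozen=True)
class OUParams:
    """OU parameters: relaxation time ``tau`` (s), diffusion amplitude
    ``sigma``, simulation step ``dt`` (s) and horizon (s). The stationary
    standard deviation is ``sigma * sqrt(tau / 2)``."""

    tau: float = 1.0
    sigma: float = 1.0
    dt: float = 1e-3
    horizon: float = 10.0

    def __post_init__(self):
        if min(self.tau, self.dt, self.horizon) <= 0 or self.sigma < 0:
            raise ValueError("invalid OU parameters")
        if self.dt > self.tau / 10:
            raise ValueError("dt must be small relative to tau")

    @property
    def stationary_sd(self) -> float:
        return self.sigma * math.sqrt(self.tau / 2.0)


@dataclass(frozen=True)
class TailCurve:
    """Analytic tail probability ``P(X > a)`` on an increasing level grid."""

    levels: np.ndarray
    probs: np.ndarray
    mc_se: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        lv = np.asarray(self.levels, dtype=float)
        pr = np.asarray(self.probs, dtype=float)
        if lv.shape != pr.shape or lv.ndim != 1:
            raise ValueError("levels and probs must be matching 1-D arrays")
        if np.any(np.diff(lv) <= 0):
            raise ValueError("levels must be strictly increasing")
        if pr[0] > 1 + 1e-9 or np.any(pr < -1e-12):
            raise ValueError("probs must lie in [0, 1]")
        if np.any(np.diff(pr) > 1e-9):
            raise ValueError("tail probabilities must be non-increasing")
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "probs", pr)


# ---------------------------------------------------------------------------
# simulators


def simulate_shot_noise(
    params: ShotNoiseParams,
    seed: int | np.random.Generator,
    sample_rate: float = 1000.0,
) -> tuple[MultiChannelSignal, np.ndarray]:
    """Exact event-driven shot-noise path sampled at ``sample_rate``.

    Event times from all drivers are superposed (a Poisson process of the
    summed rate); the path at each sample time is the exact sum of
    exponentially decayed jumps. Returns the sampled path as a one-channel
    signal plus the sorted event times.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = params.total_rate
    n_ev = rng.poisson(lam * params.horizon)
    t_ev = np.sort(rng.uniform(0.0, params.horizon, n_ev))
    n_samp = int(round(params.horizon * sample_rate))
    dt = 1.0 / sample_rate
    # injection into each sample bin, decayed to the bin's right edge
    k = np.minimum((t_ev * sample_rate).astype(np.int64), n_samp - 1)
    edge = (k + 1) * dt
    inj = np.zeros(n_samp)
    np.add.at(inj, k, params.jump * np.exp(-(edge - t_ev) / params.tau))
    decay = math.exp(-dt / params.tau)
    path = sps.lfilter([1.0], [1.0, -decay], inj)
    return (
        MultiChannelSignal(path[None, :], sample_rate, ["shotnoise"]),
        t_ev,
    )


def simulate_ou(
    params: OUParams,
    seed: int | np.random.Generator,
    start: float = 0.0,
) -> MultiChannelSignal:
    """OU path via the exact conditional-Gaussian discretization.

    ``X[k+1] = X[k] * exp(-dt/tau) + sqrt(sigma^2 tau/2 * (1 - exp(-2dt/tau))) * xi``
    — exact in law at the sample times (not an Euler scheme).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(params.horizon / params.dt))
    rho = math.exp(-params.dt / params.tau)
    noise_sd = params.stationary_sd * math.sqrt(1.0 - rho * rho)
    # scan x_k = rho * x_{k-1} + noise_sd * xi_k, plus the deterministic
    # decay of the starting value (linear recursion, so they superpose)
    x = sps.lfilter([1.0], [1.0, -rho], noise_sd * rng.standard_normal(n))
    x += start * rho ** np.arange(1, n + 1)
    return MultiChannelSignal(x[None, :], 1.0 / params.dt, ["ou"])


# ---------------------------------------------------------------------------
# shot-noise analytic tails


def _poisson_truncation(lam_t: float, tol: float, n_cap: int = 4000) -> int:
    """Smallest n_max with size-weighted Poisson tail mass below tol."""
    n = max(4, int(lam_t))
    while n < n_cap:
        # remainder of sum_{k>n} k * pmf(k) = lam_t * P(K >= n) for K~Poisson
        rest = lam_t * stats.poisson.sf(n - 1, lam_t)
        if rest / max(lam_t, 1e-300) < tol:
            return n
        n += max(1, n // 8)
    raise ValueError("Poisson series does not truncate; increase n_max/tolerance")


def _conditional_maxima(
    rng: np.random.Generator, n: int, n_draws: int, params: ShotNoiseParams
) -> np.ndarray:
    """Local-maximum values M_k for n jumps at uniform order statistics.

    Returns an (n_draws, n) array: ``M_k = M_{k-1} e^{-dt/tau} + w`` along
    the sorted jump times of each draw.
    """
    t = np.sort(rng.uniform(0.0, params.horizon, size=(n_draws, n)), axis=1)
    m = np.empty((n_draws, n))
    m[:, 0] = params.jump
    for k in range(1, n):
        dt = t[:, k] - t[:, k - 1]
        m[:, k] = m[:, k - 1] * np.exp(-dt / params.tau) + params.jump
    return m


def shotnoise_peak_tail(
    params: ShotNoiseParams,
    levels: np.ndarray,
    seed: int = 0,
    n_max: Optional[int] = None,
    n_draws: int = 20_000,
    truncation_tol: float = 1e-6,
) -> TailCurve:
    """Tail ``P(local maximum > a)`` of the shot-noise process.

    Conditions on the number of jumps ``n`` in the window (uniform order
    statistics given ``n``), evaluates the conditional expected number of
    maxima above each level by Monte-Carlo quadrature with ``n_draws``
    draws per ``n``, and weights by Poisson probabilities. The series is
    truncated once the size-weighted Poisson tail mass falls below
    ``truncation_tol`` (an error asks for a larger ``n_max`` otherwise).
    """
    levels = np.asarray(levels, dtype=float)
    lam_t = params.total_rate * params.horizon
    auto = _poisson_truncation(lam_t, truncation_tol)
    if n_max is None:
        n_max = auto
    elif n_max < auto:
        raise ValueError(
            f"n_max={n_max} leaves truncation error above {truncation_tol}; "
            f"need >= {auto}"
        )
    rng = np.random.default_rng(seed)
    pmf = stats.poisson.pmf(np.arange(n_max + 1), lam_t)
    num = np.zeros(levels.size)
    var = np.zeros(levels.size)
    for n in range(1, n_max + 1):
        m = _conditional_maxima(rng, n, n_draws, params)
        counts = (m[:, :, None] > levels[None, None, :]).sum(axis=1)  # draws x levels
        num += pmf[n] * counts.mean(axis=0)
        var += pmf[n] ** 2 * counts.var(axis=0) / n_draws
    probs = num / lam_t
    se = np.sqrt(var) / lam_t
    return TailCurve(
        levels, np.minimum(np.maximum.accumulate(probs[::-1])[::-1], 1.0), se,
        meta={"model": "shotnoise-peak", "horizon": params.horizon,
              "n_max": n_max, "n_draws": n_draws, "seed": seed},
    )


def shotnoise_excursion_tail(
    params: ShotNoiseParams,
    theta: float,
    levels: np.ndarray,
    seed: int = 0,
    n_max: Optional[int] = None,
    n_draws: int = 20_000,
    truncation_tol: float = 1e-6,
) -> TailCurve:
    """Tail of excursion maxima: ``P(max of an excursion above theta > a)``.

    Uses the joint law of successive maxima (at jump times) and pre-jump
    minima under the conditional uniform representation: an excursion
    starts at a jump carrying the process above ``theta`` and ends when a
    pre-jump minimum (pure decay) falls back below it; its maximum is the
    largest jump-time value in between.
    """
    levels = np.asarray(levels, dtype=float)
    if np.any(levels < theta):
        raise ValueError("levels must be >= theta")
    lam_t = params.total_rate * params.horizon
    auto = _poisson_truncation(lam_t, truncation_tol)
    if n_max is None:
        n_max = auto
    elif n_max < auto:
        raise ValueError(f"n_max too small for tolerance; need >= {auto}")
    rng = np.random.default_rng(seed)
    pmf = stats.poisson.pmf(np.arange(n_max + 1), lam_t)
    num = np.zeros(levels.size)  # E[# excursions with max > a]
    den = 0.0                    # E[# excursions]
    var = np.zeros(levels.size)
    for n in range(1, n_max + 1):
        t = np.sort(rng.uniform(0.0, params.horizon, size=(n_draws, n)), axis=1)
        m = np.empty((n_draws, n))
        m[:, 0] = params.jump
        for k in range(1, n):
            m[:, k] = m[:, k - 1] * np.exp(-(t[:, k] - t[:, k - 1]) / params.tau) + params.jump
        counts = np.zeros((n_draws, levels.size))
        n_exc = np.zeros(n_draws)
        above = np.zeros(n_draws, dtype=bool)
        cur_max = np.zeros(n_draws)
        for k in range(n):
            mk = m[:, k]
            starting = (~above) & (mk > theta)
            cur_max = np.where(starting, mk, np.where(above, np.maximum(cur_max, mk), cur_max))
            above = above | starting
            # pre-next-jump minimum (pure decay); after the last jump the
            # process only decays, so the excursion's maximum is final
            if k < n - 1:
                pre_min = mk * np.exp(-(t[:, k + 1] - t[:, k]) / params.tau)
                ending = above & (pre_min < theta)
            else:
                ending = above.copy()
            if ending.any():
                counts[ending] += cur_max[ending, None] > levels[None, :]
                n_exc[ending] += 1
                above = above & ~ending
        num += pmf[n] * counts.mean(axis=0)
        var += pmf[n] ** 2 * counts.var(axis=0) / n_draws
        den += pmf[n] * n_exc.mean()
    if den <= 0:
        raise ValueError("no excursions above theta at these parameters")
    probs = np.minimum(num / den, 1.0)
    se = np.sqrt(var) / den
    return TailCurve(
        levels, np.maximum.accumulate(probs[::-1])[::-1], se,
        meta={"model": "shotnoise-excursion", "theta": theta,
              "horizon": params.horizon, "n_max": n_max,
              "n_draws": n_draws, "seed": seed},
    )


# ---------------------------------------------------------------------------
# OU first passage (Volterra integral equation) and tails


def _ou_kernel(params: OUParams, b: float, y: float | np.ndarray, dt: float | np.ndarray):
    """Second-kind Volterra kernel Psi built on the OU transition density.

    ``Psi(t | y, s) = f(b, t | y, s) * [b/(2 tau) + (sigma^2/2)(b - m)/v]``
    with ``m, v`` the OU conditional mean and variance over ``t - s``; the
    Wiener-process limit reproduces the known closed-form first-passage
    density, which fixes signs and normalization.
    """
    tau, sig2 = params.tau, params.sigma ** 2
    rho = np.exp(-np.asarray(dt) / tau)
    m = y * rho
    v = 0.5 * sig2 * tau * (1.0 - rho * rho)
    f = np.exp(-0.5 * (b - m) ** 2 / v) / np.sqrt(2.0 * math.pi * v)
    return f * (b / (2.0 * tau) + 0.5 * sig2 * (b - m) / v)


def _fpt_density_grid(
    params: OUParams, start: float, level: float, t_end: float, n_steps: int
) -> tuple[np.ndarray, np.ndarray]:
    """First-passage density on a uniform grid by product-midpoint Volterra
    solve; the kernel's ``t -> s`` square-root singularity is avoided by
    evaluating it at subinterval midpoints."""
    h = t_end / n_steps
    t = np.linspace(0.0, t_end, n_steps + 1)
    g = np.zeros(n_steps + 1)
    mids = t[:-1] + 0.5 * h
    for j in range(1, n_steps + 1):
        tj = t[j]
        psi0 = _ou_kernel(params, level, start, tj)
        kmid = _ou_kernel(params, level, level, tj - mids[:j])
        # sum over subintervals i = 1..j with g at midpoints ~ trapezoid
        s = 0.0
        if j > 1:
            gmid = 0.5 * (g[: j - 1] + g[1:j])
            s = float(np.dot(gmid, kmid[: j - 1]))
        k_last = kmid[j - 1]
        g[j] = (2.0 * psi0 - 2.0 * h * s - h * g[j - 1] * k_last) / (1.0 + h * k_last)
    return t, np.maximum(g, 0.0)


def ou_first_passage_cdf(
    params: OUParams,
    start: float,
    level: float,
    t_grid: np.ndarray,
    tol: float = 1e-3,
    n_steps0: int = 256,
    max_refine: int = 5,
) -> np.ndarray:
    """CDF of the first hitting time of ``level`` from ``start``.

    Solves the second-kind Volterra integral equation for the first-passage
    density on a uniform grid (trapezoidal/midpoint product quadrature) and
    integrates it; the grid is halved until the CDF changes by less than
    ``tol``. A CDF exceeding ``1 + tol`` raises (finer grid needed).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0) or t_grid[0] <= 0:
        raise ValueError("t_grid must be increasing and start above 0")
    if level == start:
        return np.ones_like(t_grid)
    if level < start:
        raise ValueError("level must be >= start")
    t_end = float(t_grid[-1])
    prev = None
    n_steps = n_steps0
    for _ in range(max_refine):
        t, g = _fpt_density_grid(params, start, level, t_end, n_steps)
        cdf_fine = integrate.cumulative_trapezoid(g, t, initial=0.0)
        cdf = np.interp(t_grid, t, cdf_fine)
        if np.any(cdf > 1.0 + 10 * tol):
            raise ValueError("non-convergent discretization: CDF exceeds 1; refine grid")
        if prev is not None and np.max(np.abs(cdf - prev)) < tol:
            return np.minimum(cdf, 1.0)
        prev = cdf
        n_steps *= 2
    return np.minimum(prev, 1.0)


def ou_peak_tail(
    params: OUParams,
    theta: float,
    levels: np.ndarray,
    horizon: Optional[float] = None,
    start: float = 0.0,
) -> TailCurve:
    """Exceedance tail ``P(sup X > a | sup X > theta)`` over the horizon.

    Both probabilities come from the first-passage CDF at the horizon; the
    ratio equals 1 at ``a = theta`` and is non-increasing in ``a``.
    """
    levels = np.asarray(levels, dtype=float)
    if np.any(levels < theta):
        raise ValueError("levels must be >= theta")
    T = params.horizon if horizon is None else horizon
    t_grid = np.array([T])
    p_theta = float(ou_first_passage_cdf(params, start, theta, t_grid)[0]) if theta > start else 1.0
    if p_theta < 1e-12:
        raise ValueError("exceedance probability of theta is numerically zero")
    probs = np.empty(levels.size)
    for i, a in enumerate(levels):
        probs[i] = (
            1.0 if a <= start
            else float(ou_first_passage_cdf(params, start, float(a), t_grid)[0])
        )
    probs = np.minimum(probs / p_theta, 1.0)
    probs = np.maximum.accumulate(probs[::-1])[::-1]
    return TailCurve(
        levels, probs, None,
        meta={"model": "ou-peak", "theta": theta, "horizon": T, "start": start},
    )


def _ou_scale(params: OUParams, x: float) -> float:
    """OU scale function ``S(x) = int_0^x exp(u^2 / (tau sigma^2)) du``."""
    c = params.tau * params.sigma ** 2
    return 0.5 * math.sqrt(math.pi * c) * special.erfi(x / math.sqrt(c))


def ou_excursion_tail(
    params: OUParams,
    theta: float,
    levels: np.ndarray,
    epsilon: float = 1e-3,
    cross_check_tol: float = 1e-3,
) -> TailCurve:
    """Excursion tail: probability of reaching ``a`` before falling back
    below ``theta``, started just above the threshold at ``theta + eps``.

    Computed from the closed-form scale-function ratio
    ``[S(theta+eps) - S(theta)] / [S(a) - S(theta)]`` and cross-checked
    against direct numerical quadrature of the scale density.
    """
    levels = np.asarray(levels, dtype=float)
    if np.any(levels <= theta):
        raise ValueError("levels must exceed theta")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    c = params.tau * params.sigma ** 2
    s_theta = _ou_scale(params, theta)
    s_start = _ou_scale(params, theta + epsilon)
    probs = np.empty(levels.size)
    for i, a in enumerate(levels):
        closed = (s_start - s_theta) / (_ou_scale(params, float(a)) - s_theta)
        # independent route: quadrature of the scale density
        q_num, _ = integrate.quad(lambda u: math.exp((u * u - a * a) / c), theta, theta + epsilon)
        q_den, _ = integrate.quad(lambda u: math.exp((u * u - a * a) / c), theta, float(a))
        quad_ratio = q_num / q_den
        if abs(closed - quad_ratio) > cross_check_tol:
            raise RuntimeError("scale-function cross-check failed")
        probs[i] = closed
    probs = np.minimum(np.maximum.accumulate(probs[::-1])[::-1], 1.0)
    return TailCurve(
        levels, probs, None,
        meta={"model": "ou-excursion", "theta": theta, "epsilon": epsilon},
    )
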