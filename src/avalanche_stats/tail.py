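"""Power-law versus exponential tail inference for avalanche-size samples.

Implements the maximum-likelihood tail-fitting toolbox used throughout the
package: closed-form and numeric MLEs for power-law and exponential tails
(continuous and discrete), Kolmogorov-Smirnov distances, KS-minimizing
selection of the tail cutoff ``x_min``, parametric-bootstrap goodness-of-fit
p-values, and Vuong-style log-likelihood-ratio model comparison.

Conventions
-----------
Continuous power law on ``x >= x_min``::

    p(x) = (alpha - 1) / x_min * (x / x_min) ** -alpha,   alpha > 1

Continuous (shifted) exponential on ``x >= x_min``::

    p(x) = lam * exp(-lam * (x - x_min)),                 lam > 0

Discrete power law on integers ``k >= x_min``::

    p(k) = k ** -alpha / zeta(alpha, x_min)               (Hurwitz zeta)

Discrete exponential (geometric) on integers ``k >= x_min``::

    p(k) = (1 - exp(-lam)) * exp(-lam * (k - x_min))

The discrete exponential *estimator* is the same closed form as the
continuous one, ``lam = 1 / (mean - x_min)``; its log-likelihood is
evaluated under the normalized geometric pmf above so that model
comparison against the discrete power law is on equal footing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "TailSample",
    "TailFit",
    "GofResult",
    "LlrResult",
    "DegenerateTailError",
    "mle_powerlaw_continuous",
    "mle_powerlaw_discrete",
    "mle_exponential",
    "fit_at",
    "ks_distance",
    "select_x_min",
    "sample_fitted",
    "gof_pvalue",
    "llr_compare",
    "fit_tail_curve",
    "loglog_histogram_fit",
]

Mode = Literal["continuous", "discrete"]
Law = Literal["powerlaw", "exponential"]

#: search bracket for the discrete power-law exponent
ALPHA_BRACKET = (1.0 + 1e-6, 20.0)
#: search bracket for truncated continuous fits (exponent / rate)
TRUNCATED_BRACKET = (1e-6, 100.0)


class DegenerateTailError(ValueError):
    """Raised when a tail is too degenerate to fit (e.g. all values equal)."""


@dataclass(frozen=True)
class TailSample:
    """A multiset of positive observations to be tail-fitted.

    Parameters
    ----------
    values : array-like of positive reals (or positive integers in
        discrete mode).
    mode : ``"continuous"`` or ``"discrete"``.
    """

    values: np.ndarray
    mode: Mode = "continuous"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("sample must be a non-empty 1-D array")
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise ValueError("sample values must be positive and finite")
        if self.mode == "discrete" and not np.allclose(v, np.round(v)):
            raise ValueError("discrete-mode values must be integers")
        if self.mode not in ("continuous", "discrete"):
            raise ValueError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size

    def tail(self, x_min: float, x_max: Optional[float] = None) -> np.ndarray:
        """Values in ``[x_min, x_max]`` (upper bound optional)."""
        v = self.values[self.values >= x_min]
        if x_max is not None:
            v = v[v <= x_max]
        return v


@dataclass(frozen=True)
class TailFit:
    """One fitted tail law: parameter, cutoff, likelihood and KS distance."""

    law: Law
    mode: Mode
    param: float
    x_min: float
    n_tail: int
    tail_fraction: float
    log_likelihood: float
    ks: float
    x_max: Optional[float] = None
    boundary: bool = False  # optimizer hit the exponent search bound


@dataclass(frozen=True)
class GofResult:
    """Parametric-bootstrap goodness-of-fit result."""

    p_value: float
    n_replicates: int
    observed_ks: float
    seed: int


@dataclass(frozen=True)
class LlrResult:
    """Vuong log-likelihood-ratio comparison (power law minus exponential)."""

    llr: float
    significance: float
    common_x_min: float
    n_common: int
    verdict: Literal["PL", "Exp", "inconclusive"]


# ---------------------------------------------------------------------------
# support helpers


def _support_start(x_min: float, mode: Mode) -> float:
    """Lower end of the fitted support; integer ceiling in discrete mode."""
    return float(math.ceil(x_min - 1e-9)) if mode == "discrete" else float(x_min)


# ---------------------------------------------------------------------------
# maximum-likelihood estimators


def mle_powerlaw_continuous(
    sample: TailSample, x_min: float, x_max: Optional[float] = None
) -> tuple[float, float]:
    """Continuous power-law MLE above ``x_min``.

    Untruncated: the closed form ``alpha = 1 + n / sum(log(x_i / x_min))``
    and its attained log-likelihood. With ``x_max`` the truncated likelihood
    is maximized numerically (the exponent may then fall below 1).

    Returns ``(alpha, log_likelihood)``.
    """
    x = sample.tail(x_min, x_max)
    n = x.size
    if np.count_nonzero(x > x_min) < 2:
        raise DegenerateTailError(
            "need at least 2 tail values strictly above x_min"
        )
    s = float(np.sum(np.log(x / x_min)))
    if s <= 0:
        raise DegenerateTailError("all tail values equal x_min")
    if x_max is None:
        alpha = 1.0 + n / s
        ll = n * math.log(alpha - 1.0) - n * math.log(x_min) - alpha * s
        return alpha, ll

    # truncated: p(x) = x^-alpha / Z,  Z = int_{x_min}^{x_max} u^-alpha du
    log_sum = float(np.sum(np.log(x)))

    def _log_z(alpha: float) -> float:
        if abs(alpha - 1.0) < 1e-8:
            return math.log(math.log(x_max / x_min))
        a1 = 1.0 - alpha
        # log |(x_max^a1 - x_min^a1) / a1| computed stably
        hi, lo = a1 * math.log(x_max), a1 * math.log(x_min)
        m = max(hi, lo)
        return m + math.log(abs(math.exp(hi - m) - math.exp(lo - m))) - math.log(abs(a1))

    def neg_ll(alpha: float) -> float:
        return alpha * log_sum + n * _log_z(alpha)

    res = optimize.minimize_scalar(
        neg_ll, bounds=TRUNCATED_BRACKET, method="bounded",
        options={"xatol": 1e-9},
    )
    return float(res.x), -float(res.fun)


def mle_powerlaw_discrete(
    sample: TailSample, x_min: float
) -> tuple[float, float, bool]:
    """Discrete power-law MLE above ``x_min`` by numeric maximization.

    The normalizer is the Hurwitz zeta ``zeta(alpha, x_min)``; the
    log-likelihood ``-n log zeta(alpha, x_min) - alpha sum(log x_i)`` is
    unimodal in ``alpha`` and is maximized by bounded Brent search on
    ``(1 + 1e-6, 20]``.

    Returns ``(alpha, log_likelihood, boundary)`` where ``boundary`` flags
    an optimizer solution at the bracket edge.
    """
    start = _support_start(x_min, "discrete")
    x = sample.tail(start)
    n = x.size
    if n == 0:
        raise DegenerateTailError("empty tail")
    if np.all(x == x[0]):
        raise DegenerateTailError("all tail values identical")
    log_sum = float(np.sum(np.log(x)))

    def neg_ll(alpha: float) -> float:
        return n * math.log(special.zeta(alpha, start)) + alpha * log_sum

    res = optimize.minimize_scalar(
        neg_ll, bounds=ALPHA_BRACKET, method="bounded", options={"xatol": 1e-8}
    )
    alpha = float(res.x)
    boundary = (
        alpha <= ALPHA_BRACKET[0] + 1e-5 or alpha >= ALPHA_BRACKET[1] - 1e-5
    )
    if boundary:
        warnings.warn(
            f"discrete power-law exponent hit search bound at {alpha:.4g}",
            RuntimeWarning,
            stacklevel=2,
        )
    return alpha, -float(res.fun), boundary


def mle_exponential(
    sample: TailSample, x_min: float, x_max: Optional[float] = None
) -> tuple[float, float]:
    """Exponential-tail MLE above ``x_min``: ``lam = 1 / (mean - x_min)``.

    The same closed-form estimator is used in continuous and discrete mode;
    the returned log-likelihood is evaluated under the mode-appropriate
    normalized law (shifted exponential density, or geometric pmf on the
    integer support). With ``x_max`` (continuous only) the truncated
    likelihood is maximized numerically.
    """
    start = _support_start(x_min, sample.mode)
    x = sample.tail(start, x_max)
    n = x.size
    if n == 0:
        raise DegenerateTailError("empty tail")
    xbar = float(np.mean(x))
    if xbar <= start:
        raise DegenerateTailError("tail mean does not exceed x_min")
    centered = float(np.sum(x - start))

    if x_max is not None:
        if sample.mode == "discrete":
            raise NotImplementedError("truncated discrete exponential")

        def neg_ll(lam: float) -> float:
            log_z = math.log1p(-math.exp(-lam * (x_max - start))) - math.log(lam)
            return lam * centered + n * log_z

        res = optimize.minimize_scalar(
            neg_ll, bounds=TRUNCATED_BRACKET, method="bounded",
            options={"xatol": 1e-9},
        )
        return float(res.x), -float(res.fun)

    lam = 1.0 / (xbar - start)
    if sample.mode == "discrete":
        ll = n * math.log1p(-math.exp(-lam)) - lam * centered
    else:
        ll = n * math.log(lam) - lam * centered
    return lam, ll


# ---------------------------------------------------------------------------
# CDFs of the fitted laws


def _fit_cdf(fit: TailFit, x: np.ndarray) -> np.ndarray:
    """CDF of the fitted tail law evaluated at ``x`` (within the support)."""
    x = np.asarray(x, dtype=float)
    start = _support_start(fit.x_min, fit.mode)
    a = fit.param
    if fit.mode == "continuous":
        if fit.law == "powerlaw":
            if fit.x_max is None:
                return 1.0 - (x / start) ** (1.0 - a)
            if abs(a - 1.0) < 1e-8:
                num = np.log(x / start)
                den = math.log(fit.x_max / start)
            else:
                num = start ** (1 - a) - x ** (1 - a)
                den = start ** (1 - a) - fit.x_max ** (1 - a)
            return num / den
        # exponential
        if fit.x_max is None:
            return -np.expm1(-a * (x - start))
        return -np.expm1(-a * (x - start)) / -math.expm1(-a * (fit.x_max - start))
    # discrete: CDF at integer k is P(X <= k)
    k = np.floor(x + 1e-9)
    if fit.law == "powerlaw":
        return 1.0 - special.zeta(a, k + 1.0) / special.zeta(a, start)
    return -np.expm1(-a * (k - start + 1.0))


def ks_distance(sample: TailSample, fit: TailFit) -> float:
    """Kolmogorov-Smirnov distance between the tail's empirical CDF and the
    fitted CDF, checking both one-sided deviations at every step.

    In discrete mode both CDFs jump at the atoms, so the lower empirical
    deviation is compared against the fitted CDF's left limit ``F(v - 1)``;
    in continuous mode the two limits coincide.
    """
    x = np.sort(sample.tail(_support_start(fit.x_min, fit.mode), fit.x_max))
    n = x.size
    if n == 0:
        raise DegenerateTailError("empty tail")
    vals, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts)
    ecdf_hi = cum / n
    ecdf_lo = (cum - counts) / n
    f_hi = _fit_cdf(fit, vals)
    f_lo = _fit_cdf(fit, vals - 1.0) if fit.mode == "discrete" else f_hi
    return float(np.max(np.maximum(np.abs(ecdf_hi - f_hi), np.abs(ecdf_lo - f_lo))))


# ---------------------------------------------------------------------------
# fitting at a fixed cutoff / cutoff selection


def fit_at(
    sample: TailSample,
    law: Law,
    x_min: float,
    x_max: Optional[float] = None,
) -> TailFit:
    """Fit one law by MLE at a fixed ``x_min`` and attach its KS distance."""
    boundary = False
    if law == "powerlaw":
        if sample.mode == "discrete":
            param, ll, boundary = mle_powerlaw_discrete(sample, x_min)
        else:
            param, ll = mle_powerlaw_continuous(sample, x_min, x_max)
    elif law == "exponential":
        param, ll = mle_exponential(sample, x_min, x_max)
    else:
        raise ValueError(f"unknown law {law!r}")
    start = _support_start(x_min, sample.mode)
    n_tail = int(sample.tail(start, x_max).size)
    fit = TailFit(
        law=law,
        mode=sample.mode,
        param=param,
        x_min=start,
        x_max=x_max,
        n_tail=n_tail,
        tail_fraction=n_tail / sample.n,
        log_likelihood=ll,
        ks=math.nan,
        boundary=boundary,
    )
    return replace(fit, ks=ks_distance(sample, fit))


def select_x_min(
    sample: TailSample,
    law: Law,
    min_tail: int = 10,
    x_max: Optional[float] = None,
    candidates: Optional[Sequence[float]] = None,
) -> TailFit:
    """Choose ``x_min`` by KS minimization over candidate cutoffs.

    Candidates default to the unique sample values; each candidate keeping at
    least ``min_tail`` observations is fitted by MLE and scored by its KS
    distance; the smallest KS wins, ties broken toward the smaller ``x_min``
    (the larger tail). The default exhaustive scan is evaluated on
    precomputed suffix statistics of the sorted sample; explicit candidate
    lists and truncated (``x_max``) fits go through the generic per-cutoff
    path.
    """
    if candidates is not None or x_max is not None:
        return _select_scan(sample, law, candidates, min_tail, x_max)

    uniq, counts = np.unique(sample.values, return_counts=True)
    n = sample.n
    cum = np.cumsum(counts)
    below = cum - counts  # values strictly below uniq[k]
    n_tail = n - below
    logs = np.log(uniq)
    suf_log = np.cumsum((counts * logs)[::-1])[::-1]
    suf_sum = np.cumsum((counts * uniq)[::-1])[::-1]
    best: Optional[TailFit] = None
    for k in range(uniq.size):
        nt = int(n_tail[k])
        if nt < min_tail:
            break  # n_tail only shrinks as the cutoff rises
        start = float(uniq[k])
        boundary = False
        if law == "powerlaw":
            s = float(suf_log[k] - nt * logs[k])
            if sample.mode == "continuous":
                if n - cum[k] < 2 or s <= 0:
                    continue
                param = 1.0 + nt / s
                ll = nt * math.log(param - 1.0) - nt * logs[k] - param * s
            else:
                if n - cum[k] < 1:
                    continue
                lsum = float(suf_log[k])

                def neg_ll(a, _n=nt, _st=start, _ls=lsum):
                    return _n * math.log(special.zeta(a, _st)) + a * _ls

                res = optimize.minimize_scalar(
                    neg_ll, bounds=ALPHA_BRACKET, method="bounded",
                    options={"xatol": 1e-8},
                )
                param, ll = float(res.x), -float(res.fun)
                boundary = (
                    param <= ALPHA_BRACKET[0] + 1e-5
                    or param >= ALPHA_BRACKET[1] - 1e-5
                )
        else:
            xbar = float(suf_sum[k]) / nt
            if xbar <= start:
                continue
            param = 1.0 / (xbar - start)
            centered = float(suf_sum[k]) - nt * start
            if sample.mode == "discrete":
                ll = nt * math.log1p(-math.exp(-param)) - param * centered
            else:
                ll = nt * math.log(param) - param * centered
        fit = TailFit(
            law=law, mode=sample.mode, param=param, x_min=start, x_max=None,
            n_tail=nt, tail_fraction=nt / n, log_likelihood=ll,
            ks=math.nan, boundary=boundary,
        )
        f_hi = _fit_cdf(fit, uniq[k:])
        f_lo = _fit_cdf(fit, uniq[k:] - 1.0) if sample.mode == "discrete" else f_hi
        ecdf_hi = (cum[k:] - below[k]) / nt
        ecdf_lo = (below[k:] - below[k]) / nt
        ks = float(np.max(np.maximum(np.abs(ecdf_hi - f_hi),
                                     np.abs(ecdf_lo - f_lo))))
        if best is None or ks < best.ks - 1e-15:
            best = replace(fit, ks=ks)
    if best is None:
        raise DegenerateTailError(
            f"no x_min candidate keeps a fittable tail of >= {min_tail} values"
        )
    return best


def _select_scan(
    sample: TailSample,
    law: Law,
    candidates: Optional[Sequence[float]],
    min_tail: int,
    x_max: Optional[float],
) -> TailFit:
    """Generic per-cutoff scan (used for custom candidates / truncation)."""
    if candidates is None:
        candidates = np.unique(sample.values)
    best: Optional[TailFit] = None
    for xm in np.sort(np.asarray(candidates, dtype=float)):
        start = _support_start(xm, sample.mode)
        if sample.tail(start, x_max).size < min_tail:
            continue
        try:
            fit = fit_at(sample, law, start, x_max)
        except (DegenerateTailError, NotImplementedError):
            continue
        if best is None or fit.ks < best.ks - 1e-15:
            best = fit
    if best is None:
        raise DegenerateTailError(
            f"no x_min candidate keeps a tail of >= {min_tail} values"
        )
    return best


# ---------------------------------------------------------------------------
# sampling from a fitted law


def sample_fitted(
    fit: TailFit, n: int, seed: int | np.random.Generator
) -> TailSample:
    """Draw ``n`` i.i.d. values from the fitted tail law.

    Continuous laws use the inverse CDF; the discrete power law uses an
    exact inverse-CDF table (Hurwitz-zeta tail ratios) with a geometrically
    grown support, and the discrete exponential the exact geometric inverse.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.random(n)
    a = fit.param
    start = _support_start(fit.x_min, fit.mode)
    if fit.mode == "continuous":
        if fit.law == "powerlaw":
            if fit.x_max is None:
                x = start * (1.0 - u) ** (-1.0 / (a - 1.0))
            else:
                lo, hi = start ** (1 - a), fit.x_max ** (1 - a)
                x = (lo - u * (lo - hi)) ** (1.0 / (1 - a))
        else:
            if fit.x_max is None:
                x = start - np.log1p(-u) / a
            else:
                z = -math.expm1(-a * (fit.x_max - start))
                x = start - np.log1p(-u * z) / a
        return TailSample(x, "continuous")
    if fit.law == "exponential":
        k = start + np.floor(-np.log1p(-u) / a)
        return TailSample(k, "discrete")
    # discrete power law: exact inverse CDF. A bounded table covers the
    # bulk; the few draws beyond it are inverted one by one with a
    # doubling-then-bisection search on the Hurwitz-zeta tail.
    z0 = special.zeta(a, start)
    k_table = int(start) + 65536
    ks = np.arange(start, k_table + 1.0)
    cdf = 1.0 - special.zeta(a, ks + 1.0) / z0

    def _f(k: float) -> float:  # P(X <= k)
        return 1.0 - special.zeta(a, k + 1.0) / z0

    x = np.empty(n)
    in_table = u <= cdf[-1]
    idx = np.searchsorted(cdf, u[in_table], side="left")
    x[in_table] = ks[idx]
    for i in np.where(~in_table)[0]:
        lo, hi = float(k_table), 2.0 * k_table
        while _f(hi) < u[i]:
            lo, hi = hi, hi * 2.0
        while hi - lo > 1.0:  # invariant: F(lo) < u[i] <= F(hi)
            mid = math.floor((lo + hi) / 2.0)
            if _f(mid) < u[i]:
                lo = mid
            else:
                hi = mid
        x[i] = hi
    return TailSample(x, "discrete")


# ---------------------------------------------------------------------------
# goodness of fit


def gof_pvalue(
    sample: TailSample,
    fit: TailFit,
    n_replicates: int = 1000,
    seed: int = 0,
    resample: Literal["parametric", "semiparametric"] = "parametric",
) -> GofResult:
    """Parametric-bootstrap goodness-of-fit p-value.

    Each replicate draws ``fit.n_tail`` values from the fitted law,
    re-estimates the parameter at the *same* ``x_min``, and records the KS
    distance; the p-value is the fraction of replicates whose KS is
    *strictly* greater than the observed one (so a perfect observed fit has
    p = 1). ``resample="semiparametric"`` instead redraws full-sample-sized
    replicates mixing empirical body values (below ``x_min``) with
    tail-law draws, then re-fits at the same cutoff.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    observed = fit.ks if np.isfinite(fit.ks) else ks_distance(sample, fit)
    start = _support_start(fit.x_min, fit.mode)
    body = sample.values[sample.values < start]
    exceed = 0
    for _ in range(n_replicates):
        if resample == "parametric":
            rep_vals = sample_fitted(fit, fit.n_tail, rng).values
        elif resample == "semiparametric":
            n_from_tail = int(rng.binomial(sample.n, fit.tail_fraction))
            n_from_tail = max(n_from_tail, 2)
            parts = [sample_fitted(fit, n_from_tail, rng).values]
            n_body = sample.n - n_from_tail
            if n_body > 0 and body.size > 0:
                parts.append(rng.choice(body, size=n_body, replace=True))
            rep_vals = np.concatenate(parts)
        else:
            raise ValueError(f"unknown resample scheme {resample!r}")
        rep = TailSample(rep_vals, sample.mode)
        try:
            rep_fit = fit_at(rep, fit.law, start, fit.x_max)
        except DegenerateTailError:
            exceed += 1  # unfittable replicate counts as a poorer fit
            continue
        if rep_fit.ks > observed:
            exceed += 1
    return GofResult(
        p_value=exceed / n_replicates,
        n_replicates=n_replicates,
        observed_ks=observed,
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
    )


# ---------------------------------------------------------------------------
# model comparison


def _log_density(fit: TailFit, x: np.ndarray) -> np.ndarray:
    """Log pdf/pmf of the fitted law on its support."""
    a = fit.param
    start = _support_start(fit.x_min, fit.mode)
    if fit.mode == "continuous":
        if fit.law == "powerlaw":
            return math.log(a - 1.0) - math.log(start) - a * np.log(x / start)
        return math.log(a) - a * (x - start)
    if fit.law == "powerlaw":
        return -a * np.log(x) - math.log(special.zeta(a, start))
    return math.log1p(-math.exp(-a)) - a * (x - start)


def llr_compare(
    sample: TailSample,
    fit_pl: TailFit,
    fit_exp: TailFit,
    significance_threshold: float = 0.05,
) -> LlrResult:
    """Vuong log-likelihood-ratio comparison of the two fitted laws.

    Both laws are re-fitted by MLE above a common cutoff (the arithmetic
    mean of the two selected ``x_min``); the statistic is the summed
    per-point log-likelihood difference (power law minus exponential) and
    its significance the two-sided normal tail probability of
    ``|llr| / (sigma * sqrt(n))`` with ``sigma`` the empirical standard
    deviation of the per-point differences.
    """
    common = 0.5 * (fit_pl.x_min + fit_exp.x_min)
    start = _support_start(common, sample.mode)
    x = sample.tail(start)
    n = x.size
    pl = fit_at(sample, "powerlaw", start)
    ex = fit_at(sample, "exponential", start)
    diffs = _log_density(pl, x) - _log_density(ex, x)
    llr = float(np.sum(diffs))
    sigma = float(np.std(diffs, ddof=1)) if n > 1 else 0.0
    if sigma <= 0 or n < 2:
        return LlrResult(llr, math.nan, start, n, "inconclusive")
    z = abs(llr) / (sigma * math.sqrt(n))
    significance = float(2.0 * stats.norm.sf(z))
    if llr > 0 and significance <= significance_threshold:
        verdict = "PL"
    elif llr < 0 and significance <= significance_threshold:
        verdict = "Exp"
    else:
        verdict = "inconclusive"
    return LlrResult(llr, significance, start, n, verdict)


# ---------------------------------------------------------------------------
# fitting analytically computed tail curves


def fit_tail_curve(
    curve,
    law: Law,
    n_pseudo: int = 10_000,
    min_tail: int = 10,
    x_max: Optional[float] = None,
) -> TailFit:
    """Fit a tail law to an analytically computed tail-probability curve.

    The curve (an object with increasing ``levels`` and the tail
    probabilities ``probs = P(X > a)``) is converted into ``n_pseudo``
    deterministic quantile pseudo-observations at plotting positions
    ``(k - 0.5) / n_pseudo``, which are then passed through the standard
    ``select_x_min`` machinery. The log-likelihood-ratio test is *not*
    applicable to such fits (it is defined for samples, not distributions).
    """
    levels = np.asarray(curve.levels, dtype=float)
    probs = np.asarray(curve.probs, dtype=float)
    if levels.ndim != 1 or levels.size < 2 or np.any(np.diff(levels) <= 0):
        raise ValueError("curve levels must be strictly increasing")
    if np.any(np.diff(probs) > 1e-12) or probs[0] <= probs[-1]:
        raise ValueError("curve must be a decreasing tail function")
    g = probs / probs[0]  # conditional tail given X > levels[0]
    q = (np.arange(1, n_pseudo + 1) - 0.5) / n_pseudo
    # invert g (decreasing) at 1 - q
    x = np.interp(1.0 - q, g[::-1], levels[::-1])
    pseudo = TailSample(x[x > 0], "continuous")
    return select_x_min(pseudo, law, min_tail=min_tail, x_max=x_max)


# ---------------------------------------------------------------------------
# the naive log-log line fit (for contrast with the likelihood machinery)


def loglog_histogram_fit(
    values: np.ndarray,
    x_min: Optional[float] = None,
    n_bins: int = 20,
) -> tuple[float, float]:
    """Least-squares line through the log-binned log-density histogram.

    The classic graphical power-law check: bin the values into
    logarithmically spaced bins above ``x_min``, regress ``log(density)``
    on ``log(bin center)``, and report ``(slope, r_squared)``. A straight
    line (``r_squared`` near 1) is what log-log plots reward — the whole
    point of the likelihood machinery in this module is that such lines
    arise just as readily from exponentially tailed data.
    """
    v = np.asarray(values, dtype=float)
    if x_min is not None:
        v = v[v >= x_min]
    if v.size < 10:
        raise ValueError("too few values for a histogram fit")
    lo, hi = v.min(), v.max()
    if hi <= lo:
        raise ValueError("degenerate value range")
    edges = np.geomspace(lo, hi * (1 + 1e-12), n_bins + 1)
    hist, _ = np.histogram(v, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    dens = hist / widths / v.size
    keep = dens > 0
    if keep.sum() < 3:
        raise ValueError("too few occupied bins")
    lx, ly = np.log(centers[keep]), np.log(dens[keep])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return float(slope), r2
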