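"""Avalanche scaling statistics: power-law exponents, the crackling-noise
exponent relation, and avalanche-shape collapse.

At criticality the avalanche observables obey

    P(S) ~ S^-tau,    P(T) ~ T^-alpha,    <S>(T) ~ T^gamma,

and the three exponents are tied by the crackling-noise relation

    gamma = (alpha - 1) / (tau - 1).

Density and cumulative exponents differ by exactly one: a density
exponent tau corresponds to a complementary-cumulative exponent tau - 1.

Exponents are estimated two ways side by side — discrete truncated
maximum likelihood (primary) and a least-squares fit to the
complementary CDF (figure parity) — because neither dominates for all
uses; the MLE feeds the relation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import linregress

from .avalanche import Avalanche, mean_profile
from .errors import EmptyResultError, FitRefusedError

__all__ = [
    "PowerlawFit",
    "ScalingFit",
    "CollapseResult",
    "fit_powerlaw_tail",
    "fit_size_vs_duration",
    "exponent_relation_check",
    "shape_collapse",
    "analyze_ensemble",
]

MIN_TAIL_SAMPLES = 100
MIN_AVALANCHES_PER_DURATION = 20
MIN_DISTINCT_DURATIONS = 10


@dataclass
class PowerlawFit:
    """Truncated discrete power-law fit on [x_min, x_max].

    ``exponent`` is the density (PDF) exponent by maximum likelihood;
    ``exponent_ccdf`` the least-squares slope magnitude of the empirical
    complementary CDF (cumulative exponent, i.e. density - 1 for an
    ideal power law)."""

    exponent: float
    stderr: float
    exponent_ccdf: float
    stderr_ccdf: float
    x_min: int
    x_max: int
    n_samples: int

    @property
    def cumulative_exponent(self) -> float:
        return self.exponent - 1.0


@dataclass
class ScalingFit:
    """Joint exponent fit for one avalanche ensemble."""

    size_fit: PowerlawFit
    duration_fit: PowerlawFit
    gamma: float
    gamma_stderr: float
    gamma_range: tuple[int, int]
    relation_residual: float = field(init=False)
    relation_stderr: float = field(init=False)

    def __post_init__(self):
        res, se = exponent_relation_check(
            self.size_fit.exponent, self.size_fit.stderr,
            self.duration_fit.exponent, self.duration_fit.stderr,
            self.gamma, self.gamma_stderr)
        self.relation_residual = res
        self.relation_stderr = se

    @property
    def tau_s(self) -> float:
        return self.size_fit.exponent

    @property
    def alpha_t(self) -> float:
        return self.duration_fit.exponent

    @property
    def relation_consistent(self) -> bool:
        """True when the residual gamma - (alpha-1)/(tau-1) is within two
        propagated standard errors of zero."""
        return abs(self.relation_residual) <= 2.0 * self.relation_stderr

    def to_dict(self) -> dict:
        return {
            "tau_s": self.tau_s,
            "tau_s_stderr": self.size_fit.stderr,
            "tau_s_cumulative": self.size_fit.cumulative_exponent,
            "tau_s_ccdf_lsq": self.size_fit.exponent_ccdf,
            "size_range": [self.size_fit.x_min, self.size_fit.x_max],
            "alpha_t": self.alpha_t,
            "alpha_t_stderr": self.duration_fit.stderr,
            "alpha_t_cumulative": self.duration_fit.cumulative_exponent,
            "alpha_t_ccdf_lsq": self.duration_fit.exponent_ccdf,
            "duration_range": [self.duration_fit.x_min,
                               self.duration_fit.x_max],
            "gamma": self.gamma,
            "gamma_stderr": self.gamma_stderr,
            "gamma_range": list(self.gamma_range),
            "relation_residual": self.relation_residual,
            "relation_stderr": self.relation_stderr,
            "relation_consistent": self.relation_consistent,
        }


@dataclass
class CollapseResult:
    """Shape-collapse scan result.

    ``collapse_error`` is the normalized variance across rescaled mean
    profiles at the best exponent; ``baseline_error`` the same quantity
    without amplitude rescaling (gamma = 1), the reference an actual
    collapse must beat."""

    gamma_shape: float
    gamma_stderr: float
    collapse_error: float
    baseline_error: float
    durations: list[int]

    def to_dict(self) -> dict:
        return {
            "gamma_shape": self.gamma_shape,
            "gamma_shape_stderr": self.gamma_stderr,
            "collapse_error": self.collapse_error,
            "baseline_error": self.baseline_error,
            "durations": self.durations,
        }


def _truncated_zipf_logZ(tau: float, support: np.ndarray) -> float:
    return float(np.log(np.sum(support ** (-tau))))


def fit_powerlaw_tail(samples, x_min: int, x_max: int) -> PowerlawFit:
    """Discrete truncated power-law fit to samples restricted to
    [x_min, x_max].

    MLE maximizes the truncated Zipf likelihood
    ``P(x) = x^-tau / sum_{k=x_min}^{x_max} k^-tau``; the standard error
    comes from the observed information (model variance of log X).  A
    least-squares fit of log CCDF vs log x over the same range is
    reported alongside.  Refuses when fewer than 100 samples fall in
    range or the in-range support is degenerate.
    """
    x = np.asarray(samples, dtype=np.int64)
    if x.size and x.min() < 1:
        raise FitRefusedError("samples must be positive integers")
    if x_min < 1 or x_max <= x_min:
        raise FitRefusedError(f"bad fit range [{x_min}, {x_max}]")
    x = x[(x >= x_min) & (x <= x_max)]
    if x.size < MIN_TAIL_SAMPLES:
        raise FitRefusedError(
            f"only {x.size} samples in [{x_min}, {x_max}] "
            f"(need >= {MIN_TAIL_SAMPLES})")
    if np.unique(x).size < 2:
        raise FitRefusedError("degenerate support: all in-range samples equal")

    support = np.arange(x_min, x_max + 1, dtype=np.float64)
    log_support = np.log(support)
    mean_logx = float(np.log(x).mean())

    def nll(tau: float) -> float:
        return _truncated_zipf_logZ(tau, support) + tau * mean_logx

    res = minimize_scalar(nll, bounds=(0.05, 8.0), method="bounded",
                          options={"xatol": 1e-7})
    tau = float(res.x)
    # observed information: n * Var_tau(log X) under the fitted model
    p = support ** (-tau)
    p /= p.sum()
    var_log = float(np.sum(p * log_support ** 2) - np.sum(p * log_support) ** 2)
    stderr = 1.0 / np.sqrt(x.size * var_log) if var_log > 0 else float("inf")

    # CCDF least squares over the same range (figure-parity estimator)
    vals, counts = np.unique(x, return_counts=True)
    ccdf = 1.0 - np.concatenate(([0.0], np.cumsum(counts[:-1]))) / x.size
    lr = linregress(np.log(vals.astype(np.float64)), np.log(ccdf))
    return PowerlawFit(exponent=tau, stderr=stderr,
                       exponent_ccdf=float(-lr.slope),
                       stderr_ccdf=float(lr.stderr),
                       x_min=int(x_min), x_max=int(x_max),
                       n_samples=int(x.size))


def mean_size_by_duration(avalanches: list[Avalanche]) -> tuple[np.ndarray,
                                                                np.ndarray,
                                                                np.ndarray]:
    """Durations, mean sizes <S>(T), and counts, duration-sorted."""
    t = np.array([a.duration for a in avalanches], dtype=np.int64)
    s = np.array([a.size for a in avalanches], dtype=np.float64)
    durations = np.unique(t)
    means = np.array([s[t == d].mean() for d in durations])
    counts = np.array([(t == d).sum() for d in durations])
    return durations, means, counts


def fit_size_vs_duration(avalanches: list[Avalanche], t_min: int,
                         t_max: int) -> tuple[float, float]:
    """Least-squares slope gamma of log <S>(T) against log T.

    Only durations in [t_min, t_max] populated by at least 20 avalanches
    enter the fit; at least 10 such distinct durations are required.
    Returns (gamma, stderr).
    """
    durations, means, counts = mean_size_by_duration(avalanches)
    keep = ((durations >= t_min) & (durations <= t_max)
            & (counts >= MIN_AVALANCHES_PER_DURATION))
    if keep.sum() < MIN_DISTINCT_DURATIONS:
        raise FitRefusedError(
            f"only {int(keep.sum())} durations in [{t_min}, {t_max}] with "
            f">= {MIN_AVALANCHES_PER_DURATION} avalanches "
            f"(need >= {MIN_DISTINCT_DURATIONS})")
    lr = linregress(np.log(durations[keep].astype(np.float64)),
                    np.log(means[keep]))
    return float(lr.slope), float(lr.stderr)


def exponent_relation_check(tau: float, tau_se: float, alpha: float,
                            alpha_se: float, gamma: float,
                            gamma_se: float) -> tuple[float, float]:
    """Crackling-noise relation residual gamma - (alpha-1)/(tau-1) with
    first-order error propagation.  Returns (residual, stderr)."""
    residual = gamma - (alpha - 1.0) / (tau - 1.0)
    d_alpha = -1.0 / (tau - 1.0)
    d_tau = (alpha - 1.0) / (tau - 1.0) ** 2
    stderr = float(np.sqrt(gamma_se ** 2 + (d_alpha * alpha_se) ** 2
                           + (d_tau * tau_se) ** 2))
    return float(residual), stderr


def _collapse_error(avalanches, durations, gamma, n_bins):
    curves = np.stack([mean_profile(avalanches, d, n_bins, gamma)[1]
                       for d in durations])
    grand = curves.mean(axis=0)
    denom = float(np.mean(grand ** 2))
    if denom == 0.0:
        return float("inf")
    return float(np.mean(curves.var(axis=0)) / denom)


def shape_collapse(avalanches: list[Avalanche],
                   candidate_gammas=None,
                   durations: list[int] | None = None,
                   n_bins: int = 25,
                   min_per_class: int = 50) -> CollapseResult:
    """Scan collapse exponents over duration classes.

    For each candidate gamma the mean profiles of the duration classes
    are rescaled (time to t/T, amplitude to profile / T^(gamma-1)) onto
    a common grid and the variance across classes, normalized by the
    squared grand mean, is computed; the minimizing gamma wins.  The
    stderr is read from the local curvature of the error curve.
    """
    if candidate_gammas is None:
        candidate_gammas = np.arange(1.0, 3.01, 0.02)
    candidate_gammas = np.asarray(candidate_gammas, dtype=np.float64)
    counts: dict[int, int] = {}
    for a in avalanches:
        counts[a.duration] = counts.get(a.duration, 0) + 1
    if durations is None:
        durations = sorted(d for d, c in counts.items()
                           if c >= min_per_class and d >= 2)
    else:
        durations = sorted(durations)
        lacking = [d for d in durations if counts.get(d, 0) < min_per_class]
        if lacking:
            raise FitRefusedError(
                f"duration classes {lacking} have fewer than "
                f"{min_per_class} avalanches")
    if len(durations) < 3:
        raise FitRefusedError(
            f"need >= 3 duration classes with >= {min_per_class} "
            f"avalanches, found {len(durations)}")

    errors = np.array([_collapse_error(avalanches, durations, g, n_bins)
                       for g in candidate_gammas])
    k = int(np.argmin(errors))
    gamma_best = float(candidate_gammas[k])
    err_best = float(errors[k])
    # refine via parabola through the bracketing grid points; the
    # curvature also yields a (heuristic) one-sigma width where the
    # error rises by err_best above its minimum
    if 0 < k < len(candidate_gammas) - 1:
        g0, g1, g2 = candidate_gammas[k - 1:k + 2]
        e0, e1, e2 = errors[k - 1:k + 2]
        denom = (e0 - 2 * e1 + e2)
        if denom > 0:
            h = g1 - g0
            gamma_best = float(g1 + 0.5 * h * (e0 - e2) / denom)
            curv = denom / h ** 2
            gamma_se = float(np.sqrt(2.0 * max(err_best, 1e-12) / curv))
        else:
            gamma_se = float(candidate_gammas[1] - candidate_gammas[0])
    else:
        gamma_se = float(candidate_gammas[1] - candidate_gammas[0])
    baseline = _collapse_error(avalanches, durations, 1.0, n_bins)
    return CollapseResult(gamma_shape=gamma_best, gamma_stderr=gamma_se,
                          collapse_error=err_best, baseline_error=baseline,
                          durations=list(durations))


def default_size_range(avalanches: list[Avalanche],
                       n_nodes: int) -> tuple[int, int]:
    """Default size fit range [1, N/2]: the distribution is power-law
    almost up to network size, with finite-size mass near S ~ N."""
    return 1, max(2, n_nodes // 2)


def default_duration_range(avalanches: list[Avalanche],
                           n_nodes: int) -> tuple[int, int]:
    """Default duration fit range [1, knee], the knee being the first
    duration whose mean size exceeds N/2 — beyond it avalanches span
    most of the system, cutting off the scaling regime."""
    durations, means, _ = mean_size_by_duration(avalanches)
    above = durations[means > 0.5 * n_nodes]
    t_max = int(above.min()) - 1 if above.size else int(durations.max())
    return 1, max(2, t_max)


def analyze_ensemble(avalanches: list[Avalanche], n_nodes: int,
                     size_range: tuple[int, int] | None = None,
                     duration_range: tuple[int, int] | None = None,
                     gamma_range: tuple[int, int] | None = None,
                     ) -> ScalingFit:
    """Full scaling fit for one ensemble: tau from sizes, alpha from
    durations, gamma from <S>(T), plus the relation residual.

    Ranges default to the finite-size heuristics of
    :func:`default_size_range` / :func:`default_duration_range`; the
    gamma fit reuses the duration range.
    """
    sizes = [a.size for a in avalanches]
    durs = [a.duration for a in avalanches]
    s_rng = size_range or default_size_range(avalanches, n_nodes)
    t_rng = duration_range or default_duration_range(avalanches, n_nodes)
    g_rng = gamma_range or t_rng
    size_fit = fit_powerlaw_tail(sizes, *s_rng)
    duration_fit = fit_powerlaw_tail(durs, *t_rng)
    gamma, gamma_se = fit_size_vs_duration(avalanches, *g_rng)
    return ScalingFit(size_fit=size_fit, duration_fit=duration_fit,
                      gamma=gamma, gamma_stderr=gamma_se,
                      gamma_range=tuple(g_rng))
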