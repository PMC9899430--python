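"""Closed-form quantities of the Gompertz / AR(1) population model.

On the log scale the stochastic Gompertz model is the AR(1) process

    y_t = r + beta * y_{t-1} + eps_t,      eps_t ~ N(0, sigma2) i.i.d.,

with beta = 1 - r/k measuring the strength of density dependence.  For
|beta| < 1 the process is stationary with Normal stationary distribution
of mean mu_inf = r/(1-beta) = k and variance v_inf = sigma2/(1-beta^2).
The excess of v_inf over the environmental variance sigma2 is the
density-dependent variance component

    sigma2_dd = beta^2 * sigma2 / (1 - beta^2),

so the proportion of stationary variance attributable to density
regulation is phi_dd = sigma2_dd / v_inf = beta^2 — independent of the
noise level.  These functions are pure, total on their stated domains,
and serve as the oracle layer for the simulators, the fitting code and
the simulation experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "NonstationaryError",
    "StationarySummary",
    "VarianceDecomposition",
    "beta_from_rk",
    "k_from_rbeta",
    "stationary_mean",
    "stationary_variance",
    "dd_variance",
    "dd_proportion",
    "analytic_decomposition",
    "deterministic_solution",
    "theoretical_autocovariance",
    "ricker_linearized_variance",
]


class NonstationaryError(ValueError):
    """Raised when a stationary quantity is requested for |beta| >= 1."""


def _require_stationary(beta: float) -> None:
    if abs(beta) >= 1.0:
        if beta == 1.0:
            raise NonstationaryError(
                "beta = 1: the log-abundance is a random walk with drift; "
                "Var(y_t) = t*sigma2 grows without bound and no stationary "
                "distribution exists"
            )
        raise NonstationaryError(
            f"|beta| = {abs(beta):g} >= 1: the AR(1) process is explosive "
            "and has no stationary distribution"
        )


@dataclass(frozen=True)
class StationarySummary:
    """Stationary mean and variance of log-abundance under Gompertz dynamics."""

    mu_inf: float
    v_inf: float


@dataclass(frozen=True)
class VarianceDecomposition:
    """Split of the stationary variance into environmental and
    density-dependent parts.

    ``sigma2_env + sigma2_dd = v_inf`` holds by construction.  Empirical
    decompositions (v_inf from data, sigma2_env estimated) can yield a
    negative ``sigma2_dd`` through sampling noise; such records are kept
    and flagged via :attr:`negative_dd` rather than clipped.
    """

    v_inf: float
    sigma2_env: float
    sigma2_dd: float
    phi_dd: float

    @property
    def negative_dd(self) -> bool:
        return self.sigma2_dd < 0.0


def beta_from_rk(r: float, k: float) -> float:
    """Density-dependence strength beta = 1 - r/k of the AR(1) form."""
    if k == 0:
        raise ZeroDivisionError("k must be nonzero")
    if r <= 0 or k <= 0:
        raise ValueError(f"r and k must be positive, got r={r}, k={k}")
    return 1.0 - r / k


def k_from_rbeta(r: float, beta: float) -> float:
    """Log carrying capacity k = r/(1-beta); inverse of :func:`beta_from_rk`."""
    if r <= 0:
        raise ValueError(f"r must be positive, got {r}")
    if beta >= 1:
        raise NonstationaryError(
            f"beta = {beta:g} >= 1 corresponds to k -> infinity "
            "(density-independent dynamics)"
        )
    return r / (1.0 - beta)


def stationary_mean(intercept: float, beta: float) -> float:
    """Stationary mean mu_inf = intercept/(1-beta), equal to k for the
    Gompertz parameterization (intercept = r)."""
    _require_stationary(beta)
    return intercept / (1.0 - beta)


def stationary_variance(beta: float, sigma2: float) -> float:
    """Stationary variance v_inf = sigma2 / (1 - beta^2)."""
    _require_stationary(beta)
    if sigma2 < 0:
        raise ValueError(f"sigma2 must be >= 0, got {sigma2}")
    return sigma2 / (1.0 - beta * beta)


def dd_variance(beta: float, sigma2: float) -> float:
    """Density-dependent variance component beta^2 * sigma2 / (1 - beta^2).

    Equals ``stationary_variance(beta, sigma2) - sigma2``: the amplification
    of environmental noise by the density feedback.
    """
    _require_stationary(beta)
    if sigma2 < 0:
        raise ValueError(f"sigma2 must be >= 0, got {sigma2}")
    b2 = beta * beta
    return b2 * sigma2 / (1.0 - b2)


def dd_proportion(beta: float) -> float:
    """Proportion of stationary variance due to density regulation: beta^2."""
    _require_stationary(beta)
    return beta * beta


def analytic_decomposition(beta: float, sigma2: float) -> VarianceDecomposition:
    """Full analytic variance decomposition at (beta, sigma2)."""
    v = stationary_variance(beta, sigma2)
    dd = dd_variance(beta, sigma2)
    return VarianceDecomposition(
        v_inf=v, sigma2_env=sigma2, sigma2_dd=dd, phi_dd=dd_proportion(beta)
    )


def deterministic_solution(y0: float, intercept: float, beta: float, t: int) -> float:
    """Noise-free log-abundance after t steps: y_t = y_inf + beta^t (y0 - y_inf).

    Closed form of the linear difference equation y_t = intercept + beta*y_{t-1};
    agrees with direct iteration to round-off.
    """
    if t < 0:
        raise ValueError(f"t must be a non-negative integer, got {t}")
    y_inf = stationary_mean(intercept, beta)
    return y_inf + beta**t * (y0 - y_inf)


def theoretical_autocovariance(h: int, beta: float, sigma2: float) -> float:
    """Lag-h stationary autocovariance beta^h * v_inf of the AR(1) process."""
    if h < 0:
        raise ValueError(f"lag h must be >= 0, got {h}")
    return beta**h * stationary_variance(beta, sigma2)


def ricker_linearized_variance(r: float, sigma2: float) -> float:
    """Small-noise log-scale stationary variance of the Ricker model.

    Linearizing the Ricker map about its equilibrium K gives a log-scale
    AR(1) with coefficient 1 - r, hence variance sigma2 / (1 - (1-r)^2).
    This is an approximation valid for sigma2 small relative to the
    curvature of the map; it is used as a simulation oracle only, never as
    an exact Ricker result.
    """
    if not 0.0 < r < 2.0:
        raise ValueError(
            f"linearization requires 0 < r < 2 (|1-r| < 1), got r={r}"
        )
    if sigma2 < 0:
        raise ValueError(f"sigma2 must be >= 0, got {sigma2}")
    c = 1.0 - r
    return sigma2 / (1.0 - c * c)
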