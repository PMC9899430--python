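"""Simulators for stochastic Gompertz and Ricker population dynamics.

This is the package's data-generating layer: replicated synthetic
trajectories are the inputs to every downstream fit and to the variance-
decomposition experiment.  The Gompertz model is simulated on the natural-log
scale, where it is exactly the linear AR(1) recursion

    y_t = y_{t-1} + r (1 - y_{t-1}/k) + eps_t  =  r + beta y_{t-1} + eps_t,

with beta = 1 - r/k and eps_t ~ N(0, sigma2) i.i.d.  The Ricker model is
simulated on the untransformed abundance scale,

    Y_t = Y_{t-1} exp{ r (1 - Y_{t-1}/K) + eps_t },

which is nonlinear and has no closed-form stationary distribution.

Trajectories carry burn-in bookkeeping (``n_discard``) so that stationary
summaries use only the tail of the series, after the transient approach to
the equilibrium has died out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.signal import lfilter

from .analytic import (
    NonstationaryError,
    StationarySummary,
    beta_from_rk,
    k_from_rbeta,
    stationary_mean,
    stationary_variance,
)

__all__ = [
    "GompertzParams",
    "ARForm",
    "RickerParams",
    "Trajectory",
    "simulate_gompertz",
    "simulate_ricker",
    "generate_ensemble",
    "stationary_segment",
]

SeedLike = int | tuple[int, ...] | np.random.SeedSequence


@dataclass(frozen=True)
class GompertzParams:
    """Stochastic Gompertz parameters: intrinsic growth rate ``r``, log
    carrying capacity ``k`` and environmental variance ``sigma2``.

    The derived AR(1) coefficient beta = 1 - r/k must satisfy |beta| < 1
    (i.e. 0 < r < 2k) so that a stationary distribution exists.
    """

    r: float
    k: float
    sigma2: float

    def __post_init__(self) -> None:
        if not (self.r > 0):
            raise ValueError(f"r must be > 0, got {self.r}")
        if not (self.k > 0):
            raise ValueError(f"k must be > 0, got {self.k}")
        if not (self.sigma2 >= 0):
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")
        if abs(self.beta) >= 1:
            raise NonstationaryError(
                f"r={self.r}, k={self.k} gives beta={self.beta:g}; "
                "|beta| < 1 (0 < r < 2k) is required for stationarity"
            )

    @property
    def beta(self) -> float:
        return beta_from_rk(self.r, self.k)

    @property
    def K(self) -> float:
        """Carrying capacity on the untransformed abundance scale, e^k."""
        return math.exp(self.k)

    def to_ar(self) -> "ARForm":
        return ARForm(intercept=self.r, beta=self.beta, sigma2=self.sigma2)


@dataclass(frozen=True)
class ARForm:
    """The Gompertz model written as an AR(1) process
    y_t = intercept + beta*y_{t-1} + eps_t; bijective with
    :class:`GompertzParams` through beta = 1 - r/k, k = r/(1-beta).
    """

    intercept: float
    beta: float
    sigma2: float

    def __post_init__(self) -> None:
        if not (self.sigma2 >= 0):
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")

    @property
    def is_stationary(self) -> bool:
        return abs(self.beta) < 1

    def to_gompertz(self) -> GompertzParams:
        return GompertzParams(
            r=self.intercept,
            k=k_from_rbeta(self.intercept, self.beta),
            sigma2=self.sigma2,
        )

    def stationary_summary(self) -> StationarySummary:
        return StationarySummary(
            mu_inf=stationary_mean(self.intercept, self.beta),
            v_inf=stationary_variance(self.beta, self.sigma2),
        )


@dataclass(frozen=True)
class RickerParams:
    """Stochastic Ricker parameters on the abundance scale: intrinsic growth
    rate ``r``, carrying capacity ``K`` (untransformed, not logged) and
    environmental variance ``sigma2`` of the shocks to the log growth rate.
    """

    r: float
    K: float
    sigma2: float

    def __post_init__(self) -> None:
        if not (self.r > 0):
            raise ValueError(f"r must be > 0, got {self.r}")
        if not (self.K > 0):
            raise ValueError(f"K must be > 0, got {self.K}")
        if not (self.sigma2 >= 0):
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")


@dataclass(frozen=True)
class Trajectory:
    """A simulated (or externally supplied) population time series.

    ``values[0]`` is the initial condition; ``values[1:]`` are the
    ``n_total`` simulated steps.  The first ``n_discard`` post-initial
    values are flagged as transient and excluded by
    :func:`stationary_segment`.  Realized innovations are not stored:
    ``seed`` plus the generating parameters reproduce them.
    """

    values: np.ndarray
    scale: Literal["log", "natural"]
    y0: float
    n_total: int
    n_discard: int
    seed: SeedLike | None
    source: str = "external"
    params: object | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.scale not in ("log", "natural"):
            raise ValueError(f"scale must be 'log' or 'natural', got {self.scale!r}")
        if values.ndim != 1 or len(values) != self.n_total + 1:
            raise ValueError(
                f"values must be 1-D of length n_total+1={self.n_total + 1}, "
                f"got shape {values.shape}"
            )
        if not (0 <= self.n_discard <= self.n_total):
            raise ValueError(
                f"n_discard must be in [0, n_total], got {self.n_discard}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("trajectory contains non-finite values")
        if self.scale == "natural" and not np.all(values > 0):
            raise ValueError("natural-scale abundances must be strictly positive")

    def __len__(self) -> int:
        return len(self.values)


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(seed))


def simulate_gompertz(
    params: GompertzParams,
    y0: float,
    n_steps: int,
    seed: SeedLike,
    n_discard: int = 0,
) -> Trajectory:
    """Simulate a log-scale Gompertz trajectory of ``n_steps`` steps.

    With ``sigma2 = 0`` the output is the deterministic recursion; the same
    seed always reproduces the same trajectory bit for bit.
    """
    if not math.isfinite(y0):
        raise ValueError(f"y0 must be finite, got {y0}")
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    rng = _rng(seed)
    eps = rng.normal(0.0, math.sqrt(params.sigma2), size=n_steps)
    beta = params.beta
    # y_t = r + beta*y_{t-1} + eps_t is a first-order linear filter.
    y, _ = lfilter([1.0], [1.0, -beta], params.r + eps, zi=[beta * y0])
    values = np.concatenate(([y0], y))
    return Trajectory(
        values=values,
        scale="log",
        y0=y0,
        n_total=n_steps,
        n_discard=n_discard,
        seed=seed,
        source="gompertz",
        params=params,
    )


def simulate_ricker(
    params: RickerParams,
    Y0: float,
    n_steps: int,
    seed: SeedLike,
    n_discard: int = 0,
) -> Trajectory:
    """Simulate a natural-scale Ricker trajectory of ``n_steps`` steps.

    Aborts with :class:`FloatingPointError` if the abundance underflows to
    zero or overflows — possible in principle at large sigma2, a regime the
    variance-decomposition experiment never enters.
    """
    if not (Y0 > 0 and math.isfinite(Y0)):
        raise ValueError(f"Y0 must be a positive finite abundance, got {Y0}")
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    rng = _rng(seed)
    eps = rng.normal(0.0, math.sqrt(params.sigma2), size=n_steps)
    values = np.empty(n_steps + 1)
    values[0] = Y0
    r, K = params.r, params.K
    Y = Y0
    for t in range(n_steps):
        try:
            Y = Y * math.exp(r * (1.0 - Y / K) + eps[t])
        except OverflowError:
            Y = math.inf
        if Y <= 0.0 or not math.isfinite(Y):
            raise FloatingPointError(
                f"Ricker abundance left (0, inf) at step {t + 1} (Y={Y}); "
                "the simulation regime is numerically unstable"
            )
        values[t + 1] = Y
    return Trajectory(
        values=values,
        scale="natural",
        y0=Y0,
        n_total=n_steps,
        n_discard=n_discard,
        seed=seed,
        source="ricker",
        params=params,
    )


def generate_ensemble(
    model: Literal["gompertz", "ricker"],
    params: GompertzParams | RickerParams,
    n_replicates: int,
    n_steps: int,
    n_discard: int,
    base_seed: int,
    y0: float | None = None,
) -> list[Trajectory]:
    """Generate ``n_replicates`` independent replicate trajectories.

    Replicate i uses the RNG stream SeedSequence((base_seed, i)), so
    ensembles are reproducible and independent of generation order.  The
    initial value defaults to the carrying capacity on the model's scale
    (y0 = k for Gompertz, Y0 = K for Ricker).
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    if not (0 <= n_discard < n_steps):
        raise ValueError(
            f"need 0 <= n_discard < n_steps, got {n_discard}, {n_steps}"
        )
    if model == "gompertz":
        if not isinstance(params, GompertzParams):
            raise TypeError("model='gompertz' requires GompertzParams")
        start = params.k if y0 is None else y0
        sim = simulate_gompertz
    elif model == "ricker":
        if not isinstance(params, RickerParams):
            raise TypeError("model='ricker' requires RickerParams")
        start = params.K if y0 is None else y0
        sim = simulate_ricker
    else:
        raise ValueError(f"unknown model {model!r}")
    return [
        sim(params, start, n_steps, seed=(base_seed, i), n_discard=n_discard)
        for i in range(n_replicates)
    ]


def stationary_segment(traj: Trajectory) -> np.ndarray:
    """Retained stationary part of a trajectory: values after the initial
    condition and the ``n_discard`` transient steps."""
    if traj.n_discard >= traj.n_total:
        raise ValueError(
            f"n_discard={traj.n_discard} leaves no stationary points "
            f"(n_total={traj.n_total})"
        )
    return traj.values[traj.n_discard + 1 :]
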