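"""The zero-reverting Ornstein-Uhlenbeck perturbation m(t) of the transmission rate.

dm = -k m dt + theta dB.  Everything here is analytic: transient moments,
the invariant (stationary) density, the ergodic mean of |m|, and the exact
Gaussian transition used for bias-free sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "OUSpec",
    "ou_mean_var",
    "ou_stationary_variance",
    "ou_invariant_density",
    "ou_ergodic_abs_mean",
    "ou_exact_step",
    "ou_exact_path",
]


@dataclass(frozen=True)
class OUSpec:
    """Initial value m0, reversion speed k > 0 and volatility theta >= 0."""

    m0: float
    k: float
    theta: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"reversion speed k must be positive, got {self.k!r}")
        if self.theta < 0:
            raise ValueError(f"volatility theta must be nonnegative, got {self.theta!r}")


def ou_mean_var(spec: OUSpec, t: float) -> tuple[float, float]:
    """Exact transient mean and variance of m(t).

    E[m(t)] = m0 e^{-kt},  Var[m(t)] = theta^2 (1 - e^{-2kt}) / (2k).
    """
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t!r}")
    mean = spec.m0 * math.exp(-spec.k * t)
    var = spec.theta**2 * (1.0 - math.exp(-2.0 * spec.k * t)) / (2.0 * spec.k)
    return mean, var


def ou_stationary_variance(spec: OUSpec) -> float:
    """theta^2 / (2k), the t -> infinity limit of the transient variance."""
    return spec.theta**2 / (2.0 * spec.k)


def ou_invariant_density(x, spec: OUSpec):
    """Invariant density zeta(x) = sqrt(k/(pi theta^2)) exp(-k x^2/theta^2).

    This is the N(0, theta^2/(2k)) density, to which m(t) converges weakly.
    Vectorized over ``x``.  theta = 0 is degenerate (point mass at 0) and
    rejected.
    """
    if spec.theta <= 0:
        raise ValueError("invariant density is degenerate for theta = 0")
    x = np.asarray(x, dtype=float)
    out = np.sqrt(spec.k / (np.pi * spec.theta**2)) * np.exp(-spec.k * x**2 / spec.theta**2)
    return out if out.ndim else float(out)


def ou_ergodic_abs_mean(spec: OUSpec) -> float:
    """Ergodic limit of (1/t) int_0^t |m| dtau, namely theta / sqrt(pi k)."""
    return spec.theta / math.sqrt(math.pi * spec.k)


def ou_exact_step(m, dt: float, spec: OUSpec, noise):
    """One exact transition: m e^{-k dt} + theta sqrt((1-e^{-2k dt})/(2k)) * noise.

    ``noise`` is a standard-normal draw; the step is exact in distribution
    for any dt > 0, so long simulations carry no time-step bias.  Vectorized
    over ``m``/``noise``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    decay = math.exp(-spec.k * dt)
    scale = spec.theta * math.sqrt((1.0 - decay**2) / (2.0 * spec.k))
    return m * decay + scale * np.asarray(noise, dtype=float)


def ou_exact_path(spec: OUSpec, dt: float, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    """Sample m on a grid of n_steps exact transitions (length n_steps + 1).

    The AR(1) recursion m_{i+1} = a m_i + s h_i is run through a linear
    filter, which keeps multi-million-step paths cheap.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    a = math.exp(-spec.k * dt)
    s = spec.theta * math.sqrt((1.0 - a**2) / (2.0 * spec.k))
    shocks = s * rng.standard_normal(n_steps)
    # m_i = a^i m0 + sum_{j<i} a^{i-1-j} shock_j  ==  IIR filter 1/(1 - a z^-1)
    driven = signal.lfilter([1.0], [1.0, -a], shocks)
    path = np.empty(n_steps + 1)
    path[0] = spec.m0
    powers = a ** np.arange(1, n_steps + 1)
    path[1:] = spec.m0 * powers + driven
    return path
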