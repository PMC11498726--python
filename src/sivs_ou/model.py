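"""Parameters, invariant region, reproduction numbers and equilibria.

The deterministic SIVS model tracks susceptible ``S``, infected ``I`` and
vaccinated ``V`` individuals.  A fraction ``g`` of the constant recruitment
``A`` is vaccinated at birth, susceptibles are vaccinated at rate ``p``,
vaccine immunity wanes at rate ``alpha`` (V -> S), recovery returns I to S at
rate ``gamma``, and ``eta``/``epsilon`` are the natural and disease-induced
mortality rates.  The stochastic variant replaces the transmission
coefficient ``beta`` by ``beta + m(t)`` where ``m`` is a zero-reverting
Ornstein-Uhlenbeck process with reversion speed ``k`` and volatility
``theta``.

This module holds everything that is available in closed form: parameter
validation, the positively invariant region Gamma, the deterministic
reproduction number R0, its stochastic extinction/persistence counterparts
R0E and R0S, and the disease-free and (quasi-)endemic equilibria.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "ModelParams",
    "SivsState",
    "Thresholds",
    "Equilibria",
    "NoEndemicEquilibrium",
    "PARAM_NAMES",
    "FIXTURES",
    "fixture",
    "validate_params",
    "in_invariant_region",
    "reproduction_number",
    "stochastic_thresholds",
    "disease_free_equilibrium",
    "endemic_equilibrium",
]

PARAM_NAMES = ("A", "g", "eta", "p", "beta", "gamma", "alpha", "epsilon", "k", "theta")


class NoEndemicEquilibrium(ValueError):
    """Raised when an operation requires R0 > 1 but the endemic state is absent."""


@dataclass(frozen=True)
class ModelParams:
    """The ten rate constants of the stochastic SIVS system.

    All rates are per unit time; ``A`` is individuals per unit time, ``g`` is
    the dimensionless newborn vaccination fraction, ``beta`` is per
    (individual x time), and ``theta`` has units of beta per square-root
    time.  Invariants: every field nonnegative, ``A, eta, k > 0`` and
    ``0 < g < 1``.
    """

    A: float
    g: float
    eta: float
    p: float
    beta: float
    gamma: float
    alpha: float
    epsilon: float
    k: float
    theta: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"parameter {name!r} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"parameter {name!r} must be nonnegative, got {value!r}")
        if self.A <= 0:
            raise ValueError(f"recruitment A must be positive, got {self.A!r}")
        if self.eta <= 0:
            raise ValueError(f"natural mortality eta must be positive, got {self.eta!r}")
        if not 0.0 < self.g < 1.0:
            raise ValueError(f"newborn vaccination fraction g must lie in (0, 1), got {self.g!r}")
        if self.k <= 0:
            raise ValueError(f"OU reversion speed k must be positive, got {self.k!r}")
        if self.epsilon >= self.p:
            warnings.warn(
                "disease-induced mortality epsilon >= vaccination rate p; the model "
                "is usually applied with lethality below the vaccination rate",
                UserWarning,
                stacklevel=2,
            )

    @property
    def carrying_total(self) -> float:
        """Upper bound A/eta on the total population inside Gamma."""
        return self.A / self.eta

    def replace(self, **updates: float) -> "ModelParams":
        vals = {name: getattr(self, name) for name in PARAM_NAMES}
        vals.update(updates)
        return ModelParams(**vals)


@dataclass(frozen=True)
class SivsState:
    """One point (S, I, V, m) of the state space Gamma x R."""

    S: float
    I: float
    V: float
    m: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.I, self.V, self.m], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "SivsState":
        S, I, V, m = (float(x) for x in arr)
        return cls(S=S, I=I, V=V, m=m)


@dataclass(frozen=True)
class Thresholds:
    """Deterministic and stochastic reproduction thresholds.

    ``R0E`` and ``R0S`` shift R0 up/down by the ergodic mean of A|m|/eta
    scaled by 1/(eta+gamma+epsilon); R0S <= R0 <= R0E always, with equality
    iff theta = 0.  ``extinction_rate_bound`` is the almost-sure exponential
    rate bound on ln I(t)/t when R0E < 1; ``persistence_lower_bound`` bounds
    the long-run time-average of I from below when R0S > 1 (None otherwise).
    """

    R0: float
    R0E: float
    R0S: float
    extinction_rate_bound: float
    persistence_lower_bound: float | None


@dataclass(frozen=True)
class Equilibria:
    """Disease-free and, when R0 > 1, quasi-endemic equilibrium components.

    The quasi-endemic equilibrium of the stochastic system has m* = 0 and
    coincides with the deterministic endemic equilibrium.
    """

    S0: float
    V0: float
    S_star: float | None = None
    I_star: float | None = None
    V_star: float | None = None
    m_star: float = 0.0

    @property
    def has_endemic(self) -> bool:
        return self.I_star is not None

    def endemic_state(self) -> SivsState:
        if not self.has_endemic:
            raise NoEndemicEquilibrium("R0 <= 1: no endemic equilibrium")
        return SivsState(S=self.S_star, I=self.I_star, V=self.V_star, m=self.m_star)


# Worked parameter sets; k and theta as used in the corresponding
# extinction (group1) and persistence (group2) experiments.
FIXTURES: dict[str, dict[str, float]] = {
    "group1": dict(A=0.05, g=0.6, eta=0.05, p=0.2, beta=0.5, gamma=0.2,
                   alpha=0.1, epsilon=0.1, k=0.65, theta=0.14),
    "group2": dict(A=0.5, g=0.8, eta=0.1, p=0.6, beta=0.9, gamma=0.3,
                   alpha=0.2, epsilon=0.15, k=0.7, theta=0.1),
}


def fixture(name: str, **overrides: float) -> ModelParams:
    """Return a built-in parameter set ('group1' or 'group2'), optionally overridden."""
    try:
        vals = dict(FIXTURES[name])
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
    vals.update(overrides)
    return ModelParams(**vals)


def validate_params(raw: Mapping[str, float]) -> ModelParams:
    """Validate a flat name->value mapping into :class:`ModelParams`.

    All ten parameter names must be present; unknown keys are rejected to
    catch typos in config files.
    """
    missing = [n for n in PARAM_NAMES if n not in raw]
    if missing:
        raise ValueError(f"missing parameter(s): {missing}")
    unknown = [n for n in raw if n not in PARAM_NAMES]
    if unknown:
        raise ValueError(f"unknown parameter(s): {unknown}")
    return ModelParams(**{n: float(raw[n]) for n in PARAM_NAMES})


def in_invariant_region(state: SivsState, params: ModelParams) -> bool:
    """True iff (S, I, V) lies in Gamma: all positive with S+I+V <= A/eta.

    Gamma is positively invariant: trajectories starting inside it stay
    inside almost surely.  The OU coordinate m is unrestricted.
    """
    return (
        state.S > 0
        and state.I > 0
        and state.V > 0
        and state.S + state.I + state.V <= params.carrying_total
    )


def reproduction_number(params: ModelParams) -> float:
    """Deterministic basic reproduction number R0.

    R0 = beta*A*[eta*(1-g)+alpha] / (eta*(eta+gamma+epsilon)*(eta+alpha+p)).
    """
    p = params
    num = p.beta * p.A * (p.eta * (1.0 - p.g) + p.alpha)
    den = p.eta * (p.eta + p.gamma + p.epsilon) * (p.eta + p.alpha + p.p)
    return num / den


def _ou_correction(params: ModelParams) -> float:
    # ergodic mean of A|m|/eta, scaled by 1/(eta+gamma+epsilon)
    p = params
    return p.A * p.theta / (math.sqrt(math.pi * p.k) * p.eta * (p.eta + p.gamma + p.epsilon))


def stochastic_thresholds(params: ModelParams) -> Thresholds:
    """Extinction/persistence thresholds R0E, R0S and the theorem bounds.

    R0E = R0 + A*theta/(sqrt(pi*k)*eta*(eta+gamma+epsilon)) and R0S is R0
    minus the same term.  When R0E < 1 the infection dies out exponentially
    with limsup ln I(t)/t <= (eta+gamma+epsilon)(R0E - 1) < 0; when R0S > 1
    the time-average of I is bounded below by
    eta*(eta+alpha+p)*(eta+gamma+epsilon)*(R0S-1) / (beta*(eta+epsilon)*(eta+alpha)).
    """
    p = params
    r0 = reproduction_number(p)
    corr = _ou_correction(p)
    r0e = r0 + corr
    r0s = r0 - corr
    rate = (p.eta + p.gamma + p.epsilon) * (r0e - 1.0)
    lower = (
        p.eta * (p.eta + p.alpha + p.p) * (p.eta + p.gamma + p.epsilon) * (r0s - 1.0)
        / (p.beta * (p.eta + p.epsilon) * (p.eta + p.alpha))
    )
    return Thresholds(
        R0=r0,
        R0E=r0e,
        R0S=r0s,
        extinction_rate_bound=rate,
        persistence_lower_bound=lower if lower > 0 else None,
    )


def disease_free_equilibrium(params: ModelParams) -> tuple[float, float]:
    """Disease-free equilibrium (S0, V0); I = 0 there and S0 + V0 = A/eta."""
    p = params
    den = p.eta * (p.eta + p.alpha + p.p)
    s0 = p.A * (p.eta * (1.0 - p.g) + p.alpha) / den
    v0 = p.A * (p.eta * p.g + p.p) / den
    return s0, v0


def endemic_equilibrium(params: ModelParams) -> Equilibria:
    """All equilibria; endemic components are present only when R0 > 1.

    S* = (eta+gamma+epsilon)/beta,
    I* = eta*(eta+gamma+epsilon)*(eta+alpha+p)*(R0-1) / (beta*(eta+epsilon)*(eta+alpha)),
    V* = (g*A*beta + p*(eta+gamma+epsilon)) / (beta*(eta+alpha)),
    and m* = 0.  R0 <= 1 yields a typed "no endemic equilibrium" result
    (``has_endemic`` False), not an exception, so regime classification can
    consume it.
    """
    p = params
    s0, v0 = disease_free_equilibrium(p)
    r0 = reproduction_number(p)
    if r0 <= 1.0:
        return Equilibria(S0=s0, V0=v0)
    s_star = (p.eta + p.gamma + p.epsilon) / p.beta
    i_star = (
        p.eta * (p.eta + p.gamma + p.epsilon) * (p.eta + p.alpha + p.p) * (r0 - 1.0)
        / (p.beta * (p.eta + p.epsilon) * (p.eta + p.alpha))
    )
    v_star = (p.g * p.A * p.beta + p.p * (p.eta + p.gamma + p.epsilon)) / (p.beta * (p.eta + p.alpha))
    return Equilibria(S0=s0, V0=v0, S_star=s_star, I_star=i_star, V_star=v_star)


def deterministic_rhs(state: SivsState, params: ModelParams) -> np.ndarray:
    """Right-hand side of the four-dimensional system at zero noise.

    Used for equilibrium-residual checks and deterministic integration.
    """
    p = params
    S, I, V, m = state.S, state.I, state.V, state.m
    beta_eff = p.beta + m
    dS = (1.0 - p.g) * p.A - beta_eff * S * I - (p.eta + p.p) * S + p.gamma * I + p.alpha * V
    dI = beta_eff * S * I - (p.eta + p.gamma + p.epsilon) * I
    dV = p.A * p.g + p.p * S - (p.eta + p.alpha) * V
    dm = -p.k * m
    return np.array([dS, dI, dV, dm])
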