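"""Regime classification and long-run diagnostics on simulated paths.

The thresholds give an almost-complete dichotomy: R0E < 1 implies
extinction with an exponential rate bound on ln I(t)/t, and R0S > 1 implies
persistence with a lower bound on the time-average of I.  Because
R0S <= R0E, a band of parameter sets satisfies neither condition; those are
reported as ``indeterminate`` — no unified stochastic threshold is known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import ModelParams, Thresholds, disease_free_equilibrium, stochastic_thresholds
from .simulate import Trajectory

__all__ = [
    "RegimeReport",
    "EnsembleSummary",
    "ExtinctionLimitReport",
    "classify_regime",
    "lyapunov_exponent_estimate",
    "time_average_I",
    "ensemble_summary",
    "limit_check_extinction",
]


@dataclass(frozen=True)
class RegimeReport:
    """Threshold-based regime: extinct (R0E < 1), persistent (R0S > 1), else indeterminate."""

    regime: str
    thresholds: Thresholds

    @property
    def R0E(self) -> float:
        return self.thresholds.R0E

    @property
    def R0S(self) -> float:
        return self.thresholds.R0S

    @property
    def rate_bound(self) -> float:
        """(eta+gamma+epsilon)(R0E - 1); negative exactly in the extinct regime."""
        return self.thresholds.extinction_rate_bound

    @property
    def avg_I_bound(self) -> float | None:
        """Persistence lower bound for the time-average of I; None unless positive."""
        return self.thresholds.persistence_lower_bound


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-time moments and stationary-window histograms of an ensemble.

    ``mean``/``sd`` have shape (n_times, 3) with columns S, I, V.
    Histograms pool all recorded states of all paths inside the stationary
    window; ``covariance`` is the empirical 4x4 covariance of (S, I, V, m)
    over the same pool.
    """

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    window: tuple[float, float]
    hist_edges: dict[str, np.ndarray]
    hist_counts: dict[str, np.ndarray]
    covariance: np.ndarray
    n_paths: int

    def mode(self, compartment: str) -> float:
        """Midpoint of the fullest stationary-window bin of S, I or V."""
        counts = self.hist_counts[compartment]
        edges = self.hist_edges[compartment]
        j = int(np.argmax(counts))
        return 0.5 * (edges[j] + edges[j + 1])


@dataclass(frozen=True)
class ExtinctionLimitReport:
    """Terminal S and V versus the disease-free equilibrium they converge to."""

    S_terminal: float
    V_terminal: float
    S0: float
    V0: float

    @property
    def S_abs_error(self) -> float:
        return abs(self.S_terminal - self.S0)

    @property
    def V_abs_error(self) -> float:
        return abs(self.V_terminal - self.V0)


def classify_regime(params: ModelParams) -> RegimeReport:
    """Classify by the stochastic thresholds; the two regimes are exclusive."""
    th = stochastic_thresholds(params)
    if th.R0E < 1.0:
        regime = "extinct"
    elif th.R0S > 1.0:
        regime = "persistent"
    else:
        regime = "indeterminate"
    return RegimeReport(regime=regime, thresholds=th)


def lyapunov_exponent_estimate(traj: Trajectory, window: tuple[float, float]) -> float:
    """Least-squares slope of ln I(t) versus t over the given time window.

    In the extinct regime this estimates the almost-sure exponential decay
    rate, to be compared with the bound (eta+gamma+epsilon)(R0E - 1).  If I
    hits zero inside the window (a clamped path) the fit stops at the last
    positive value and a warning is issued.
    """
    t0, t1 = window
    mask = (traj.times >= t0) & (traj.times <= t1)
    if not mask.any():
        raise ValueError(f"window {window!r} does not intersect the time grid")
    t = traj.times[mask]
    I = traj.I[mask]
    nonpos = I <= 0
    if nonpos.any():
        stop = int(np.argmax(nonpos))
        if stop < 2:
            raise ValueError("I is nonpositive at the start of the window; cannot fit ln I")
        warnings.warn(
            f"I(t) reaches zero inside the window; slope fitted on the first {stop} points",
            UserWarning,
            stacklevel=2,
        )
        t, I = t[:stop], I[:stop]
    slope, _ = np.polyfit(t, np.log(I), 1)
    return float(slope)


def time_average_I(traj: Trajectory, burn_in: float = 0.0) -> float:
    """Mean of I over grid points with t >= burn_in."""
    mask = traj.times >= burn_in
    if not mask.any():
        raise ValueError(f"burn_in {burn_in!r} leaves no grid points")
    return float(traj.I[mask].mean())


def ensemble_summary(
    ensemble: Sequence[Trajectory],
    stationary_window: tuple[float, float] | None = None,
    n_bins: int = 50,
) -> EnsembleSummary:
    """Per-time mean/SD and pooled stationary-window histograms and covariance.

    The default stationary window is the last half of the horizon.
    Histogram edges span the observed min-max per compartment.
    """
    times = ensemble[0].times
    states = np.stack([traj.states for traj in ensemble], axis=1)  # (n_times, n_paths, 4)
    if stationary_window is None:
        stationary_window = (0.5 * times[-1], times[-1])
    t0, t1 = stationary_window
    mask = (times >= t0) & (times <= t1)
    if not mask.any():
        raise ValueError(f"stationary window {stationary_window!r} disjoint from the time grid")

    mean = states[:, :, :3].mean(axis=1)
    sd = states[:, :, :3].std(axis=1)

    pool = states[mask].reshape(-1, 4)  # all recorded window states, all paths
    hist_edges: dict[str, np.ndarray] = {}
    hist_counts: dict[str, np.ndarray] = {}
    for j, name in enumerate(("S", "I", "V")):
        counts, edges = np.histogram(pool[:, j], bins=n_bins)
        hist_edges[name] = edges
        hist_counts[name] = counts
    covariance = np.cov(pool, rowvar=False)

    return EnsembleSummary(
        times=times,
        mean=mean,
        sd=sd,
        window=(float(t0), float(t1)),
        hist_edges=hist_edges,
        hist_counts=hist_counts,
        covariance=covariance,
        n_paths=len(ensemble),
    )


def limit_check_extinction(traj: Trajectory, params: ModelParams) -> ExtinctionLimitReport:
    """Compare terminal S and V with the disease-free equilibrium (S0, V0).

    Meaningful in the extinct regime, where S(t) -> S0 and V(t) -> V0
    almost surely.
    """
    s0, v0 = disease_free_equilibrium(params)
    final = traj.final_state
    return ExtinctionLimitReport(S_terminal=final.S, V_terminal=final.V, S0=s0, V0=v0)
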