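"""Stationary Gaussian law around the quasi-endemic equilibrium.

When R0S > 1 the stochastic SIVS system, linearized in the deviations
u = (S - S*, I - I*, V - V*, m), is the linear SDE du = A u dt + G dB with
G = diag(0, 0, 0, theta).  Its stationary law is N(0, Sigma) with Sigma the
solution of the continuous Lyapunov equation

    G^2 + A Sigma + Sigma A^T = 0.

Two routes to Sigma are provided:

* :func:`solve_lyapunov` — the direct solve (ground truth here);
* :func:`sigma_transform_chain` — the closed-form similarity-transformation
  chain J1, J2, J3, M1 that reduces A to companion form, where the
  standardized covariance Sigma1 is known explicitly in the characteristic
  coefficients c1..c4.

Two printed variants of the chain scalar ``a7`` circulate; they are
algebraically identical once an obvious transcription slip in one
denominator is repaired, and :func:`validate_chain` reports each variant's
entrywise discrepancy against the Lyapunov solve rather than silently
picking one.  The closed-form Sigma1 as usually printed also drops a factor
c4 from its (4,4) denominator; the corrected entry (c1 c2 - c3)/(2 c4 D) is
what the companion-form Lyapunov equation actually requires, and is used
here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .model import Equilibria, ModelParams, NoEndemicEquilibrium, endemic_equilibrium

__all__ = [
    "LinearSystem",
    "CharCoeffs",
    "CovarianceResult",
    "MarginalDensity",
    "linearize",
    "characteristic_coefficients",
    "solve_lyapunov",
    "sigma_transform_chain",
    "validate_chain",
    "marginal_densities",
    "density_at",
]

A7_VARIANTS = ("theorem", "proof")


@dataclass(frozen=True)
class LinearSystem:
    """Coefficients and matrices of the linearized system around (S*, I*, V*, 0).

    a11 = beta I* + eta + p, a12 = beta S* - gamma = eta + epsilon,
    a13 = alpha, a14 = S* I*, a21 = beta I*, a31 = p, a33 = eta + alpha,
    a44 = k.  ``A_matrix`` carries the drift sign pattern

        du1 = (-a11 u1 - a12 u2 + a13 u3 - a14 u4) dt
        du2 = ( a21 u1 + a14 u4) dt
        du3 = ( a31 u1 - a33 u3) dt
        du4 = ( -a44 u4) dt + theta dB
    """

    a11: float
    a12: float
    a13: float
    a14: float
    a21: float
    a31: float
    a33: float
    a44: float
    theta: float
    A_matrix: np.ndarray
    G_matrix: np.ndarray
    equilibria: Equilibria


@dataclass(frozen=True)
class CharCoeffs:
    """Characteristic-polynomial coefficients and the Hurwitz verdict.

    phi_A(lambda) = (lambda + a44)(lambda^3 + b1 lambda^2 + b2 lambda + b3);
    the quartic expansion has coefficients c1..c4.  ``hurwitz`` holds the
    Routh-Hurwitz sign conditions b1, b2, b3 > 0, b1 b2 - b3 > 0, a44 > 0,
    cross-checked elsewhere against a numeric eigendecomposition.
    """

    b1: float
    b2: float
    b3: float
    c1: float
    c2: float
    c3: float
    c4: float
    hurwitz: bool


@dataclass(frozen=True)
class CovarianceResult:
    """Stationary covariance with provenance (``method``: lyapunov or chain)."""

    Sigma: np.ndarray
    method: str
    equilibria: Equilibria
    Sigma1: np.ndarray | None = None
    J1: np.ndarray | None = None
    J2: np.ndarray | None = None
    J3: np.ndarray | None = None
    M1: np.ndarray | None = None
    chain_scalars: dict | None = None


@dataclass(frozen=True)
class MarginalDensity:
    """One-dimensional Gaussian marginal N(mean, variance) of a compartment."""

    mean: float
    variance: float

    @property
    def prefactor(self) -> float:
        return 1.0 / math.sqrt(2.0 * math.pi * self.variance)

    @property
    def exp_coeff(self) -> float:
        return 1.0 / (2.0 * self.variance)

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = self.prefactor * np.exp(-self.exp_coeff * (x - self.mean) ** 2)
        return out if out.ndim else float(out)


def linearize(params: ModelParams) -> LinearSystem:
    """Linearize the stochastic system around the quasi-endemic equilibrium.

    Requires R0 > 1; raises :class:`NoEndemicEquilibrium` otherwise.
    """
    eq = endemic_equilibrium(params)
    if not eq.has_endemic:
        raise NoEndemicEquilibrium("R0 <= 1: no quasi-endemic equilibrium to linearize around")
    p = params
    a11 = p.beta * eq.I_star + p.eta + p.p
    a12 = p.eta + p.epsilon  # equals beta S* - gamma at the equilibrium
    a13 = p.alpha
    a14 = eq.S_star * eq.I_star
    a21 = p.beta * eq.I_star
    a31 = p.p
    a33 = p.eta + p.alpha
    a44 = p.k
    A = np.array(
        [
            [-a11, -a12, a13, -a14],
            [a21, 0.0, 0.0, a14],
            [a31, 0.0, -a33, 0.0],
            [0.0, 0.0, 0.0, -a44],
        ]
    )
    G = np.diag([0.0, 0.0, 0.0, p.theta])
    return LinearSystem(
        a11=a11, a12=a12, a13=a13, a14=a14, a21=a21, a31=a31, a33=a33, a44=a44,
        theta=p.theta, A_matrix=A, G_matrix=G, equilibria=eq,
    )


def characteristic_coefficients(lin: LinearSystem) -> CharCoeffs:
    """Cubic (b) and quartic (c) characteristic coefficients plus Hurwitz flag."""
    b1 = lin.a11 + lin.a33
    b2 = lin.a12 * lin.a21 + lin.a11 * lin.a33 - lin.a13 * lin.a31
    b3 = lin.a12 * lin.a21 * lin.a33
    c1 = b1 + lin.a44
    c2 = b2 + lin.a44 * b1
    c3 = b3 + lin.a44 * b2
    c4 = lin.a44 * b3
    hurwitz = b1 > 0 and b2 > 0 and b3 > 0 and (b1 * b2 - b3) > 0 and lin.a44 > 0
    return CharCoeffs(b1=b1, b2=b2, b3=b3, c1=c1, c2=c2, c3=c3, c4=c4, hurwitz=hurwitz)


def solve_lyapunov(lin: LinearSystem) -> CovarianceResult:
    """Solve G^2 + A Sigma + Sigma A^T = 0 directly; the reference route.

    The solution is symmetrized to remove round-off asymmetry.  Raises if
    the drift matrix is not Hurwitz (no positive-semidefinite stationary
    covariance exists then).
    """
    if not characteristic_coefficients(lin).hurwitz:
        raise ValueError("drift matrix is not Hurwitz: no stationary covariance")
    G2 = lin.G_matrix @ lin.G_matrix
    Sigma = linalg.solve_continuous_lyapunov(lin.A_matrix, -G2)
    Sigma = 0.5 * (Sigma + Sigma.T)
    return CovarianceResult(Sigma=Sigma, method="lyapunov", equilibria=lin.equilibria)


def _chain_scalars(lin: LinearSystem, a7_variant: str) -> dict:
    if a7_variant not in A7_VARIANTS:
        raise ValueError(f"a7_variant must be one of {A7_VARIANTS}, got {a7_variant!r}")
    d = lin.a12 + lin.a21 - lin.a11
    if d == 0:
        raise ZeroDivisionError("degenerate chain: a12 + a21 - a11 = 0")
    a1 = -lin.a44
    a2 = -lin.a14
    a3 = -lin.a11 + lin.a12
    a4 = -lin.a11 + lin.a12 + lin.a21
    a5 = -lin.a12 + lin.a13 * lin.a31 / d
    a6 = lin.a13
    a8 = -lin.a13 * lin.a31 / d - lin.a33
    if a7_variant == "theorem":
        # printed as (a12+a8)a31/(a12+a1-a11); the a1 is a transcription
        # slip for a21 (with a1 = -a44 the chain provably fails)
        a7 = (lin.a12 + a8) * lin.a31 / d
    else:
        a7 = (lin.a12 - lin.a33) * lin.a31 / d - lin.a13 * lin.a31**2 / d**2
    if a7 == 0:
        raise ZeroDivisionError("degenerate chain: a7 = 0")
    m1 = a2 * a4 * a7
    m2 = a4 * a7 * (a3 + a5 + a8)
    m3 = a5 * a7 * (a4 + a5 + a8) + a7 * (a6 * a7 + a8**2)
    m4 = a6 * a7 * (a4 + a5 + a8) + a8 * (a6 * a7 + a8**2)
    if m1 == 0:
        raise ZeroDivisionError("degenerate chain: m1 = 0")
    return dict(a1=a1, a2=a2, a3=a3, a4=a4, a5=a5, a6=a6, a7=a7, a8=a8,
                m1=m1, m2=m2, m3=m3, m4=m4)


def sigma_transform_chain(lin: LinearSystem, a7_variant: str = "proof") -> CovarianceResult:
    """Closed-form Sigma via the similarity-transformation chain.

    Sigma = (m1 theta)^2 (M1 J3 J2 J1)^{-1} Sigma1 [(M1 J3 J2 J1)^{-1}]^T,
    where M1 J3 J2 J1 takes the drift to the companion matrix B with top
    row (-c1, -c2, -c3, -c4) and Sigma1 is the standardized companion-form
    stationary covariance.  The (4,4) entry of Sigma1 uses the corrected
    denominator 2 c4 (c1 c2 c3 - c3^2 - c1^2 c4).
    """
    coeffs = characteristic_coefficients(lin)
    if not coeffs.hurwitz:
        raise ValueError("drift matrix is not Hurwitz: no stationary covariance")
    sc = _chain_scalars(lin, a7_variant)
    a4s, a5, a6, a7, a8 = sc["a4"], sc["a5"], sc["a6"], sc["a7"], sc["a8"]
    m1, m2, m3, m4 = sc["m1"], sc["m2"], sc["m3"], sc["m4"]

    J1 = np.array([[0, 0, 0, 1], [1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]], dtype=float)
    J2 = np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 1, 1, 0], [0, 0, 0, 1]], dtype=float)
    J3 = np.eye(4)
    J3[3, 2] = -lin.a31 / (lin.a12 + lin.a21 - lin.a11)
    M1 = np.array(
        [
            [m1, m2, m3, m4],
            [0.0, a4s * a7, a7 * (a5 + a8), a6 * a7 + a8**2],
            [0.0, 0.0, a7, a8],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )

    c1, c2, c3, c4 = coeffs.c1, coeffs.c2, coeffs.c3, coeffs.c4
    D = c1 * c2 * c3 - c3**2 - c1**2 * c4
    if D <= 0:
        raise ValueError("companion determinant condition c1 c2 c3 - c3^2 - c1^2 c4 <= 0")
    den = 2.0 * D
    Sigma1 = np.array(
        [
            [(c2 * c3 - c1 * c4) / den, 0.0, -c3 / den, 0.0],
            [0.0, c3 / den, 0.0, -c1 / den],
            [-c3 / den, 0.0, c1 / den, 0.0],
            [0.0, -c1 / den, 0.0, (c1 * c2 - c3) / (2.0 * c4 * D)],
        ]
    )

    T = M1 @ J3 @ J2 @ J1
    T_inv = np.linalg.inv(T)
    Sigma = (m1 * lin.theta) ** 2 * T_inv @ Sigma1 @ T_inv.T
    Sigma = 0.5 * (Sigma + Sigma.T)
    return CovarianceResult(
        Sigma=Sigma, method="chain", equilibria=lin.equilibria,
        Sigma1=Sigma1, J1=J1, J2=J2, J3=J3, M1=M1, chain_scalars=sc,
    )


def companion_matrix(lin: LinearSystem, a7_variant: str = "proof") -> np.ndarray:
    """B = M1 A3 M1^{-1}: the companion form reached by the chain (for checks)."""
    res = sigma_transform_chain(lin, a7_variant)
    T = res.M1 @ res.J3 @ res.J2 @ res.J1
    return T @ lin.A_matrix @ np.linalg.inv(T)


def validate_chain(lin: LinearSystem, atol: float = 1e-8) -> dict[str, float]:
    """Max entrywise |chain Sigma - Lyapunov Sigma| for every a7 variant.

    Reports both printed variants against the direct solve so the caller can
    see which (if either) reproduces the reference covariance.
    """
    ref = solve_lyapunov(lin).Sigma
    out = {}
    for variant in A7_VARIANTS:
        try:
            out[variant] = float(np.abs(sigma_transform_chain(lin, variant).Sigma - ref).max())
        except (ZeroDivisionError, ValueError):
            out[variant] = float("inf")
    return out


def marginal_densities(
    cov: CovarianceResult, eq: Equilibria | None = None
) -> tuple[MarginalDensity, MarginalDensity, MarginalDensity]:
    """Gaussian marginals of S, I and V: N(equilibrium component, Sigma[i, i])."""
    eq = eq if eq is not None else cov.equilibria
    if not eq.has_endemic:
        raise NoEndemicEquilibrium("marginal densities require the endemic equilibrium")
    means = (eq.S_star, eq.I_star, eq.V_star)
    out = []
    for i, mean in enumerate(means):
        var = float(cov.Sigma[i, i])
        if var <= 0:
            raise ValueError(f"nonpositive marginal variance Sigma[{i},{i}] = {var!r}")
        out.append(MarginalDensity(mean=mean, variance=var))
    return tuple(out)


def is_positive_definite(Sigma: np.ndarray, tol: float = 1e-12) -> bool:
    """Positive definiteness via attempted Cholesky factorization."""
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return False
    return bool(np.min(np.diag(L)) ** 2 > tol * np.max(np.diag(L)) ** 2)


def density_at(u, cov: CovarianceResult) -> float:
    """Stationary Gaussian density at the deviation vector u = (u1, u2, u3, u4).

    Phi(u) = (2 pi)^{-2} |Sigma|^{-1/2} exp(-u Sigma^{-1} u^T / 2).
    """
    Sigma = cov.Sigma
    if not is_positive_definite(Sigma):
        raise ValueError("Sigma is singular or not positive definite")
    return float(stats.multivariate_normal(mean=np.zeros(4), cov=Sigma).pdf(np.asarray(u, dtype=float)))
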