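"""Closed-form results of the stochastic damage/repair/division model.

A source of DNA damage creates lesions in bursts (frequency ``f``, mean burst
size ``b``), and a finite pool of ``N`` repair agents detects lesions at rate
``r1`` per lesion per free agent and completes repair at rate ``r2``.  Each
completed repair leaves a mismatch with probability ``eps``.  At cell division
(rate ``phi``), every unrepaired lesion is bypassed by translesion synthesis
(TLS), which errs at the lesion with probability ``1 - p_tls`` and makes a
collateral error nearby with probability ``eps_prime`` (removed by mismatch
repair with probability ``q_mmr``).

Two regimes arise.  When repair capacity exceeds the mean damage rate
(``N*r2 > f*b``, *efficient* repair) the lesion count reaches a stationary
distribution — a two-component gamma mixture — and mutations accrue linearly
in time from both unrepaired damage and repair errors.  When damage overwhelms
repair (``N*r2 < f*b``) lesions grow linearly and unrepaired damage dominates
the mutational output.

This module exposes the analytic results: the effective repair rate, the
stationary lesion distribution, expected lesion and mismatch counts, the
per-time mutation rates of both channels, and a phase diagram of signature
detectability in the (cumulative damage, division rate) plane.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ModelParams",
    "RegimeRates",
    "PhaseDiagramSpec",
    "NoSteadyStateError",
    "effective_repair_rate",
    "steady_state_density",
    "steady_state_components",
    "expected_lesions",
    "expected_repair_errors",
    "tls_bracket",
    "mutation_rates",
    "phase_diagram",
    "PHASE_LABELS",
]


class NoSteadyStateError(ValueError):
    """Raised when a steady-state quantity is requested in the overwhelmed regime."""


@dataclass(frozen=True)
class ModelParams:
    """Kinetic parameters of the damage/repair/division model.

    Parameters
    ----------
    f : float
        Frequency of damage bursts (events per unit time).
    b : float
        Mean burst size (lesions per burst, > 0).
    r1 : float
        Lesion detection rate (per lesion per free agent per unit time).
    r2 : float
        Repair-completion rate (per engaged agent per unit time).
    N : int
        Number of repair agents.
    eps : float
        Probability that a completed repair leaves a mismatch (repair error).
    eps_prime : float
        Probability of a collateral TLS error near a bypassed lesion.
    p_tls : float
        Probability that TLS inserts the correct base across the lesion.
    q_mmr : float
        Probability that a collateral TLS error is removed by mismatch repair.
    phi : float
        Cell-division rate (per unit time); replication is instantaneous and
        simultaneous with division.
    """

    f: float = 1.0
    b: float = 5.0
    r1: float = 0.01
    r2: float = 10.0
    N: int = 10
    eps: float = 0.0
    eps_prime: float = 0.0
    p_tls: float = 1.0
    q_mmr: float = 0.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        if self.f < 0 or self.r1 <= 0 or self.r2 <= 0 or self.phi < 0:
            raise ValueError("rates must be nonnegative (r1, r2 strictly positive)")
        if self.b <= 0:
            raise ValueError("mean burst size b must be positive")
        if self.N < 1 or int(self.N) != self.N:
            raise ValueError("N must be a positive integer")
        for name in ("eps", "eps_prime", "p_tls", "q_mmr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.r2 < 10.0 * self.r1:
            warnings.warn(
                "r2 < 10*r1: the quasi-steady-state approximation assumes "
                "r2 >> r1 and may degrade",
                stacklevel=2,
            )

    def mean_damage_rate(self) -> float:
        """Mean damage rate u-bar = f*b (lesions per unit time)."""
        return self.f * self.b

    @property
    def regime(self) -> Literal["efficient", "overwhelmed"]:
        """'efficient' iff repair capacity N*r2 exceeds the mean damage rate."""
        return "efficient" if self.N * self.r2 > self.f * self.b else "overwhelmed"


@dataclass(frozen=True)
class RegimeRates:
    """Per-unit-time mutation rates of the two channels, by regime."""

    n_unrepaired_per_time: float
    n_errors_per_time: float
    regime: Literal["efficient", "overwhelmed"]


def effective_repair_rate(x: float, params: ModelParams) -> float:
    """Quasi-steady-state repair flux r(x) = N / (1/(r1*x) + 1/r2).

    The harmonic-mean structure interpolates between detection-limited
    (``N*r1*x`` at low lesion load) and capacity-limited (``N*r2`` at
    saturation) repair.  Returns 0 at ``x = 0``.
    """
    if x < 0:
        raise ValueError("lesion count x must be nonnegative")
    if x == 0:
        return 0.0
    return params.N / (1.0 / (params.r1 * x) + 1.0 / params.r2)


def _mixture_parts(params: ModelParams):
    """Shape/rate and component weights of the stationary gamma mixture.

    The stationary density p(x) ∝ (1/(r1 x) + 1/r2) x^α e^{−λx} with
    α = f/(N r1), λ = (N r2 − f b)/(N r2 b) is exactly
    w·Gamma(α, λ) + (1−w)·Gamma(α+1, λ); the normalization is analytic.
    """
    f, b, r1, r2, N = params.f, params.b, params.r1, params.r2, params.N
    if N * r2 <= f * b:
        raise NoSteadyStateError(
            "no steady state: the damage rate surpasses the repair capacity "
            f"(N*r2 = {N * r2} <= f*b = {f * b})"
        )
    alpha = f / (N * r1)
    lam = (N * r2 - f * b) / (N * r2 * b)
    # component normalizers: Z1 = Γ(α)/(r1 λ^α), Z2 = Γ(α+1)/(r2 λ^(α+1))
    logZ1 = gammaln(alpha) - math.log(r1) - alpha * math.log(lam)
    logZ2 = gammaln(alpha + 1.0) - math.log(r2) - (alpha + 1.0) * math.log(lam)
    m = max(logZ1, logZ2)
    w1 = math.exp(logZ1 - m)
    w2 = math.exp(logZ2 - m)
    w = w1 / (w1 + w2)
    return alpha, lam, w


def steady_state_components(params: ModelParams):
    """(alpha, lam, weight) of the stationary mixture w·Γ(α,λ) + (1−w)·Γ(α+1,λ)."""
    return _mixture_parts(params)


def steady_state_density(x, params: ModelParams):
    """Stationary probability density of the unrepaired-lesion load.

    Valid only in the efficient regime; normalized analytically via the
    gamma-mixture representation.  Accepts scalars or arrays.
    """
    alpha, lam, w = _mixture_parts(params)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("lesion load must be nonnegative")
    out = w * stats.gamma.pdf(x, a=alpha, scale=1.0 / lam) + (1.0 - w) * stats.gamma.pdf(
        x, a=alpha + 1.0, scale=1.0 / lam
    )
    return out if out.ndim else float(out)


def steady_state_cdf(x, params: ModelParams):
    """Stationary CDF of the lesion load (efficient regime)."""
    alpha, lam, w = _mixture_parts(params)
    x = np.asarray(x, dtype=float)
    out = w * stats.gamma.cdf(x, a=alpha, scale=1.0 / lam) + (1.0 - w) * stats.gamma.cdf(
        x, a=alpha + 1.0, scale=1.0 / lam
    )
    return out if out.ndim else float(out)


def expected_lesions(params: ModelParams) -> float:
    """Stationary mean lesion count <x> = (r2/r1 + b) * f*b / (N*r2 - f*b).

    In the limit of ample capacity (N*r2 >> f*b) with b << r2/r1 this reduces
    to u-bar/(N*r1), the detection-limited result.
    """
    f, b, r1, r2, N = params.f, params.b, params.r1, params.r2, params.N
    if f == 0:
        return 0.0
    if N * r2 <= f * b:
        raise NoSteadyStateError(
            "no steady state: the damage rate surpasses the repair capacity"
        )
    return (r2 / r1 + b) * (f * b) / (N * r2 - f * b)


def expected_repair_errors(params: ModelParams, t: float) -> float:
    """Expected cumulative mismatches <y(t)> = eps * f * b * t.

    At long times nearly all damage has passed through repair, so mismatch
    accumulation is a compound Poisson process tracking cumulative damage.
    """
    if t < 0:
        raise ValueError("time t must be nonnegative")
    if params.regime != "efficient":
        raise NoSteadyStateError("expected_repair_errors assumes the efficient regime")
    return params.eps * params.f * params.b * t


def tls_bracket(params: ModelParams) -> float:
    """Expected mutations per unrepaired lesion per division.

    K = [(1-p) + eps'*p*(1-q) + eps'*(1-p)*(1-q)] / 2: lesion-site TLS error,
    collateral error after error-free TLS, and collateral error alongside a
    lesion-site error (a two-mutation cluster); each resolved mismatch is fixed
    in the followed daughter lineage with probability 1/2.
    """
    p, e2, q = params.p_tls, params.eps_prime, params.q_mmr
    return ((1.0 - p) + e2 * p * (1.0 - q) + e2 * (1.0 - p) * (1.0 - q)) / 2.0


def mutation_rates(params: ModelParams) -> RegimeRates:
    """Per-unit-time mutation rates from unrepaired damage and repair errors.

    Efficient regime: unrepaired-damage mutations accrue at <x>*phi*K and
    repair-error mutations at eps*f*b/2 (independent of phi and of repair
    rates).  Overwhelmed regime: lesions accumulate at f*b - N*r2, so
    unrepaired-damage mutations accrue at (f*b - N*r2)*K regardless of phi,
    while repair errors are capped by capacity at eps*N*r2/2.
    """
    K = tls_bracket(params)
    f, b, r2, N = params.f, params.b, params.r2, params.N
    if params.regime == "efficient":
        n_unrep = expected_lesions(params) * params.phi * K
        n_err = params.eps * f * b / 2.0
    else:
        n_unrep = (f * b - N * r2) * K
        n_err = params.eps * N * r2 / 2.0
    return RegimeRates(n_unrep, n_err, params.regime)


PHASE_LABELS = ("none", "unrepaired", "errors", "both")


@dataclass
class PhaseDiagramSpec:
    """Grid specification for the signature-detectability phase diagram.

    ``damage_grid`` is cumulative damage f*b*t (x-axis); ``phi_grid`` is the
    cell-division rate (y-axis); a signature is called detectable when its
    expected mutation count exceeds ``n_star``.
    """

    n_star: float
    damage_grid: np.ndarray = field(default_factory=lambda: np.geomspace(1.0, 1e6, 60))
    phi_grid: np.ndarray = field(default_factory=lambda: np.geomspace(1e-4, 1.0, 50))

    def __post_init__(self) -> None:
        self.damage_grid = np.asarray(self.damage_grid, dtype=float)
        self.phi_grid = np.asarray(self.phi_grid, dtype=float)
        if self.n_star <= 0:
            raise ValueError("n_star must be positive")
        if np.any(self.damage_grid <= 0) or np.any(self.phi_grid <= 0):
            raise ValueError("grid axes must be strictly positive")


def phase_diagram(spec: PhaseDiagramSpec, params: ModelParams):
    """Label each (cumulative damage, phi) cell by which signatures are detectable.

    The cumulative-damage axis is f*b*t at the fixed f*b of ``params``, so each
    column corresponds to exposure time t = damage/(f*b).  Expected mutation
    counts at time t follow the regime-appropriate rates; the repair-error
    boundary n_errors = n_star is a vertical line (independent of phi).

    Returns an integer array of shape (len(phi_grid), len(damage_grid)) with
    values indexing ``PHASE_LABELS``: 0 none, 1 unrepaired only, 2 errors only,
    3 both.
    """
    fb = params.mean_damage_rate()
    if fb <= 0:
        raise ValueError("phase diagram requires f*b > 0")
    t = spec.damage_grid / fb
    labels = np.zeros((spec.phi_grid.size, spec.damage_grid.size), dtype=int)
    for i, phi in enumerate(spec.phi_grid):
        p = ModelParams(
            f=params.f, b=params.b, r1=params.r1, r2=params.r2, N=params.N,
            eps=params.eps, eps_prime=params.eps_prime, p_tls=params.p_tls,
            q_mmr=params.q_mmr, phi=float(phi),
        )
        rates = mutation_rates(p)
        unrep = rates.n_unrepaired_per_time * t >= spec.n_star
        err = rates.n_errors_per_time * t >= spec.n_star
        labels[i] = unrep.astype(int) + 2 * err.astype(int)
    return labels
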