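"""Exact stochastic simulation of the damage/repair/division kinetics.

Two modes are provided.  ``full`` simulates the complete agent-based kinetics
with the standard Gillespie algorithm: damage bursts arrive at rate ``f`` and
add a geometric number of lesions (mean ``b``); free agents engage lesions at
rate ``r1*x*z``; engaged agents complete repair at rate ``r2*(N-z)``, each
completion leaving a mismatch with probability ``eps``; divisions occur at
rate ``phi``.  ``qss`` simulates the reduced quasi-steady-state dynamics in
which the lesion load is a continuous jump process — exponential bursts at
rate ``f`` with deterministic decay at the effective repair rate
``r(x) = N/(1/(r1 x) + 1/r2)`` between jumps — mirroring the regime in which
the analytic results hold.

At each division every undetected lesion independently produces translesion
synthesis (TLS) outcomes: a lesion-site mutation with probability ``1-p_tls``
and a collateral mismatch with probability ``eps_prime`` that survives
mismatch repair with probability ``1-q_mmr``; every surviving mismatch is
fixed in the followed daughter lineage with probability 1/2.  Accumulated
repair-error mismatches are likewise resolved (fixed w.p. 1/2) and reset.
Lesions persist across divisions (they are bypassed, not removed).  Events in
which both the lesion-site and a collateral mutation fix produce a
two-mutation cluster and increment ``n_cluster_events``.

The simulator serves as the independent oracle for the closed-form results in
:mod:`funnelsig.model_core`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import lambertw

from .model_core import ModelParams

__all__ = ["Trajectory", "simulate", "replicate_summary", "summarize_replicates"]

_CHUNK = 16384


@dataclass
class Trajectory:
    """Recorded state of one simulated lineage.

    ``times``/``x``/``y``/``z`` are the sampled trajectory (``z`` is NaN in
    qss mode, which does not resolve individual agents).  ``y`` counts
    cumulative mismatches ever created (nondecreasing); the mutation counters
    count fixed mutations from unrepaired damage (``n_unrepaired``, including
    collateral TLS errors), from repair errors (``n_errors``), and two-mutation
    TLS cluster events (``n_cluster_events``).  ``time_avg_x`` is the exact
    time average of x over [t_burn, t_max].
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    division_times: np.ndarray
    n_unrepaired: int
    n_errors: int
    n_cluster_events: int
    final_x: float
    final_y: float
    final_z: float
    time_avg_x: float
    t_max: float
    t_burn: float
    mode: str
    seed: int
    #: counter/mismatch values at t_burn, for windowed rates free of the
    #: relaxation transient: (n_unrepaired, n_errors, n_cluster_events, y)
    burn_counters: tuple = (0, 0, 0, 0.0)

    def windowed_rates(self) -> dict:
        """Per-time mutation/mismatch rates over [t_burn, t_max]."""
        dt = self.t_max - self.t_burn
        b = self.burn_counters
        return dict(
            n_unrepaired=(self.n_unrepaired - b[0]) / dt,
            n_errors=(self.n_errors - b[1]) / dt,
            n_cluster_events=(self.n_cluster_events - b[2]) / dt,
            y=(self.final_y - b[3]) / dt,
        )


class _Uniforms:
    """Sequential buffered uniform(0,1) draws from a numpy Generator."""

    __slots__ = ("rng", "buf", "i")

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.buf = rng.random(_CHUNK)
        self.i = 0

    def next(self) -> float:
        i = self.i
        if i >= _CHUNK:
            self.buf = self.rng.random(_CHUNK)
            i = 0
        self.i = i + 1
        return self.buf[i]


def _division_outcomes(k: int, params: ModelParams, rng: np.random.Generator):
    """TLS bookkeeping for k lesions at one division.

    Returns (n_fixed_mutations, n_cluster_events).
    """
    if k <= 0:
        return 0, 0
    u = rng.random((4, k))
    lesion_err = u[0] < (1.0 - params.p_tls)
    collateral = u[1] < params.eps_prime * (1.0 - params.q_mmr)
    fix_a = lesion_err & (u[2] < 0.5)
    fix_c = collateral & (u[3] < 0.5)
    return int(fix_a.sum() + fix_c.sum()), int((fix_a & fix_c).sum())


def simulate(
    params: ModelParams,
    t_max: float,
    mode: Literal["full", "qss"] = "full",
    seed: int = 0,
    sample_dt: float | None = None,
    t_burn: float = 0.0,
) -> Trajectory:
    """Simulate one lineage for ``t_max`` time units.

    ``sample_dt=None`` records the state at every event (suitable for short
    runs); a positive ``sample_dt`` records on a regular grid; ``math.inf``
    records nothing but still returns terminal state, counters and the exact
    time average of x over ``[t_burn, t_max]``.  Identical seeds give
    identical trajectories.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if mode not in ("full", "qss"):
        raise ValueError(f"unknown mode {mode!r}")
    if t_burn < 0 or t_burn >= t_max:
        t_burn = max(0.0, min(t_burn, t_max))
    rng = np.random.default_rng(seed)
    if mode == "full":
        return _simulate_full(params, t_max, rng, sample_dt, t_burn, seed)
    return _simulate_qss(params, t_max, rng, sample_dt, t_burn, seed)


def _simulate_full(params, t_max, rng, sample_dt, t_burn, seed):
    f, b, r1, r2, N = params.f, params.b, params.r1, params.r2, params.N
    eps, phi = params.eps, params.phi
    p_geo = 1.0 / b if b > 1.0 else 1.0
    t = 0.0
    x = 0  # undetected lesions
    z = N  # free agents
    y_cum = 0.0
    y_pending = 0  # repair-error mismatches awaiting the next division
    n_unrep = n_err = n_clust = 0
    divisions: list[float] = []
    record_events = sample_dt is None
    times: list[float] = []
    xs: list[float] = []
    ys: list[float] = []
    zs: list[float] = []
    next_sample = 0.0 if (sample_dt is not None and math.isfinite(sample_dt)) else math.inf
    int_x = 0.0  # integral of x over [t_burn, t_max]
    burn = None if t_burn > 0 else (0, 0, 0, 0.0)
    U = _Uniforms(rng)
    log = math.log
    if record_events:
        times.append(0.0); xs.append(0.0); ys.append(0.0); zs.append(float(N))
    while True:
        a1 = f
        a2 = r1 * x * z
        a3 = r2 * (N - z)
        a4 = phi
        atot = a1 + a2 + a3 + a4
        if atot <= 0.0:
            dt = t_max - t
        else:
            u = U.next()
            if u <= 0.0:
                u = 1e-300
            dt = -log(u) / atot
        t_new = t + dt
        if t_new >= t_max:
            seg0 = max(t, t_burn)
            if t_max > seg0:
                int_x += x * (t_max - seg0)
            while next_sample <= t_max:
                times.append(next_sample); xs.append(float(x)); ys.append(y_cum); zs.append(float(z))
                next_sample += sample_dt
            t = t_max
            break
        seg0 = max(t, t_burn)
        if t_new > seg0:
            int_x += x * (t_new - seg0)
        while next_sample < t_new:
            times.append(next_sample); xs.append(float(x)); ys.append(y_cum); zs.append(float(z))
            next_sample += sample_dt
        t = t_new
        if burn is None and t > t_burn:
            burn = (n_unrep, n_err, n_clust, y_cum)
        r = U.next() * atot
        if r < a1:  # damage burst
            x += int(rng.geometric(p_geo))
        elif r < a1 + a2:  # agent engages a lesion
            x -= 1
            z -= 1
        elif r < a1 + a2 + a3:  # repair completes
            z += 1
            if eps > 0.0 and U.next() < eps:
                y_cum += 1.0
                y_pending += 1
        else:  # division
            divisions.append(t)
            dm, dc = _division_outcomes(x, params, rng)
            n_unrep += dm
            n_clust += dc
            if y_pending:
                n_err += int(rng.binomial(y_pending, 0.5))
                y_pending = 0
        if record_events:
            times.append(t); xs.append(float(x)); ys.append(y_cum); zs.append(float(z))
    denom = t_max - t_burn
    return Trajectory(
        np.asarray(times), np.asarray(xs), np.asarray(ys), np.asarray(zs),
        np.asarray(divisions), n_unrep, n_err, n_clust,
        float(x), y_cum, float(z), int_x / denom if denom > 0 else float("nan"),
        t_max, t_burn, "full", seed,
        burn if burn is not None else (n_unrep, n_err, n_clust, y_cum),
    )


def _decay(x0: float, tau: float, a: float, c: float) -> float:
    """Lesion load after deterministic decay for time tau.

    Solves g(x1) = g(x0) - tau with g(x) = a*x + c*ln(x), a = 1/(N*r2),
    c = 1/(N*r1); g is strictly increasing so the root is unique:
    x1 = (c/a) * W0((a/c) * exp(R/c)) with R = g(x0) - tau.
    """
    if x0 <= 0.0:
        return 0.0
    R = a * x0 + c * math.log(x0) - tau
    u = math.log(a / c) + R / c
    if u < -700.0:
        return 0.0
    if u < 700.0:
        return (c / a) * float(lambertw(math.exp(u)).real)
    # asymptotic W0(e^u) ~ u - ln(u), refined by Newton on g
    x1 = (c / a) * (u - math.log(u))
    for _ in range(3):
        g = a * x1 + c * math.log(x1) - R
        x1 -= g / (a + c / x1)
    return x1


def _simulate_qss(params, t_max, rng, sample_dt, t_burn, seed):
    f, b, r1, r2, N = params.f, params.b, params.r1, params.r2, params.N
    eps, phi = params.eps, params.phi
    a = 1.0 / (N * r2)
    c = 1.0 / (N * r1)
    t = 0.0
    x = 0.0
    y_cum = 0.0
    y_pending = 0.0
    n_unrep = n_err = n_clust = 0
    divisions: list[float] = []
    record_events = sample_dt is None
    times: list[float] = []
    xs: list[float] = []
    ys: list[float] = []
    next_sample = 0.0 if (sample_dt is not None and math.isfinite(sample_dt)) else math.inf
    int_x = 0.0
    burn = None if t_burn > 0 else (0, 0, 0, 0.0)
    U = _Uniforms(rng)
    log = math.log

    def seg_integral(x0, x1):
        # integral of x dt along a decay from x0 to x1
        return ((x0 - x1) / r1 + (x0 * x0 - x1 * x1) / (2.0 * r2)) / N

    if record_events:
        times.append(0.0); xs.append(0.0); ys.append(0.0)
    rate_ev = f + phi
    while True:
        u = U.next()
        if u <= 0.0:
            u = 1e-300
        dt = -log(u) / rate_ev if rate_ev > 0 else t_max - t
        t_new = min(t + dt, t_max)
        tau = t_new - t
        x1 = _decay(x, tau, a, c)
        # bookkeeping of repair flux along the decay segment
        repaired = x - x1
        y_cum += eps * repaired
        y_pending += eps * repaired
        # time-average accumulation, honouring the burn-in boundary
        if t_new > t_burn:
            if t >= t_burn:
                int_x += seg_integral(x, x1)
            else:
                x_at = _decay(x, t_burn - t, a, c)
                int_x += seg_integral(x_at, x1)
        while next_sample < t_new:
            times.append(next_sample); xs.append(_decay(x, next_sample - t, a, c)); ys.append(y_cum)
            next_sample += sample_dt
        t = t_new
        x = x1
        if burn is None and t > t_burn:
            burn = (n_unrep, n_err, n_clust, y_cum)
        if t >= t_max:
            while next_sample <= t_max:
                times.append(next_sample); xs.append(x); ys.append(y_cum)
                next_sample += sample_dt
            break
        if rate_ev <= 0:
            break
        if U.next() * rate_ev < f:  # burst with exponential size
            x += rng.exponential(b)
        else:  # division
            divisions.append(t)
            frac = x - math.floor(x)
            k = int(math.floor(x)) + (1 if U.next() < frac else 0)
            dm, dc = _division_outcomes(k, params, rng)
            n_unrep += dm
            n_clust += dc
            if y_pending > 0.0:
                n_err += int(rng.poisson(0.5 * y_pending))
                y_pending = 0.0
        if record_events:
            times.append(t); xs.append(x); ys.append(y_cum)
    denom = t_max - t_burn
    nan = float("nan")
    return Trajectory(
        np.asarray(times), np.asarray(xs), np.asarray(ys),
        np.full(len(times), nan), np.asarray(divisions),
        n_unrep, n_err, n_clust, x, y_cum, nan,
        int_x / denom if denom > 0 else nan, t_max, t_burn, "qss", seed,
        burn if burn is not None else (n_unrep, n_err, n_clust, y_cum),
    )


def replicate_summary(
    params: ModelParams,
    t_max: float,
    n_reps: int,
    mode: Literal["full", "qss"] = "full",
    seed: int = 0,
    t_burn: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Terminal state and counters across replicate lineages.

    Replicate ``i`` uses seed ``seed + i``.  Returns ``(replicates, summary)``
    where ``summary`` holds the mean and standard error of every column.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    rows = []
    for i in range(n_reps):
        tr = simulate(params, t_max, mode=mode, seed=seed + i,
                      sample_dt=math.inf, t_burn=t_burn)
        w = tr.windowed_rates()
        rows.append(
            dict(
                replicate=i, seed=seed + i, x=tr.final_x, y=tr.final_y,
                time_avg_x=tr.time_avg_x, n_unrepaired=tr.n_unrepaired,
                n_errors=tr.n_errors, n_cluster_events=tr.n_cluster_events,
                n_divisions=len(tr.division_times),
                rate_unrepaired=w["n_unrepaired"], rate_errors=w["n_errors"],
                rate_clusters=w["n_cluster_events"], rate_y=w["y"],
            )
        )
    reps = pd.DataFrame(rows).set_index("replicate")
    return reps, summarize_replicates(reps)


def summarize_replicates(reps: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error (from replicate variance) of each column."""
    cols = [c for c in reps.columns if c != "seed"]
    return pd.DataFrame({"mean": reps[cols].mean(), "se": reps[cols].sem()})
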