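"""Genome-window repair-rate estimation and the hyperbolic mutation-rate model.

Nucleotide-excision-repair (NER) rates along the genome are estimated per
window (5 Mb by default) by fitting an exponential decay to lesion-count time
courses, L(t) = L0 * exp(-rNER * t).  The kinetic model predicts that
mutations from unrepaired damage in a window scale as 1/(rNER - r*), where r*
is the critical rate below which local repair is overwhelmed, while mutations
from repair errors are independent of rNER.  Counts binned by repair-rate
percentile are therefore fit with

    y = A / (r - r*) + B,

whose baseline B captures the rate-independent repair-error channel and whose
hyperbolic part captures translesion synthesis (TLS) over unrepaired damage;
the per-bin TLS share [A/(r-r*)] / [A/(r-r*) + B] decomposes the two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "HyperbolicFit",
    "estimate_ner_rates",
    "bin_by_rate",
    "fit_hyperbolic",
    "hyperbolic",
    "decompose_contributions",
]


def estimate_ner_rates(timecourse: pd.DataFrame, nonlinear: bool = False) -> pd.DataFrame:
    """Per-window repair rates from lesion-count time courses.

    ``timecourse`` columns: window_id, time, count.  Default fit is linear
    regression of log counts on time, weighted by sqrt(count) — the
    inverse-variance weight for Poisson counts on the log scale, which removes
    the small-count bias of late time points; the fit is exact in the
    noiseless case.  Windows with a nonpositive count at any time point, or
    fewer than two usable time points, are dropped and reported in the
    ``dropped`` attribute.  ``nonlinear=True`` refines with a nonlinear
    exponential fit.
    """
    required = {"window_id", "time", "count"}
    if not required.issubset(timecourse.columns):
        raise ValueError(f"time course needs columns {sorted(required)}")
    rows, dropped = [], []
    for wid, sub in timecourse.groupby("window_id", sort=False):
        t = sub.time.to_numpy(dtype=float)
        c = sub["count"].to_numpy(dtype=float)
        if (c <= 0).any() or len(sub) < 2 or np.unique(t).size < 2:
            dropped.append(wid)
            continue
        slope, intercept = np.polyfit(t, np.log(c), 1, w=np.sqrt(c))
        rate, L0 = -slope, float(np.exp(intercept))
        if nonlinear:
            try:
                (L0, rate), _ = optimize.curve_fit(
                    lambda tt, l0, r: l0 * np.exp(-r * tt), t, c, p0=[L0, rate]
                )
            except RuntimeError:
                pass
        rows.append(dict(window_id=wid, rate=float(rate), L0=float(L0)))
    if not rows and dropped:
        raise ValueError("no window had >= 2 usable (positive-count) time points")
    out = pd.DataFrame(rows, columns=["window_id", "rate", "L0"])
    out.attrs["dropped"] = dropped
    return out


def bin_by_rate(windows: pd.DataFrame, n_bins: int,
                count_cols: list[str] | None = None) -> pd.DataFrame:
    """Aggregate window mutation counts into repair-rate percentile bins.

    ``windows`` must carry a ``rate`` column; ``count_cols`` (default: all
    numeric columns except ``rate``) are summed per bin.  Bins are equal-count
    partitions of the rate-sorted windows (sizes differ by at most 1).
    """
    if "rate" not in windows.columns:
        raise ValueError("windows must carry a 'rate' column")
    if len(windows) < n_bins:
        raise ValueError(f"fewer windows ({len(windows)}) than bins ({n_bins})")
    if count_cols is None:
        count_cols = [
            c for c in windows.columns
            if c != "rate" and np.issubdtype(windows[c].dtype, np.number)
        ]
    w = windows.sort_values("rate", kind="mergesort").reset_index(drop=True)
    bin_idx = (np.arange(len(w)) * n_bins) // len(w)
    g = w.groupby(bin_idx)
    out = g[count_cols].sum() if count_cols else pd.DataFrame(index=g.size().index)
    out.insert(0, "rate", g["rate"].mean())
    out.insert(1, "n_windows", g.size())
    out.index.name = "bin"
    return out.reset_index()


def hyperbolic(r, A, r_star, B):
    """Window mutation-count model y = A/(r - r*) + B."""
    return A / (np.asarray(r, dtype=float) - r_star) + B


@dataclass
class HyperbolicFit:
    """Fitted y = A/(r - r*) + B with A, B >= 0 and r* below the observed rates."""

    A: float
    r_star: float
    B: float
    r_squared: float
    sse: float
    n_points: int
    converged: bool
    cov: np.ndarray | None = None

    def predict(self, r):
        return hyperbolic(r, self.A, self.r_star, self.B)

    def stderr(self) -> dict:
        if self.cov is None:
            return {}
        se = np.sqrt(np.diag(self.cov))
        return dict(zip(("A", "r_star", "B"), se))


def fit_hyperbolic(rates, counts) -> HyperbolicFit:
    """Constrained least squares for the hyperbolic mutation-rate model.

    Multi-start over r* initializations {0, min(r)/2, min(r) - 2*delta}
    (delta = 1e-6 * rate range) avoids the pole at r = r*; ties broken by
    lowest SSE.  Reports R^2 = 1 - SSE/SST on the fitted points.
    """
    r = np.asarray(rates, dtype=float)
    y = np.asarray(counts, dtype=float)
    if r.size != y.size or r.size < 4:
        raise ValueError("need >= 4 (rate, count) pairs")
    if np.any(r <= 0):
        raise ValueError("rates must be positive")
    rmin = float(r.min())
    delta = 1e-6 * max(float(np.ptp(r)), rmin)
    upper_rstar = rmin - delta
    best = None
    y_mean_start = max(float(y.mean()), 1e-12)

    def residuals(theta):
        return hyperbolic(r, *theta) - y

    for rs0 in (min(0.0, upper_rstar - delta), rmin / 2.0, rmin - 2.0 * delta):
        rs0 = min(rs0, upper_rstar - delta)
        A0 = max((y.max() - y.min()) * (rmin - rs0), delta)
        for A_init, B_init in ((A0, max(float(y.min()), 0.0)), (0.0, y_mean_start)):
            try:
                sol = optimize.least_squares(
                    residuals,
                    x0=[A_init, rs0, B_init],
                    bounds=([0.0, -np.inf, 0.0], [np.inf, upper_rstar, np.inf]),
                    xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except Exception:
                continue
            sse = float(2.0 * sol.cost)
            if best is None or sse < best[0]:
                best = (sse, sol)
    if best is None:
        raise RuntimeError("hyperbolic fit failed from every start")
    sse, sol = best
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    cov = None
    try:
        J = sol.jac
        dof = max(r.size - 3, 1)
        cov = np.linalg.pinv(J.T @ J) * (sse / dof)
    except Exception:
        pass
    A, r_star, B = (float(v) for v in sol.x)
    return HyperbolicFit(A, r_star, B, r2, sse, int(r.size), bool(sol.success), cov)


def decompose_contributions(fit: HyperbolicFit, rates, counts) -> pd.DataFrame:
    """Per-bin and aggregate TLS vs repair-error shares of the fitted counts.

    The TLS (unrepaired-damage) share in a bin is [A/(r-r*)]/[A/(r-r*)+B]; the
    repair-error share is its complement.  The aggregate row is the
    count-weighted mean of the per-bin shares.
    """
    r = np.asarray(rates, dtype=float)
    y = np.asarray(counts, dtype=float)
    tls_part = fit.A / (r - fit.r_star)
    total = tls_part + fit.B
    tls_share = np.where(total > 0, tls_part / total, 0.0)
    out = pd.DataFrame(
        dict(rate=r, count=y, tls_share=tls_share, repair_error_share=1.0 - tls_share)
    )
    wsum = y.sum()
    agg_tls = float((tls_share * y).sum() / wsum) if wsum > 0 else float(tls_share.mean())
    out.attrs["aggregate_tls_share"] = agg_tls
    out.attrs["aggregate_repair_error_share"] = 1.0 - agg_tls
    return out
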