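"""Association statistics between damage-specific signatures and SBS5.

The model predicts that mutations funneled through error-prone bypass/repair
(SBS5-like) co-accumulate with damage-specific signatures across samples.
Associations are quantified with ordinary least squares on Z-scored
variables: the semipartial coefficient of determination SR^2 — the variance
in the response uniquely explained by one predictor, R^2(full) minus
R^2(full without that predictor) — plus partial correlations against a
baseline, a power filter (> 25 focus mutations per sample, >= 20 samples),
Bonferroni correction, and a donor-level resampling scheme that draws one
sample per individual to guard against intra-individual pseudoreplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SemipartialResult",
    "semipartial_r2",
    "partial_correlation",
    "power_filter",
    "bonferroni",
    "donor_resample",
]


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant column cannot be Z-scored")
    return (a - a.mean(axis=0)) / sd


def _ols_r2(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Coefficients and R^2 of OLS with intercept on Z-scored data."""
    n = X.shape[0]
    Xi = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    resid = y - Xi @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 0.0
    return beta, r2


@dataclass(frozen=True)
class SemipartialResult:
    sr2: float
    coefficient: float
    p_value: float
    r2_full: float
    r2_reduced: float
    n: int


def semipartial_r2(
    data: pd.DataFrame,
    y: str,
    x_focus: str,
    covariates: list[str] | None = None,
) -> SemipartialResult:
    """Variance in ``y`` uniquely explained by ``x_focus`` beyond the covariates.

    All variables are Z-scored; SR^2 = R^2(focus + covariates) -
    R^2(covariates only).  The two-sided p-value is the exact t-test of the
    focus coefficient in the full model.  Collinear designs (condition number
    > 1e8) trigger a warning.
    """
    covariates = list(covariates or [])
    cols = [y, x_focus, *covariates]
    sub = data[cols].astype(float).dropna()
    n = len(sub)
    k_full = 1 + len(covariates)
    if n < k_full + 2:
        raise ValueError(f"need at least {k_full + 2} rows, got {n}")
    Z = _zscore(sub.to_numpy())
    yv = Z[:, 0]
    X_full = Z[:, 1:]
    if X_full.shape[1] > 1 and np.linalg.cond(X_full) > 1e8:
        warnings.warn("predictors are nearly collinear; SR^2 may be unstable")
    beta, r2_full = _ols_r2(X_full, yv)
    if covariates:
        _, r2_red = _ols_r2(Z[:, 2:], yv)
    else:
        r2_red = 0.0
    sr2 = r2_full - r2_red
    # exact t-test on the focus coefficient
    Xi = np.column_stack([np.ones(n), X_full])
    dof = n - Xi.shape[1]
    resid = yv - Xi @ beta
    sigma2 = float((resid**2).sum()) / dof
    XtX_inv = np.linalg.pinv(Xi.T @ Xi)
    se = float(np.sqrt(sigma2 * XtX_inv[1, 1]))
    tstat = beta[1] / se if se > 0 else np.inf
    p = 2.0 * stats.t.sf(abs(tstat), dof)
    return SemipartialResult(float(sr2), float(beta[1]), float(p),
                             float(r2_full), float(r2_red), n)


def partial_correlation(
    data: pd.DataFrame, y: str, x: str, control: list[str] | str
) -> tuple[float, float]:
    """Pearson correlation of ``y`` and ``x`` after removing the control variable(s).

    Both are residualized on the controls by OLS; the p-value uses the t
    distribution with n - 2 - k degrees of freedom (k controls).
    """
    control = [control] if isinstance(control, str) else list(control)
    sub = data[[y, x, *control]].astype(float).dropna()
    n = len(sub)
    k = len(control)
    if n < k + 4:
        raise ValueError("too few rows for partial correlation")
    C = np.column_stack([np.ones(n), sub[control].to_numpy()])
    def _resid(v):
        beta, *_ = np.linalg.lstsq(C, v, rcond=None)
        return v - C @ beta
    yv, xv = sub[y].to_numpy(), sub[x].to_numpy()
    ry = _resid(yv)
    rx = _resid(xv)
    # degenerate: a variable fully explained by the controls has no residual
    # direction left, so the partial correlation is taken as 0
    if (np.linalg.norm(ry) < 1e-8 * max(np.linalg.norm(yv - yv.mean()), 1e-300)
            or np.linalg.norm(rx) < 1e-8 * max(np.linalg.norm(xv - xv.mean()), 1e-300)):
        return 0.0, 1.0
    denom = np.linalg.norm(ry) * np.linalg.norm(rx)
    if denom == 0:
        return 0.0, 1.0
    r = float(ry @ rx / denom)
    dof = n - 2 - k
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    tstat = r * np.sqrt(dof / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(tstat), dof)
    return r, float(p)


def power_filter(
    data: pd.DataFrame,
    focus: str,
    min_mutations: int = 25,
    min_samples: int = 20,
) -> pd.DataFrame | None:
    """Keep samples with strictly more than ``min_mutations`` focus-signature mutations.

    Returns the filtered frame, or ``None`` ("not powered") when fewer than
    ``min_samples`` samples survive.
    """
    kept = data[data[focus] > min_mutations]
    if len(kept) < min_samples:
        return None
    return kept


def bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Boolean significance flags at the Bonferroni-corrected level alpha/m."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    return p <= alpha / m


def donor_resample(
    data: pd.DataFrame,
    y: str,
    x_focus: str,
    covariates: list[str] | None = None,
    n_rep: int = 5000,
    seed: int = 0,
    individual_col: str = "individual_id",
) -> pd.DataFrame:
    """SR^2 distribution over replicates drawing one sample per individual.

    Each replicate resamples a single row per donor (uniformly, with a
    replicate-indexed RNG stream), recomputes the semipartial R^2, and the
    per-replicate values are returned along with summary quantiles in
    ``attrs['quantiles']``.  Guards associations against being driven by the
    genealogical structure of multiple samples per individual.
    """
    if individual_col not in data.columns:
        raise ValueError(f"column {individual_col!r} required for donor resampling")
    groups = [sub.index.to_numpy() for _, sub in data.groupby(individual_col)]
    if len(groups) < 2:
        raise ValueError("donor resampling requires >= 2 individuals")
    out = np.empty(n_rep)
    for i in range(n_rep):
        rng = np.random.default_rng([seed, i])
        rows = [g[rng.integers(len(g))] for g in groups]
        res = semipartial_r2(data.loc[rows], y, x_focus, covariates)
        out[i] = res.sr2
    df = pd.DataFrame({"replicate": np.arange(n_rep), "sr2": out})
    df.attrs["quantiles"] = {
        q: float(np.quantile(out, q)) for q in (0.025, 0.25, 0.5, 0.75, 0.975)
    }
    return df
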