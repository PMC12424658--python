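"""Inference of co-occurring (clustered) point mutations.

Mutations produced by a single event — e.g. a lesion-site TLS error together
with a collateral error nearby — appear as pairs at short genomic distances.
Chance co-localization of independent mutations also produces short distances,
so clustering is inferred from the distribution of within-sample,
within-chromosome-arm pair distances r modelled as a two-component mixture

    P(r) = rho * P1(r) + (1 - rho) * P0(r),

where P0 is the triangular null for uniformly placed mutations on an arm of
length l, P0(r) ∝ (l - r), P1 is a (truncated) negative binomial for genuine
co-occurrence, and rho is the pairwise prevalence.  The fitted mixture yields
an analytic false-discovery rate for any distance threshold,

    FDR(r) = (1-rho) F0(r) / [rho F1(r) + (1-rho) F0(r)],

used to gate cluster calling (default threshold r = 100 bp, arms with
FDR(100) > 5% excluded).  Distances r = 1 (double-base substitutions) and
r = 2 are excluded throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ArmSet",
    "ClusterFit",
    "pairwise_distances",
    "null_distance_pmf",
    "null_distance_cdf",
    "cross_individual_distances",
    "fit_mixture",
    "fdr_curve",
    "call_clusters",
    "cluster_asymmetry",
    "MIN_R_DEFAULT",
]

MIN_R_DEFAULT = 3

MUTATION_COLUMNS = ["individual_id", "sample_id", "chrom", "pos", "ref", "alt"]


@dataclass(frozen=True)
class ArmSet:
    """Chromosome-arm intervals (BED convention: 0-based half-open).

    ``table`` columns: chrom, start, end, arm_id.  Arms must be nonoverlapping
    within a chromosome and longer than the minimum pair support.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"chrom", "start", "end", "arm_id"}
        if not required.issubset(t.columns):
            raise ValueError(f"arm table needs columns {sorted(required)}")
        if (t.end - t.start <= 3).any():
            raise ValueError("arm length must exceed the minimum support (l > 3)")
        for chrom, sub in t.groupby("chrom"):
            s = sub.sort_values("start")
            if (s.start.values[1:] < s.end.values[:-1]).any():
                raise ValueError(f"overlapping arms on {chrom}")

    @property
    def lengths(self) -> pd.Series:
        return (self.table.end - self.table.start).set_axis(self.table.arm_id)

    def assign(self, muts: pd.DataFrame) -> pd.DataFrame:
        """Map 1-based mutation positions onto arms; unmapped rows get arm_id NaN.

        A 1-based position pos lies on a 0-based half-open arm [start, end)
        iff start + 1 <= pos <= end.
        """
        out = muts.copy()
        out["arm_id"] = pd.NA
        out["arm_length"] = np.nan
        for _, arm in self.table.iterrows():
            m = (
                (out.chrom == arm.chrom)
                & (out.pos >= arm.start + 1)
                & (out.pos <= arm.end)
            )
            out.loc[m, "arm_id"] = arm.arm_id
            out.loc[m, "arm_length"] = arm.end - arm.start
        return out


def _require_assigned(muts: pd.DataFrame, arms: ArmSet) -> tuple[pd.DataFrame, int]:
    if "arm_id" not in muts.columns or "arm_length" not in muts.columns:
        muts = arms.assign(muts)
    unmapped = int(muts.arm_id.isna().sum())
    if unmapped:
        warnings.warn(f"{unmapped} mutations fall outside all arms and are skipped")
    return muts[muts.arm_id.notna()], unmapped


def pairwise_distances(
    muts: pd.DataFrame,
    arms: ArmSet,
    min_r: int = MIN_R_DEFAULT,
    with_pairs: bool = False,
) -> pd.DataFrame:
    """All unordered within-sample, within-arm pair distances.

    Returns a frame with columns (sample_id, arm_id, arm_length, r) — plus the
    row indices (i, j) of each pair when ``with_pairs`` — keeping
    min_r <= r <= l - 1.  The default ``min_r=3`` drops r = 1 (DBS) and r = 2.
    """
    if min_r < 1:
        raise ValueError("min_r must be >= 1")
    mapped, _ = _require_assigned(muts, arms)
    rows = []
    for (sample, arm), sub in mapped.groupby(["sample_id", "arm_id"], observed=True):
        pos = sub.pos.to_numpy(dtype=np.int64)
        if pos.size < 2:
            continue
        l = int(sub.arm_length.iloc[0])
        idx = sub.index.to_numpy()
        order = np.argsort(pos)
        pos = pos[order]
        idx = idx[order]
        i, j = np.triu_indices(pos.size, k=1)
        r = pos[j] - pos[i]
        keep = (r >= min_r) & (r <= l - 1)
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": sample,
                    "arm_id": arm,
                    "arm_length": l,
                    "r": r[keep],
                    **({"i": idx[i[keep]], "j": idx[j[keep]]} if with_pairs else {}),
                }
            )
        )
    cols = ["sample_id", "arm_id", "arm_length", "r"] + (["i", "j"] if with_pairs else [])
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.concat(rows, ignore_index=True)


def cross_individual_distances(muts: pd.DataFrame, arms: ArmSet,
                               min_r: int = MIN_R_DEFAULT) -> pd.DataFrame:
    """Within-arm distances between mutations of *different* individuals.

    Such pairs cannot arise from a single mutagenic event and provide an
    empirical null to compare against the triangular prediction.
    """
    mapped, _ = _require_assigned(muts, arms)
    if mapped.individual_id.nunique() < 2:
        raise ValueError("cross-individual distances require >= 2 individuals")
    rows = []
    for arm, sub in mapped.groupby("arm_id", observed=True):
        pos = sub.pos.to_numpy(dtype=np.int64)
        ind = sub.individual_id.to_numpy()
        if pos.size < 2:
            continue
        l = int(sub.arm_length.iloc[0])
        i, j = np.triu_indices(pos.size, k=1)
        cross = ind[i] != ind[j]
        r = np.abs(pos[j] - pos[i])[cross]
        keep = (r >= min_r) & (r <= l - 1)
        rows.append(pd.DataFrame({"arm_id": arm, "arm_length": l, "r": r[keep]}))
    if not rows:
        return pd.DataFrame(columns=["arm_id", "arm_length", "r"])
    return pd.concat(rows, ignore_index=True)


def null_distance_pmf(l: int, min_r: int = MIN_R_DEFAULT) -> np.ndarray:
    """Triangular null pmf over r in [min_r, l-1], normalized on that support.

    Under a uniform mutation rate on a segment of length l the all-pairs
    distance law is P0(r) ∝ (l - r); the raw (l-r)/l^2 is renormalized over
    the retained support.
    """
    if l <= min_r + 1:
        raise ValueError("arm length too small for the requested support")
    r = np.arange(min_r, l)
    w = (l - r).astype(float)
    return w / w.sum()


def null_distance_cdf(r, l: int, min_r: int = MIN_R_DEFAULT):
    """Closed-form CDF of the triangular null at distance(s) r (P(R <= r))."""
    r = np.asarray(r, dtype=float)
    rc = np.clip(r, min_r - 1, l - 1)
    # sum_{k=min_r}^{rc} (l - k) with normalization over [min_r, l-1]
    def cum(v):
        n = v - min_r + 1
        return n * l - (v * (v + 1) - (min_r - 1) * min_r) / 2.0
    total = cum(l - 1.0)
    out = np.where(r < min_r, 0.0, cum(np.floor(rc)) / total)
    return out if out.ndim else float(out)


@dataclass
class ClusterFit:
    """Fitted mixture of the triangular null and a truncated negative binomial.

    ``rho`` is the pairwise prevalence; P1 is a negative binomial with mean
    ``nb_mean`` and dispersion ``nb_dispersion`` (variance mu + mu^2/k),
    truncated to r >= min_r and renormalized.  ``arm_weights`` are per-arm
    pair-count shares used by the pooled null.
    """

    rho: float
    nb_mean: float
    nb_dispersion: float
    min_r: int
    arm_lengths: dict = field(default_factory=dict)
    arm_weights: dict = field(default_factory=dict)
    converged: bool = True
    n_distances: int = 0
    max_cdf_residual: float = float("nan")

    def null_cdf(self, r) -> np.ndarray:
        """Pooled triangular-null CDF (pair-count-weighted mixture over arms)."""
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        for arm, w in self.arm_weights.items():
            out += w * null_distance_cdf(r, self.arm_lengths[arm], self.min_r)
        return out

    def clustered_cdf(self, r) -> np.ndarray:
        """CDF of the truncated negative binomial P1 (P(R <= r))."""
        k = max(self.nb_dispersion, 1e-12)
        mu = max(self.nb_mean, 1e-12)
        p = k / (k + mu)
        lo = stats.nbinom.cdf(self.min_r - 1, k, p)
        denom = max(1.0 - lo, 1e-300)
        r = np.asarray(r, dtype=float)
        out = np.clip((stats.nbinom.cdf(np.floor(r), k, p) - lo) / denom, 0.0, 1.0)
        return np.where(r < self.min_r, 0.0, out)

    def mixture_cdf(self, r) -> np.ndarray:
        return self.rho * self.clustered_cdf(r) + (1.0 - self.rho) * self.null_cdf(r)


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(t):
    return 1.0 / (1.0 + np.exp(-t))


def fit_mixture(
    distances: pd.DataFrame,
    min_r: int = MIN_R_DEFAULT,
    rho0: float = 0.01,
    nb_mean0: float = 30.0,
    nb_dispersion0: float = 1.0,
) -> ClusterFit:
    """Fit (rho, nb_mean, nb_dispersion) to pooled pair distances.

    Nonlinear least squares (Levenberg–Marquardt) on the log empirical CDF
    versus the log mixture CDF evaluated at the observed distances, with rho
    logit-transformed and the NB parameters log-transformed to respect their
    ranges.  ``distances`` must carry columns (arm_id, arm_length, r) as
    produced by :func:`pairwise_distances`.
    """
    r_all = distances.r.to_numpy(dtype=float)
    n = r_all.size
    if n < 100:
        warnings.warn(f"only {n} distances: mixture fit may be unstable")
    if n == 0:
        raise ValueError("no distances to fit")
    counts = distances.groupby("arm_id", observed=True).agg(
        n=("r", "size"), l=("arm_length", "first")
    )
    arm_lengths = {a: int(l) for a, l in counts.l.items()}
    arm_weights = {a: c / n for a, c in counts.n.items()}
    fit = ClusterFit(0.0, nb_mean0, nb_dispersion0, min_r, arm_lengths, arm_weights,
                     n_distances=n)

    r_sorted = np.sort(r_all)
    r_grid, last_idx = np.unique(r_sorted, return_index=True)
    # empirical CDF at each unique r (P(R <= r))
    counts_le = np.searchsorted(r_sorted, r_grid, side="right")
    ecdf = counts_le / n
    y = np.log(ecdf)

    def model(_x, t_rho, t_mu, t_k):
        # clamp the transforms so LM excursions cannot leave the NB's domain
        fit.rho = float(_expit(np.clip(t_rho, -40.0, 40.0)))
        fit.nb_mean = float(np.exp(np.clip(t_mu, -20.0, 25.0)))
        fit.nb_dispersion = float(np.exp(np.clip(t_k, -20.0, 20.0)))
        return np.log(np.maximum(fit.mixture_cdf(r_grid), 1e-300))

    theta0 = [_logit(np.clip(rho0, 1e-6, 1 - 1e-6)), np.log(nb_mean0), np.log(nb_dispersion0)]
    try:
        popt, _ = optimize.curve_fit(model, np.log(r_grid), y, p0=theta0,
                                     method="lm", maxfev=5000, xtol=1e-8, ftol=1e-8)
        fit.converged = True
    except RuntimeError as e:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"mixture fit did not converge: {e}") from e
    fit.rho = float(_expit(np.clip(popt[0], -40.0, 40.0)))
    fit.nb_mean = float(np.exp(np.clip(popt[1], -20.0, 25.0)))
    fit.nb_dispersion = float(np.exp(np.clip(popt[2], -20.0, 20.0)))
    # NB parameters driven to the transform boundaries mean the clustered
    # component is unidentified (it degenerated while chasing a handful of
    # chance pairs): report a pure-null fit instead
    if popt[1] >= 25.0 - 1e-6 or not (-20.0 + 1e-6 < popt[2] < 20.0 - 1e-6):
        fit.rho = 0.0
        fit.nb_mean = nb_mean0
        fit.nb_dispersion = nb_dispersion0
        fit.converged = False
    fit.max_cdf_residual = float(np.max(np.abs(fit.mixture_cdf(r_grid) - ecdf)))
    return fit


def fdr_curve(fit: ClusterFit, r, arm_id=None):
    """Expected false discovery rate at threshold distance r (pairs with r' < r).

    FDR(r) = (1-rho) F0 / (rho F1 + (1-rho) F0) with F0, F1 the null and
    clustered CDFs over r' < r; ``arm_id`` selects an arm-specific null,
    otherwise the pooled null is used.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= fit.min_r) :
        raise ValueError(f"threshold must exceed min_r={fit.min_r}")
    rm = r - 1.0  # strictly below the threshold
    if arm_id is None:
        f0 = fit.null_cdf(rm)
    else:
        f0 = null_distance_cdf(rm, fit.arm_lengths[arm_id], fit.min_r)
    f1 = fit.clustered_cdf(rm)
    num = (1.0 - fit.rho) * f0
    den = fit.rho * f1 + num
    # degenerate fits (non-finite CDFs, or no mass below the threshold) are
    # treated as all-chance: FDR = 1, so the gate excludes the arm
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1e-300), 1.0)
    out = np.where(np.isfinite(out), out, 1.0)
    return out if out.ndim else float(out)


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


@dataclass
class ClusterCalls:
    """Called clusters plus bookkeeping of the FDR gate."""

    clusters: pd.DataFrame  # cluster_id, sample_id, arm_id, members, span, size
    members: pd.DataFrame  # mutation-row index -> cluster_id
    clustered_fraction: float
    n_mutations_considered: int
    excluded_arms: list
    fdr_by_arm: dict


def call_clusters(
    muts: pd.DataFrame,
    arms: ArmSet,
    fit: ClusterFit,
    r_threshold: int = 100,
    fdr_max: float = 0.05,
) -> ClusterCalls:
    """Link within-sample mutation pairs closer than ``r_threshold`` into clusters.

    Only arms whose analytic FDR at the threshold passes ``fdr_max`` are
    considered; linked pairs are merged into connected components.  The
    clustered fraction is the share of mutations (on passing arms) that belong
    to a cluster.
    """
    mapped, _ = _require_assigned(muts, arms)
    fdr_by_arm = {}
    excluded = []
    for arm in mapped.arm_id.dropna().unique():
        if arm in fit.arm_lengths:
            fdr = float(fdr_curve(fit, r_threshold, arm_id=arm))
        else:  # arm contributed no distances to the fit: use pooled null
            fdr = float(fdr_curve(fit, r_threshold))
        fdr_by_arm[arm] = fdr
        if fdr > fdr_max:
            excluded.append(arm)
    ok = mapped[~mapped.arm_id.isin(excluded)]
    pairs = pairwise_distances(ok, arms, min_r=fit.min_r, with_pairs=True)
    close = pairs[pairs.r < r_threshold]
    uf = _UnionFind(ok.index)
    for i, j in zip(close.i, close.j):
        uf.union(i, j)
    roots = {}
    for idx in ok.index:
        roots.setdefault(uf.find(idx), []).append(idx)
    comp = {r: m for r, m in roots.items() if len(m) > 1}
    rows, member_rows = [], []
    for cid, (root, members) in enumerate(sorted(comp.items(), key=lambda kv: kv[0])):
        sub = ok.loc[members]
        rows.append(
            dict(
                cluster_id=cid,
                sample_id=sub.sample_id.iloc[0],
                arm_id=sub.arm_id.iloc[0],
                size=len(members),
                span=int(sub.pos.max() - sub.pos.min()),
                positions=sorted(sub.pos.tolist()),
            )
        )
        member_rows.extend(dict(row=m, cluster_id=cid) for m in members)
    clusters = pd.DataFrame(rows, columns=["cluster_id", "sample_id", "arm_id",
                                           "size", "span", "positions"])
    members = pd.DataFrame(member_rows, columns=["row", "cluster_id"])
    n_considered = len(ok)
    frac = len(members) / n_considered if n_considered else 0.0
    return ClusterCalls(clusters, members, frac, n_considered, excluded, fdr_by_arm)


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def cluster_asymmetry(
    muts: pd.DataFrame,
    calls: ClusterCalls,
    bins: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Polarized positional asymmetry of cluster partners around C:G→A:T mutations.

    Assuming every C:G→A:T mutation reflects a damaged guanine, the lesion
    strand is the reference strand for G→T mutations and the complement for
    C→A.  For clusters containing exactly one such polarizing mutation, each
    partner's signed offset is recorded 5'→3' along the lesion strand and
    binned; enrichment is the bin count relative to a sign-shuffling
    permutation null, with a permutation interval.
    Clusters with several polarizing mutations are excluded.
    """
    if bins is None:
        bins = np.array([-100, -50, -20, 0, 20, 50, 100], dtype=float)
    rng = np.random.default_rng(seed)
    offsets = []
    for _, cl in calls.clusters.iterrows():
        rows = calls.members[calls.members.cluster_id == cl.cluster_id].row
        sub = muts.loc[rows]
        polar = sub[((sub.ref == "G") & (sub.alt == "T")) | ((sub.ref == "C") & (sub.alt == "A"))]
        if len(polar) != 1:
            continue
        pm = polar.iloc[0]
        sign = 1 if pm.ref == "G" else -1
        for _, partner in sub.drop(polar.index).iterrows():
            offsets.append(sign * (partner.pos - pm.pos))
    offsets = np.asarray(offsets, dtype=float)
    if offsets.size == 0:
        warnings.warn("no polarizing C:G->A:T mutations in any cluster")
        return pd.DataFrame(columns=["bin_left", "bin_right", "observed",
                                     "null_mean", "null_lo", "null_hi", "enrichment"])
    obs, _ = np.histogram(offsets, bins=bins)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, offsets.size))
    null_counts = np.stack([
        np.histogram(signs[k] * np.abs(offsets), bins=bins)[0] for k in range(n_perm)
    ])
    null_mean = null_counts.mean(axis=0)
    lo, hi = np.percentile(null_counts, [2.5, 97.5], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.where(null_mean > 0, obs / null_mean, np.nan)
    return pd.DataFrame(
        dict(bin_left=bins[:-1], bin_right=bins[1:], observed=obs,
             null_mean=null_mean, null_lo=lo, null_hi=hi, enrichment=enr)
    )
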