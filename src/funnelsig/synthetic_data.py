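"""Synthetic inputs with recorded ground truth for every pipeline stage.

Each generator emulates the structure of one class of real input — COSMIC-style
signature catalogs, per-sample mutation tables with a planted clustered
fraction, lesion-decay time courses, window mutation counts following the
hyperbolic repair-rate law, and per-cell exposure tables with a planted
damage-signature coupling — and returns the data together with a
:class:`SyntheticTruth` sufficient to recompute every expected statistic.
All generators are deterministic given their seed.

The generators make no attempt to mimic the real human genome's composition,
real COSMIC vectors, or real cohort exposure margins; they provide controlled
conditions under which parameter recovery can be verified exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clusters import MIN_R_DEFAULT, ArmSet
from .signatures import SBS96_CLASSES

__all__ = [
    "SyntheticTruth",
    "gen_arms",
    "gen_signature_catalog",
    "gen_mutation_table",
    "gen_repair_timecourse",
    "gen_window_counts",
    "gen_cells",
]

_PURINE_FLIP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SyntheticTruth:
    """Planted parameters of a generated dataset, JSON-serializable."""

    generator: str
    params: dict = field(default_factory=dict)
    derived: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o).__name__)

        s = json.dumps(
            {"generator": self.generator, "params": self.params, "derived": self.derived},
            indent=2, default=default,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def gen_arms(n_arms: int = 8, length: int = 50_000_000) -> ArmSet:
    """A synthetic karyotype: ``n_arms`` equal-length arms, two per chromosome."""
    rows = []
    for i in range(n_arms):
        chrom = f"chr{i // 2 + 1}"
        which = "p" if i % 2 == 0 else "q"
        start = 0 if which == "p" else length + 3_000_000  # centromere gap
        rows.append(dict(chrom=chrom, start=start, end=start + length,
                         arm_id=f"{chrom[3:]}{which}"))
    return ArmSet(pd.DataFrame(rows))


def gen_signature_catalog(
    n_signatures: int = 5,
    sparse_concentration: float = 0.05,
    flat_concentration: float = 50.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """COSMIC-style catalog: sparse Dirichlet signatures plus one flat column.

    The designated flat column (named ``SBS5like``, always last) emulates the
    diffuse SBS5 spectrum (entropy > 6 bits); the others are peaked,
    damage-specific-like spectra.
    """
    if n_signatures < 1:
        raise ValueError("need at least one signature")
    rng = np.random.default_rng(seed)
    cols = {}
    for i in range(n_signatures - 1):
        cols[f"SIG{i + 1}"] = rng.dirichlet(np.full(96, sparse_concentration))
    cols["SBS5like"] = rng.dirichlet(np.full(96, flat_concentration))
    catalog = pd.DataFrame(cols, index=SBS96_CLASSES)
    truth = SyntheticTruth(
        "gen_signature_catalog",
        dict(n_signatures=n_signatures, sparse_concentration=sparse_concentration,
             flat_concentration=flat_concentration, seed=seed),
        dict(flat_signature="SBS5like"),
    )
    return catalog, truth


def _class_to_ref_alt(z: str, flip: bool) -> tuple[str, str]:
    ref, alt = z[2], z[4]
    if flip:
        return _PURINE_FLIP[ref], _PURINE_FLIP[alt]
    return ref, alt


def gen_mutation_table(
    arms: ArmSet,
    n_samples: int = 50,
    n_per_sample: int = 200,
    rho: float = 0.05,
    nb_mean: float = 30.0,
    nb_dispersion: float = 1.0,
    exposures: dict | None = None,
    catalog: pd.DataFrame | None = None,
    collateral_signature: str | None = None,
    n_individuals: int | None = None,
    min_r: int = MIN_R_DEFAULT,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Mutation table with a planted clustered fraction.

    Per sample, ``round(rho * n / 2)`` mutation *pairs* are planted at
    negative-binomial distances (mean ``nb_mean``, dispersion ``nb_dispersion``,
    resampled until >= ``min_r`` and inside the arm); the remaining mutations
    are placed uniformly across arms (length-weighted).  When a catalog is
    given, each mutation's 96-class is drawn from the sample's exposure
    mixture; planted-pair partner classes come from ``collateral_signature``.
    Pyrimidine-strand classes are recorded on either reference strand with
    equal probability (so C>A may appear as G>T).

    The truth records, besides the inputs, the *realized pairwise prevalence*:
    planted pairs divided by all within-sample within-arm pairs at r >= min_r,
    which is the quantity the mixture fit estimates.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = arms.table
    lengths = (t.end - t.start).to_numpy(dtype=float)
    arm_p = lengths / lengths.sum()
    n_individuals = n_individuals or n_samples
    k_nb = nb_dispersion
    p_nb = k_nb / (k_nb + nb_mean)
    sig_names = list(exposures) if exposures else None
    sig_probs = None
    if exposures:
        v = np.asarray([exposures[s] for s in sig_names], dtype=float)
        sig_probs = v / v.sum()
    rows = []
    n_resampled = 0
    pair_id = 0
    n_pairs_per_sample = int(round(rho * n_per_sample / 2.0))
    for si in range(n_samples):
        sample = f"S{si:04d}"
        individual = f"I{si % n_individuals:04d}"
        n_bg = n_per_sample - 2 * n_pairs_per_sample

        def draw_class(signature=None):
            if catalog is None:
                return None, "C", "A"
            if signature is None:
                signature = sig_names[rng.choice(len(sig_names), p=sig_probs)]
            z = SBS96_CLASSES[rng.choice(96, p=catalog[signature].to_numpy())]
            flip = bool(rng.random() < 0.5)
            ref, alt = _class_to_ref_alt(z, flip)
            return z, ref, alt

        for _ in range(n_bg):
            a = rng.choice(len(t), p=arm_p)
            arm = t.iloc[a]
            pos = int(rng.integers(arm.start + 1, arm.end + 1))
            z, ref, alt = draw_class()
            rows.append((individual, sample, arm.chrom, pos, ref, alt, z,
                         arm.arm_id, False, -1))
        for _ in range(n_pairs_per_sample):
            while True:
                a = rng.choice(len(t), p=arm_p)
                arm = t.iloc[a]
                pos1 = int(rng.integers(arm.start + 1, arm.end + 1))
                d = int(rng.negative_binomial(k_nb, p_nb))
                if d < min_r:
                    n_resampled += 1
                    continue
                pos2 = pos1 + d if rng.random() < 0.5 else pos1 - d
                if not (arm.start + 1 <= pos2 <= arm.end):
                    n_resampled += 1
                    continue
                break
            z1, ref1, alt1 = draw_class()
            z2, ref2, alt2 = draw_class(collateral_signature)
            rows.append((individual, sample, arm.chrom, pos1, ref1, alt1, z1,
                         arm.arm_id, True, pair_id))
            rows.append((individual, sample, arm.chrom, pos2, ref2, alt2, z2,
                         arm.arm_id, True, pair_id))
            pair_id += 1
    muts = pd.DataFrame(
        rows,
        columns=["individual_id", "sample_id", "chrom", "pos", "ref", "alt",
                 "sbs96", "arm_id_true", "is_clustered", "pair_id"],
    )
    # realized pairwise prevalence: planted pairs / all within-sample-arm pairs
    total_pairs = 0
    for (_, _), sub in muts.groupby(["sample_id", "arm_id_true"], observed=True):
        pos = np.sort(sub.pos.to_numpy())
        diffs = np.abs(pos[:, None] - pos[None, :])[np.triu_indices(pos.size, k=1)]
        total_pairs += int((diffs >= min_r).sum())
    truth = SyntheticTruth(
        "gen_mutation_table",
        dict(n_samples=n_samples, n_per_sample=n_per_sample, rho=rho,
             nb_mean=nb_mean, nb_dispersion=nb_dispersion, min_r=min_r, seed=seed,
             collateral_signature=collateral_signature),
        dict(
            n_planted_pairs=pair_id,
            n_resampled=n_resampled,
            total_pairs=total_pairs,
            realized_pairwise_prevalence=(pair_id / total_pairs if total_pairs else 0.0),
            clustered_mutation_fraction=float(muts.is_clustered.mean()),
        ),
    )
    return muts, truth


def gen_repair_timecourse(
    n_windows: int = 200,
    rate_range: tuple[float, float] = (0.2, 2.0),
    L0: float = 1e4,
    times: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0, 24.0),
    noise: str = "poisson",
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-window lesion-decay time courses, counts ~ Poisson(L0 exp(-rate t)).

    Rates are log-uniform over ``rate_range``; ``noise='none'`` returns exact
    exponentials.  The default six time points emulate a repair-kinetics
    experiment sampled from 0 to 24 hours.
    """
    if len(times) < 2:
        raise ValueError("need at least two time points")
    rng = np.random.default_rng(seed)
    rates = np.exp(rng.uniform(np.log(rate_range[0]), np.log(rate_range[1]), n_windows))
    rows = []
    for w in range(n_windows):
        for t in times:
            mean = L0 * np.exp(-rates[w] * t)
            c = float(rng.poisson(mean)) if noise == "poisson" else mean
            rows.append(dict(window_id=f"w{w:04d}", time=t, count=c))
    tc = pd.DataFrame(rows)
    truth = SyntheticTruth(
        "gen_repair_timecourse",
        dict(n_windows=n_windows, L0=L0, times=list(times), noise=noise, seed=seed),
        dict(rates={f"w{w:04d}": float(rates[w]) for w in range(n_windows)}),
    )
    return tc, truth


def gen_window_counts(
    rates: np.ndarray,
    A: float = 2.0,
    r_star: float = 0.1,
    B: float = 3.0,
    noise: str = "poisson",
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Window mutation counts from the hyperbolic law y = A/(r - r*) + B."""
    rates = np.asarray(rates, dtype=float)
    if r_star >= rates.min():
        raise ValueError("r_star must lie below every rate (pole violation)")
    rng = np.random.default_rng(seed)
    mean = A / (rates - r_star) + B
    counts = rng.poisson(mean).astype(float) if noise == "poisson" else mean
    df = pd.DataFrame(dict(rate=rates, count=counts))
    truth = SyntheticTruth(
        "gen_window_counts",
        dict(A=A, r_star=r_star, B=B, noise=noise, seed=seed),
        dict(mean_count=float(mean.mean())),
    )
    return df, truth


def gen_cells(
    n_individuals: int = 20,
    cells_per_individual: int = 25,
    beta: float = 1.0,
    gamma: float = 0.5,
    age_coef: float = 1.0,
    sbs4_mean: float = 150.0,
    sbs4_sd: float = 100.0,
    sbs1_per_year: float = 2.0,
    sbs5_base: float = 50.0,
    noise_sd: float = 30.0,
    individual_intercept_sd: float = 0.0,
    noise: str = "poisson",
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-cell exposure table with a planted SBS4 -> SBS5 linear coupling.

    Latent damage-specific exposure m4 ~ Normal(sbs4_mean, sbs4_sd) per cell,
    negative draws truncated at 0 (fraction reported in the truth); SBS1
    tracks donor age (the mitotic clock) with Poisson noise; the SBS5 mean is
    ``sbs5_base + beta*m4 + gamma*SBS1 + age_coef*age`` plus Gaussian noise
    (sd ``noise_sd``), truncated at 0, then observed as Poisson counts when
    ``noise='poisson'``.  The truth records the realized unique-variance
    share of SBS4 — the population value the semipartial R^2 estimates, i.e.
    beta^2 var(m4)^2 / (var(SBS4_obs) var(SBS5_obs)) with m4 independent of
    the other regressors by construction.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n = n_individuals * cells_per_individual
    ages = rng.uniform(20.0, 80.0, n_individuals)
    intercepts = rng.normal(0.0, individual_intercept_sd, n_individuals)
    m4_all = np.empty(n)
    n_truncated = 0
    i = 0
    for d in range(n_individuals):
        for c in range(cells_per_individual):
            m4 = rng.normal(sbs4_mean, sbs4_sd)
            if m4 < 0.0:
                m4 = 0.0
                n_truncated += 1
            m4_all[i] = m4
            sbs1_mean = sbs1_per_year * ages[d]
            sbs1 = float(rng.poisson(sbs1_mean))
            mu5 = (sbs5_base + intercepts[d] + beta * m4 + gamma * sbs1
                   + age_coef * ages[d] + rng.normal(0.0, noise_sd))
            if mu5 < 0.0:
                mu5 = 0.0
                n_truncated += 1
            sbs5 = float(rng.poisson(mu5)) if noise == "poisson" else mu5
            sbs4 = float(rng.poisson(m4)) if noise == "poisson" else m4
            rows.append(dict(sample_id=f"S{i:04d}", individual_id=f"I{d:03d}",
                             age=float(ages[d]), SBS1=sbs1, SBS4=sbs4, SBS5=sbs5))
            i += 1
    df = pd.DataFrame(rows)
    truncation_fraction = n_truncated / (2 * n)
    var_m4 = float(np.var(m4_all))
    var_x4 = float(np.var(df.SBS4))
    var_y = float(np.var(df.SBS5))
    unique_share = beta**2 * var_m4**2 / (var_x4 * var_y) if var_x4 * var_y > 0 else 0.0
    truth = SyntheticTruth(
        "gen_cells",
        dict(n_individuals=n_individuals, cells_per_individual=cells_per_individual,
             beta=beta, gamma=gamma, age_coef=age_coef, noise_sd=noise_sd,
             individual_intercept_sd=individual_intercept_sd, seed=seed),
        dict(realized_unique_variance_sbs4=unique_share,
             truncation_fraction=truncation_fraction),
    )
    return df, truth
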