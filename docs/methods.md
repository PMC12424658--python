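# Methods

`funnelsig` implements the quantitative machinery for studying *collateral
mutagenesis*: the idea that many kinds of DNA damage, when bypassed by
error-prone translesion synthesis (TLS) or repaired by error-prone gap
filling, converge ("funnel") onto a single flat mutational signature of the
SBS5 type. The package has three layers: a stochastic damage/repair/division
model with closed-form results and an exact simulator; genomic statistics
(mutation clusters, per-window repair rates, 96-class spectra); and
association statistics across cells and samples. Every analysis is
exercisable on synthetic data with recorded ground truth.

## The kinetic model

Damage arrives in bursts at frequency `f`; each burst adds a random number of
lesions with mean `b`, so the mean damage rate is `u = f·b`. A pool of `N`
repair agents finds lesions at rate `r1` per lesion per free agent and
completes repair at rate `r2` per engaged agent; a completed repair leaves a
mismatch with probability `eps`. On the slow timescale the repair flux at
lesion load `x` is the harmonic-mean form

    r(x) = N / (1/(r1·x) + 1/r2),

detection-limited (`N·r1·x`) at low load and capacity-limited (`N·r2`) at
saturation.

**Efficient regime** (`N·r2 > f·b`): the lesion load is stationary with
density

    p(x) ∝ (1/(r1·x) + 1/r2) · x^α · e^(−λx),
    α = f/(N·r1),   λ = (N·r2 − f·b)/(N·r2·b),

which is exactly the two-component gamma mixture `w·Γ(α,λ) + (1−w)·Γ(α+1,λ)`;
the implementation computes the normalization, CDF and mean analytically from
this identity, and the tests re-derive the mean by adaptive quadrature of the
raw density as an independent oracle. The stationary mean is
`<x> = (r2/r1 + b)·f·b/(N·r2 − f·b)`, which reduces to `u/(N·r1)` when
capacity is ample and bursts are small — both limits are tested. Cumulative
mismatches grow as `<y(t)> = eps·f·b·t`.

**Overwhelmed regime** (`N·r2 < f·b`): lesions grow linearly at
`f·b − N·r2` and mismatch production is capped by capacity at `eps·N·r2`.

**Mutations.** Cells divide at rate `phi`; replication is instantaneous and
simultaneous with division. At each division every unrepaired lesion is
bypassed by TLS: a lesion-site error with probability `1−p`, and a collateral
error nearby with probability `eps'` that survives mismatch repair with
probability `1−q`. Outside replication MMR acts symmetrically on the two
strands, so each unresolved mismatch — TLS-derived or repair-derived — fixes
in the followed daughter lineage with probability 1/2. The expected number
of mutations per lesion per division is therefore

    K = [(1−p) + eps'·p·(1−q) + eps'·(1−p)·(1−q)] / 2,

whose three terms are lesion-site error, collateral error next to error-free
bypass, and collateral error next to a lesion-site error (a two-mutation
cluster). The same expression collapses to `(1−p)/2 + eps'(1−q)/2`, the
per-lesion bookkeeping the simulator implements event by event, so the
bracket is validated at the level of individual division outcomes. The
per-time mutation rates are:

| regime | unrepaired-damage channel | repair-error channel |
|---|---|---|
| efficient | `<x>·phi·K` | `eps·f·b/2` |
| overwhelmed | `(f·b − N·r2)·K` | `eps·N·r2/2` |

The repair-error rate is independent of `phi` and of repair rates — the
property that makes the SBS5-like channel "clock-like" and detectable in
post-mitotic cells, and that makes its detection boundary a vertical line in
the (cumulative damage, division rate) phase diagram.

## Simulator

`simulate(mode="full")` is a standard Gillespie algorithm over burst,
engagement, completion and division events. Burst sizes are geometric on
{1,2,…} with mean `b` (lesions are counts; the exponential burst law of the
master equation is its continuum limit), so analytic comparisons use
`b ≥ 20` where the difference is negligible. Lesions persist across
divisions (they are bypassed, not removed); repair-error mismatches are
resolved and reset at each division. `mode="qss"` simulates the reduced
dynamics directly: a continuous jump process with exponential bursts and
deterministic decay at rate `r(x)` between events, inverted in closed form
with the Lambert W function. Each trajectory uses one seeded NumPy
generator; replicate `i` of a batch uses `seed + i`; identical seeds give
bit-identical trajectories.

Counter comparisons subtract the counter values at a burn-in time
(`windowed_rates`), removing the relaxation transient (timescale
`~1/(N·r1)`) that otherwise biases finite-horizon rate estimates.

## Mutation clusters

Within a sample and chromosome arm (length `l`), all unordered pair
distances are computed; `r = 1` (double-base substitutions) and `r = 2` are
excluded, so the support is `r ∈ [3, l−1]`. Chance co-localization follows
the triangular null `P0(r) ∝ (l − r)` (renormalized on the support); genuine
co-occurrence is modelled as a negative binomial `P1` (mean/dispersion
parameterization, truncated to `r ≥ 3`). The mixture
`P = ρ·P1 + (1−ρ)·P0` is fitted by Levenberg–Marquardt least squares on
log CDF vs log r at the observed distances, with ρ logit- and the NB
parameters log-transformed. Pooled fits across arms weight each arm's
triangular null by its pair count. Numerical choices: transforms are
clamped (|logit ρ| ≤ 40, log parameters within ±20/25); solutions driven to
the NB boundaries are non-identified and reported as pure-null fits
(ρ = 0, `converged=False`).

The fitted mixture yields the analytic false discovery rate at threshold r

    FDR(r) = (1−ρ)·F0(r⁻) / [ρ·F1(r⁻) + (1−ρ)·F0(r⁻)],

conservatively set to 1 when the denominator is zero or non-finite. Cluster
calling links pairs with `r < 100` on arms with `FDR(100) ≤ 5%` and takes
connected components; the clustered fraction is reported over mutations on
passing arms. The positional-asymmetry analysis polarizes clusters by a
single C:G→A:T mutation (lesion assumed on the guanine: reference strand for
G→T, complement for C→A), records partner offsets 5'→3' along the lesion
strand, and compares bin counts to a sign-shuffling permutation null;
clusters with several polarizing mutations are excluded.

All-pairs distances from one point set are correlated, so goodness-of-fit
checks against the triangular null use many independent placements of 5
points (correlation inflates the chi-square by <10% there), and the
cross-individual CCDF check uses a DKW band at the conservative effective
sample size `min(n_pairs, n_points)`.

## Repair-rate regression

Per-window NER rates come from `L(t) = L0·e^(−r·t)` fitted as a linear
regression of log counts on time, weighted by `sqrt(count)` (the
inverse-variance weight for Poisson counts on the log scale; unweighted fits
are biased by near-zero late time points). Windows with a nonpositive count
at any time point are dropped and reported — at the default six time points
spanning 24 h and `L0 = 1e4` this removes fast-repair windows whose late
counts hit zero, as in real short-read damage maps.

Window mutation counts vs repair rate are fitted with
`y = A/(r − r*) + B` under `A, B ≥ 0` and `r* < min(r)`, multi-started at
`r* ∈ {0, min(r)/2, min(r) − 2δ}` with ties broken by SSE; `R² = 1 − SSE/SST`
is reported on percentile-binned points (raw windows optional). The per-bin
TLS share is `[A/(r−r*)]/[A/(r−r*)+B]`; its complement is the repair-error
share; the aggregate is count-weighted. Consistency with the kinetic model
is tested by generating window counts from `expected_lesions` over a grid of
per-window repair capacities: they fit the hyperbola with `R² > 0.95` and a
pole at the capacity where repair is exactly overwhelmed.

## Signature statistics

Spectra are 96-vectors in the canonical pyrimidine-strand classes, standard
lexicographic COSMIC row order. The bootstrap ceiling
(`max_expected_similarity`) is the mean cosine between the observed spectrum
and multinomial resamples of its own count `n` (resampling model chosen as
the natural categorical-count bootstrap); the rescaled similarity divides
the observed cosine by this ceiling and can exceed 1 slightly by chance.
Residual spectra subtract all signatures but one, clip negative entries to 0
(count reported; clipping can be disabled) and renormalize. Attribution is
plain non-negative least squares without sparsity selection — a baseline,
not a reimplementation of dedicated attribution tools, whose output tables
can be supplied instead. Opportunity adjustment multiplies each class by
the window/genome ratio of its trinucleotide frequency and renormalizes per
signature; it round-trips exactly.

## Association statistics

All variables are Z-scored before OLS. `semipartial_r2` reports
`R²(full) − R²(without focus)` with the exact t-test p-value of the focus
coefficient; exposures enter untransformed (a log1p option exists but is
off by default). `partial_correlation` residualizes both variables on the
controls and uses the t distribution with `n − 2 − k` degrees of freedom;
a variable fully explained by the controls yields 0 by definition. The
power filter keeps samples with strictly more than 25 focus mutations and
requires at least 20 to remain. Bonferroni flags `p ≤ α/m`.
`donor_resample` draws one sample per individual per replicate
(replicate-indexed RNG streams, 5000 replicates by default) and recomputes
SR²; with one sample per donor the distribution is degenerate. Mixed-effects
significance testing is intentionally out of scope; the OLS path is the
implemented inference route.

## Synthetic data

The generators define the study conditions and record a `SyntheticTruth`
sufficient for closed-loop recovery:

- **Catalog**: sparse Dirichlet (concentration 0.05) damage-specific-like
  columns plus one flat `SBS5like` column (concentration 50, entropy
  > 6 bits).
- **Mutation tables**: uniform background over arms plus planted pairs at
  truncated-NB distances (mean 30, dispersion 1 — short-range collateral
  clusters). The `rho` argument is the fraction of *mutations* in pairs;
  the truth additionally records the realized *pairwise* prevalence
  (planted pairs over all retained pairs), which is what the mixture fit
  estimates and what recovery tests compare against.
- **Time courses**: Poisson counts around exponential decay, six time points
  over 24 h, `L0 = 1e4`, log-uniform rates in [0.2, 2] per day.
- **Window counts**: Poisson around `A/(r − r*) + B`.
- **Cells**: latent SBS4 ~ Normal(150, 100) truncated at 0 (truncation
  fraction reported), SBS1 tracking donor age at 2 mutations/year, and
  SBS5 mean `50 + β·SBS4 + γ·SBS1 + age` with Gaussian noise (sd 30) and
  Poisson observation; defaults β = 1, γ = 0.5 emulate a strong
  damage-coupled regime such as smoker bronchial epithelium. The truth
  records the realized unique-variance share
  `β²·var(m4)²/(var(SBS4)·var(SBS5))`.

What the generators do *not* emulate: real genome composition and
context-dependent mutability, real COSMIC signature vectors, sequencing
sensitivity and calling artifacts, phylogenetic structure beyond a shared
donor intercept, and correlated damage/repair landscapes. Passing recovery
tests therefore demonstrates correctness of the estimators under the model's
own assumptions, not robustness to real-data violations of them.

## Problem sizes and test design

Oracle comparisons use sizes chosen to keep the whole suite a few minutes on
one CPU while leaving the statistical checks well-powered: 20 random
efficient-regime parameter sets × 200 replicate lineages for the
analytic–stochastic comparison (3-SE agreement); a 50,000-time-unit
trajectory thinned at the relaxation timescale for the stationary-law KS
check (< 0.02 with a half-step continuity correction for the integer state);
~1.2×10⁴ pair distances × 20 seeds per prevalence level for cluster
recovery; 10⁶ distances for the triangular-null chi-square; 100 rate bins of
20 windows for the hyperbolic fit; n = 500 cells × 20 seeds for SR²
recovery. Stochastic checks are seeded and deterministic. At n = 500 the
SR² estimator's sampling sd is ~0.02, so planted-value recovery is asserted
on the mean error across seeds rather than per seed.

## Known limitations

- The full-mode simulator is exact but event-driven in pure Python; very
  high event rates (`f·b` ≫ 100 per unit time) are slow. No tau-leaping is
  provided by design.
- The quasi-steady-state mode assumes `r2 ≫ r1`; a warning is emitted when
  `r2 < 10·r1`.
- The mixture fit estimates a *pairwise* prevalence; converting to the
  fraction of clustered mutations depends on the per-sample pair geometry
  and is reported separately by `call_clusters`.
- Cluster calling treats all within-threshold pairs on passing arms as
  clustered; no per-pair posterior is computed.
- `cluster_asymmetry` requires single-polarizing-mutation clusters and
  resolves strand only through the recorded ref/alt alleles.
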