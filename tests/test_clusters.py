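"""Cluster inference: triangular null, mixture fit, FDR gate and asymmetry."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from funnelsig.clusters import (
    ArmSet,
    ClusterFit,
    call_clusters,
    cluster_asymmetry,
    cross_individual_distances,
    fdr_curve,
    fit_mixture,
    null_distance_cdf,
    null_distance_pmf,
    pairwise_distances,
)
from funnelsig.synthetic_data import gen_arms, gen_mutation_table


def make_muts(rows):
    return pd.DataFrame(
        rows, columns=["individual_id", "sample_id", "chrom", "pos", "ref", "alt"]
    )


@pytest.fixture()
def one_arm():
    return ArmSet(pd.DataFrame([dict(chrom="chr1", start=0, end=1000, arm_id="1p")]))


class TestPairwiseDistances:
    def test_single_pair_distance(self, one_arm):
        muts = make_muts([("I0", "S0", "chr1", 10, "C", "A"),
                          ("I0", "S0", "chr1", 25, "C", "T")])
        d = pairwise_distances(muts, one_arm)
        assert d.r.tolist() == [15]

    def test_dbs_and_r2_excluded_by_default(self, one_arm):
        muts = make_muts([("I0", "S0", "chr1", 10, "C", "A"),
                          ("I0", "S0", "chr1", 11, "C", "T"),
                          ("I0", "S0", "chr1", 12, "G", "T")])
        d = pairwise_distances(muts, one_arm)
        assert d.r.tolist() == []  # r=1 and r=2 pairs all dropped

    def test_all_pairs_combinatorics(self, one_arm):
        n = 12
        muts = make_muts([("I0", "S0", "chr1", 10 + 17 * k, "C", "A") for k in range(n)])
        d = pairwise_distances(muts, one_arm, min_r=1)
        assert len(d) == n * (n - 1) // 2

    def test_invariant_to_coordinate_shift(self):
        arms = ArmSet(pd.DataFrame([dict(chrom="c", start=0, end=5000, arm_id="a"),
                                    dict(chrom="c", start=6000, end=11000, arm_id="b")]))
        pos = [100, 350, 900]
        m1 = make_muts([("I", "S", "c", p, "C", "A") for p in pos])
        m2 = make_muts([("I", "S", "c", p + 6000, "C", "A") for p in pos])
        d1 = pairwise_distances(m1, arms)
        d2 = pairwise_distances(m2, arms)
        assert d1.r.tolist() == d2.r.tolist()

    def test_mutation_outside_arms_flagged(self, one_arm):
        muts = make_muts([("I0", "S0", "chr1", 10, "C", "A"),
                          ("I0", "S0", "chr1", 2000, "C", "A"),
                          ("I0", "S0", "chr1", 50, "C", "T")])
        with pytest.warns(UserWarning, match="outside"):
            d = pairwise_distances(muts, one_arm)
        assert d.r.tolist() == [40]


class TestTriangularNull:
    def test_normalization_and_monotonicity(self):
        pmf = null_distance_pmf(500)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(pmf) < 0).all()
        assert pmf[0] > pmf[-1]

    def test_small_arm_rejected(self):
        with pytest.raises(ValueError):
            null_distance_pmf(4, min_r=3)

    def test_cdf_matches_pmf_cumsum(self):
        l = 800
        pmf = null_distance_pmf(l)
        r = np.arange(3, l)
        assert np.allclose(null_distance_cdf(r, l), np.cumsum(pmf), atol=1e-12)

    def test_matches_uniform_placement_simulation(self):
        # independent oracle: many uniform placements of 5 points, all pairs
        rng = np.random.default_rng(7)
        l = 100_000
        pts = rng.integers(1, l + 1, size=(20_000, 5))
        i, j = np.triu_indices(5, k=1)
        r = np.abs(pts[:, i] - pts[:, j]).ravel()
        r = r[r >= 3]
        cdf_grid = null_distance_cdf(np.arange(3, l), l)
        edges = np.searchsorted(cdf_grid, np.linspace(0.1, 0.9, 9)) + 3
        bins = np.concatenate([[3], edges, [l]])
        obs, _ = np.histogram(r, bins=bins)
        exp = np.diff(np.concatenate([[0.0], null_distance_cdf(bins[1:] - 1, l)])) * r.size
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(chi2, df=len(obs) - 1)
        assert p > 0.01


class TestCrossIndividual:
    def test_single_individual_rejected(self, one_arm):
        muts = make_muts([("I0", "S0", "chr1", 10, "C", "A"),
                          ("I0", "S1", "chr1", 20, "C", "A")])
        with pytest.raises(ValueError):
            cross_individual_distances(muts, one_arm)

    def test_one_mutation_each_gives_one_distance(self, one_arm):
        muts = make_muts([("I0", "S0", "chr1", 10, "C", "A"),
                          ("I1", "S1", "chr1", 30, "C", "A")])
        d = cross_individual_distances(muts, one_arm)
        assert d.r.tolist() == [20]

    def test_uniform_placements_within_dkw_band(self):
        rng = np.random.default_rng(11)
        l = 200_000
        arms = ArmSet(pd.DataFrame([dict(chrom="c", start=0, end=l, arm_id="a")]))
        n_pts = 400
        muts = make_muts([
            (f"I{k}", f"S{k}", "c", int(rng.integers(1, l + 1)), "C", "A")
            for k in range(n_pts)
        ])
        d = cross_individual_distances(muts, arms)
        r = np.sort(d.r.to_numpy())
        ecdf = np.arange(1, r.size + 1) / r.size
        model = null_distance_cdf(r, l)
        # pairs sharing points are correlated: conservative band at n_eff = n_points
        eps = np.sqrt(np.log(2.0 / 0.01) / (2.0 * min(r.size, n_pts)))
        assert np.max(np.abs(ecdf - model)) < eps


class TestMixtureFit:
    def test_pure_null_prevalence_near_zero(self):
        arms = gen_arms(4, 10_000_000)
        muts, _ = gen_mutation_table(arms, n_samples=120, n_per_sample=26,
                                     rho=0.0, seed=3)
        d = pairwise_distances(muts, arms)
        assert len(d) > 5000
        fit = fit_mixture(d)
        assert fit.rho < 0.01

    def test_planted_prevalence_recovered(self):
        arms = gen_arms(4, 10_000_000)
        muts, truth = gen_mutation_table(arms, n_samples=150, n_per_sample=26,
                                         rho=0.15, nb_mean=30.0, seed=4)
        d = pairwise_distances(muts, arms)
        fit = fit_mixture(d)
        rho_true = truth.derived["realized_pairwise_prevalence"]
        assert fit.rho == pytest.approx(rho_true, abs=0.02)
        assert fit.nb_mean == pytest.approx(30.0, rel=0.5)

    def test_self_consistency_of_fitted_cdf(self):
        arms = gen_arms(4, 10_000_000)
        muts, _ = gen_mutation_table(arms, n_samples=150, n_per_sample=26,
                                     rho=0.15, seed=5)
        d = pairwise_distances(muts, arms)
        fit = fit_mixture(d)
        assert fit.max_cdf_residual < 0.02

    def test_few_distances_warn(self, one_arm):
        muts = make_muts([("I0", "S0", "chr1", 10 + 29 * k, "C", "A") for k in range(6)])
        d = pairwise_distances(muts, one_arm)
        with pytest.warns(UserWarning, match="unstable"):
            fit_mixture(d)
        with pytest.raises(ValueError):
            fit_mixture(d.iloc[:0])


class TestFdrCurve:
    def base_fit(self, rho):
        return ClusterFit(rho=rho, nb_mean=30.0, nb_dispersion=1.0, min_r=3,
                          arm_lengths={"a": 10_000_000}, arm_weights={"a": 1.0})

    def test_extreme_prevalences(self):
        assert fdr_curve(self.base_fit(1.0), 100) == 0.0
        assert fdr_curve(self.base_fit(0.0), 100) == pytest.approx(1.0)

    def test_monotone_nonincreasing_in_rho(self):
        vals = [fdr_curve(self.base_fit(r), 100) for r in np.linspace(0.0, 1.0, 11)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_threshold_below_support_rejected(self):
        with pytest.raises(ValueError):
            fdr_curve(self.base_fit(0.5), 2)

    def test_mixture_cdf_is_proper(self):
        fit = self.base_fit(0.3)
        r = np.arange(3, 10_000_000, 9999)
        cdf = fit.mixture_cdf(r)
        assert (np.diff(cdf) >= -1e-12).all()
        assert fit.mixture_cdf(10_000_000 - 1) == pytest.approx(1.0, abs=1e-9)


class TestCallClusters:
    def test_no_close_pairs_no_clusters(self, one_arm):
        muts = make_muts([("I0", "S0", "chr1", 100, "C", "A"),
                          ("I0", "S0", "chr1", 500, "C", "A")])
        fit = ClusterFit(rho=0.9, nb_mean=30.0, nb_dispersion=1.0, min_r=3,
                         arm_lengths={"1p": 1000}, arm_weights={"1p": 1.0})
        calls = call_clusters(muts, one_arm, fit)
        assert len(calls.clusters) == 0 and calls.clustered_fraction == 0.0

    def test_transitive_linking(self, one_arm):
        muts = make_muts([("I0", "S0", "chr1", 100, "C", "A"),
                          ("I0", "S0", "chr1", 150, "C", "T"),
                          ("I0", "S0", "chr1", 190, "G", "T")])
        fit = ClusterFit(rho=0.9, nb_mean=30.0, nb_dispersion=1.0, min_r=3,
                         arm_lengths={"1p": 1000}, arm_weights={"1p": 1.0})
        calls = call_clusters(muts, one_arm, fit)
        assert len(calls.clusters) == 1
        assert calls.clusters.iloc[0]["size"] == 3
        assert calls.clustered_fraction == 1.0

    def test_planted_fraction_recovered(self):
        arms = gen_arms(4, 10_000_000)
        muts, truth = gen_mutation_table(arms, n_samples=150, n_per_sample=26,
                                         rho=0.15, seed=6)
        d = pairwise_distances(muts, arms)
        fit = fit_mixture(d)
        calls = call_clusters(muts, arms, fit)
        true_frac = truth.derived["clustered_mutation_fraction"]
        assert calls.clustered_fraction == pytest.approx(true_frac, rel=0.2)

    def test_high_fdr_arms_excluded(self):
        arms = gen_arms(4, 10_000_000)
        muts, _ = gen_mutation_table(arms, n_samples=120, n_per_sample=26,
                                     rho=0.0, seed=7)
        d = pairwise_distances(muts, arms)
        fit = fit_mixture(d)
        calls = call_clusters(muts, arms, fit)
        # with no genuine clustering every arm fails the 5% gate: no calls
        assert set(calls.excluded_arms) == set(muts.arm_id_true.unique())
        assert len(calls.clusters) == 0


class TestClusterAsymmetry:
    def _calls(self, muts, arms):
        fit = ClusterFit(rho=0.9, nb_mean=40.0, nb_dispersion=1.0, min_r=3,
                         arm_lengths={"1p": 10_000_000},
                         arm_weights={"1p": 1.0})
        return call_clusters(muts, arms, fit)

    def _paired_muts(self, offsets, polar_ref="G"):
        rows = []
        polar_alt = "T" if polar_ref == "G" else "A"
        for k, off in enumerate(offsets):
            p0 = 1000 + 500 * k
            rows.append((f"I", f"S", "chr1", p0, polar_ref, polar_alt))
            rows.append((f"I", f"S", "chr1", p0 + off, "C", "T"))
        return make_muts(rows)

    @pytest.fixture()
    def big_arm(self):
        return ArmSet(pd.DataFrame([dict(chrom="chr1", start=0, end=10_000_000,
                                         arm_id="1p")]))

    def test_symmetric_offsets_unenriched(self, big_arm):
        rng = np.random.default_rng(8)
        offsets = rng.choice([-1, 1], 200) * rng.integers(5, 90, 200)
        muts = self._paired_muts(offsets)
        res = cluster_asymmetry(muts, self._calls(muts, big_arm), seed=1)
        ok = (res["observed"] >= res.null_lo) & (res["observed"] <= res.null_hi)
        assert ok.mean() >= 0.75

    def test_planted_downstream_enrichment(self, big_arm):
        muts = self._paired_muts([20] * 100 + [35] * 100)
        res = cluster_asymmetry(muts, self._calls(muts, big_arm), seed=1)
        down = res.loc[res.bin_left >= 0, "observed"].sum()
        up = res.loc[res.bin_right <= 0, "observed"].sum()
        assert down > 0 and up == 0

    def test_strand_flip_mirrors_profile(self, big_arm):
        offsets = [15] * 60 + [-40] * 30
        m_g = self._paired_muts(offsets, polar_ref="G")
        m_c = self._paired_muts(offsets, polar_ref="C")  # lesion on other strand
        r_g = cluster_asymmetry(m_g, self._calls(m_g, big_arm), seed=2)
        r_c = cluster_asymmetry(m_c, self._calls(m_c, big_arm), seed=2)
        assert r_g["observed"].tolist() == r_c["observed"].tolist()[::-1]

    def test_no_polarizing_mutations_warns(self, big_arm):
        muts = make_muts([("I", "S", "chr1", 1000, "C", "T"),
                          ("I", "S", "chr1", 1020, "C", "T")])
        with pytest.warns(UserWarning, match="polarizing"):
            res = cluster_asymmetry(muts, self._calls(muts, big_arm))
        assert res.empty
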