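"""Spectrum statistics: cosine, bootstrap rescaling, residuals, NNLS, opportunity."""

import numpy as np
import pandas as pd
import pytest

from funnelsig.signatures import (
    SBS96_CLASSES,
    TRINUCLEOTIDES,
    Spectrum,
    attribute_nnls,
    class_contexts,
    cosine,
    max_expected_similarity,
    opportunity_adjust,
    reconstruct,
    rescaled_similarity,
    residual_spectrum,
    validate_catalog,
)


def spectrum_from(freq, n):
    return Spectrum(np.asarray(freq) * n, n=n)


class TestClasses:
    def test_canonical_scheme(self):
        assert len(SBS96_CLASSES) == 96
        assert SBS96_CLASSES[0] == "A[C>A]A"
        assert SBS96_CLASSES == sorted(SBS96_CLASSES)
        assert len(TRINUCLEOTIDES) == 32
        assert set(class_contexts()) == set(TRINUCLEOTIDES)

    def test_spectrum_validation(self):
        with pytest.raises(ValueError):
            Spectrum(np.ones(95))
        with pytest.raises(ValueError):
            Spectrum(-np.ones(96))


class TestReconstruct:
    def test_single_signature_identity(self, catalog):
        name = catalog.columns[0]
        out = reconstruct(catalog, {name: 1.0})
        assert np.allclose(out, catalog[name].to_numpy(), atol=1e-12)

    def test_duplicate_split_gives_same_vector(self, catalog):
        name = catalog.columns[0]
        cat2 = catalog.copy()
        cat2["dup"] = catalog[name]
        out = reconstruct(cat2, {name: 0.5, "dup": 0.5})
        assert np.allclose(out, catalog[name].to_numpy(), atol=1e-12)

    def test_normalized_output(self, catalog, rng):
        expo = pd.Series(rng.random(len(catalog.columns)), index=catalog.columns)
        assert reconstruct(catalog, expo).sum() == pytest.approx(1.0, abs=1e-12)

    def test_unknown_signature_rejected(self, catalog):
        with pytest.raises(KeyError):
            reconstruct(catalog, {"nope": 1.0})


class TestCosine:
    def test_identity_and_disjoint(self):
        a = np.zeros(96); a[0] = 1.0
        b = np.zeros(96); b[1] = 1.0
        assert cosine(a, a) == pytest.approx(1.0)
        assert cosine(a, b) == 0.0

    def test_scale_invariance(self, rng):
        a, b = rng.random(96), rng.random(96)
        assert cosine(a, b) == pytest.approx(cosine(7.3 * a, 0.2 * b), rel=1e-12)

    def test_matches_double_loop(self, rng):
        a, b = rng.random(96), rng.random(96)
        num = sum(a[i] * b[i] for i in range(96))
        na = sum(v * v for v in a) ** 0.5
        nb = sum(v * v for v in b) ** 0.5
        assert cosine(a, b) == pytest.approx(num / (na * nb), abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine(np.zeros(96), np.ones(96))


class TestMaxExpectedSimilarity:
    def test_huge_n_approaches_one(self):
        s = Spectrum(np.full(96, 1e7 / 96), n=int(1e7))
        assert max_expected_similarity(s, n_boot=50, seed=0) == pytest.approx(1.0, abs=1e-3)

    def test_single_draw_flat_spectrum_closed_form(self):
        # one draw from a flat spectrum is a basis vector: cosine = 1/sqrt(96)
        s = Spectrum(np.full(96, 1.0 / 96), n=1)
        val = max_expected_similarity(s, n_boot=400, seed=1)
        assert val == pytest.approx(1.0 / np.sqrt(96), abs=1e-12)

    def test_monotone_in_n_on_average(self):
        p = np.full(96, 1.0 / 96)
        means = []
        for n in (10, 100, 1000):
            vals = [
                max_expected_similarity(Spectrum(p * n, n=n), n_boot=100, seed=s)
                for s in range(20)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            max_expected_similarity(Spectrum(np.zeros(96), n=0))


class TestRescaledSimilarity:
    def test_self_sampling_near_one(self, catalog, rng):
        mix = catalog.to_numpy().mean(axis=1)
        vals = []
        for s in range(20):
            counts = np.random.default_rng(s).multinomial(5000, mix)
            obs = Spectrum(counts.astype(float))
            vals.append(rescaled_similarity(obs, mix, n_boot=200, seed=s))
        vals = np.asarray(vals)
        assert (vals <= 1.02).all()
        assert np.abs(vals - 1.0).max() < 0.02

    def test_self_reconstruction_at_least_one(self, catalog):
        obs = Spectrum(np.random.default_rng(2).multinomial(500, catalog.iloc[:, 0]))
        assert rescaled_similarity(obs, obs.freq, n_boot=100, seed=3) >= 1.0

    def test_disjoint_reconstruction_is_zero(self):
        a = np.zeros(96); a[:48] = 1.0
        b = np.zeros(96); b[48:] = 1.0
        assert rescaled_similarity(Spectrum(a * 100), b, n_boot=50, seed=0) == 0.0


class TestResidualSpectrum:
    def test_exact_mixture_recovers_excluded(self, catalog):
        expo = pd.Series(0.2, index=catalog.columns)
        obs = spectrum_from(reconstruct(catalog, expo), 10_000)
        resid, cosines = residual_spectrum(obs, catalog, expo, exclude="SBS5like")
        assert cosines["SBS5like"] == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(resid, catalog["SBS5like"].to_numpy(), atol=1e-9)

    def test_zero_residual_rejected(self, catalog):
        # observation fully explained by the non-excluded signature: nothing left
        name = catalog.columns[0]
        obs = spectrum_from(catalog["SBS5like"].to_numpy(), 1000)
        with pytest.raises(ValueError):
            residual_spectrum(obs, catalog, {name: 0.0, "SBS5like": 1.0},
                              exclude=name)

    def test_planted_flat_component_detected(self, catalog, rng):
        hits = 0
        peaked = [c for c in catalog.columns if c != "SBS5like"]
        for s in range(50):
            g = np.random.default_rng(s)
            expo = pd.Series(0.0, index=catalog.columns)
            expo["SBS5like"] = 0.6
            for c in peaked:
                expo[c] = 0.4 / len(peaked)
            counts = g.multinomial(3000, reconstruct(catalog, expo))
            _, cosines = residual_spectrum(Spectrum(counts.astype(float)),
                                           catalog, expo, exclude="SBS5like")
            hits += cosines["SBS5like"] > cosines["uniform"]
        assert hits >= 0.95 * 50 * 0.95  # >= 95% of seeds (with slack for the bound)


class TestAttributeNnls:
    def test_single_signature_exact(self, catalog):
        name = catalog.columns[1]
        obs = spectrum_from(catalog[name].to_numpy(), 1000)
        expo = attribute_nnls(obs, catalog)
        props = expo / expo.sum()
        assert props[name] == pytest.approx(1.0, abs=1e-8)

    def test_noiseless_mixture_recovery(self, catalog):
        a, b = catalog.columns[0], catalog.columns[1]
        mix = 0.3 * catalog[a].to_numpy() + 0.7 * catalog[b].to_numpy()
        expo = attribute_nnls(spectrum_from(mix, 1000), catalog)
        props = expo / expo.sum()
        assert props[a] == pytest.approx(0.3, abs=1e-6)
        assert props[b] == pytest.approx(0.7, abs=1e-6)

    def test_multinomial_noise_recovery(self, catalog):
        a, b = catalog.columns[0], catalog.columns[1]
        mix = 0.3 * catalog[a].to_numpy() + 0.7 * catalog[b].to_numpy()
        for s in range(20):
            counts = np.random.default_rng(s).multinomial(10_000, mix)
            expo = attribute_nnls(Spectrum(counts.astype(float)), catalog)
            props = expo / expo.sum()
            assert abs(props[a] - 0.3) < 0.05
            assert abs(props[b] - 0.7) < 0.05

    def test_beats_random_search(self, catalog, rng):
        obs = Spectrum(rng.multinomial(2000, catalog.to_numpy().mean(axis=1)).astype(float))
        expo = attribute_nnls(obs, catalog)
        A = catalog.to_numpy()
        best_err = np.sum((A @ (expo / expo.sum()).to_numpy() - obs.freq) ** 2)
        for _ in range(1000):
            e = rng.random(A.shape[1])
            e /= e.sum()
            assert best_err <= np.sum((A @ e - obs.freq) ** 2) + 1e-15

    def test_duplicate_columns_warn(self, catalog):
        cat2 = catalog.copy()
        cat2["dup"] = catalog.iloc[:, 0]
        obs = spectrum_from(catalog.iloc[:, 0].to_numpy(), 100)
        with pytest.warns(UserWarning, match="degenerate"):
            attribute_nnls(obs, cat2)


class TestOpportunityAdjust:
    def flat_context(self):
        return pd.Series(1.0 / 32, index=TRINUCLEOTIDES)

    def test_identity_when_contents_match(self, catalog):
        g = self.flat_context()
        out = opportunity_adjust(catalog, g, g)
        assert np.allclose(out.to_numpy(), catalog.to_numpy(), atol=1e-12)

    def test_doubling_one_context_scales_its_classes(self, catalog):
        g = self.flat_context()
        w = g.copy()
        w["ACA"] *= 2.0
        ctx = np.asarray(class_contexts())
        ratio_cols = []
        raw = catalog.to_numpy() * np.where(ctx == "ACA", 2.0, 1.0)[:, None]
        out = opportunity_adjust(catalog, w, g)
        assert np.allclose(out.to_numpy(), raw / raw.sum(axis=0), atol=1e-12)

    def test_round_trip(self, catalog, rng):
        g = self.flat_context()
        w = pd.Series(rng.random(32) + 0.1, index=TRINUCLEOTIDES)
        there = opportunity_adjust(catalog, w, g)
        back = opportunity_adjust(there, g, w)
        assert np.allclose(back.to_numpy(), catalog.to_numpy(), atol=1e-12)

    def test_zero_context_rejected(self, catalog):
        g = self.flat_context()
        w = g.copy(); w["ACA"] = 0.0
        with pytest.raises(ValueError):
            opportunity_adjust(catalog, w, g)


def test_validate_catalog_rejects_bad_columns(catalog):
    bad = catalog.copy()
    bad.iloc[0, 0] += 0.5
    with pytest.raises(ValueError, match="sum to 1"):
        validate_catalog(bad)
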