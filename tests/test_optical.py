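"""Vegetation indices, statistics, harmonic fitting, phenology, feature block."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import earlycrop as ec
from earlycrop.compositing import WINDOW_CENTERS
from earlycrop.errors import DegeneratePhenologyError, UndefinedValueError
from earlycrop.optical import (OPTICAL_PARAMS, build_optical_features,
                               harmonic_fit_matrix, optical_parameter_matrices,
                               peak_composites, phenology_matrix, stat_matrix)
from conftest import percentile_oracle

reflectance = st.floats(0.01, 1.0)


class TestIndices:
    @pytest.mark.parametrize("nir,red,blue,expected", [
        (0.4, 0.1, 0.05, 0.75 / 1.625),   # hand arithmetic
        (0.3, 0.3, 0.1, 0.0),             # zero numerator
        (0.0, 0.0, 0.0, 0.0),             # denominator 1
    ])
    def test_evi(self, nir, red, blue, expected):
        assert ec.evi(nir, red, blue) == pytest.approx(expected)

    def test_normalized_differences(self):
        assert ec.lswi(0.4, 0.2) == pytest.approx(0.2 / 0.6)
        assert ec.rendvi(0.25, 0.25) == 0.0
        assert ec.ndsvi(0.3, 0.1) == pytest.approx(0.5)

    @pytest.mark.parametrize("red,re1,re2,re3,expected", [
        (0.1, 0.1, 0.3, 0.1, 705.0),       # zero interpolation fraction
        (0.04, 0.1, 0.3, 0.36, 722.5),     # half-step red edge
        (0.1, 0.1, 0.3, 0.5, 740.0),       # full-step red edge
    ])
    def test_repi(self, red, re1, re2, re3, expected):
        assert ec.repi(red, re1, re2, re3) == pytest.approx(expected)

    def test_zero_denominators_raise(self):
        with pytest.raises(UndefinedValueError):
            ec.lswi(0.0, 0.0)
        with pytest.raises(UndefinedValueError):
            ec.repi(0.1, 0.2, 0.2, 0.3)
        with pytest.raises(UndefinedValueError):
            ec.evi(0.1, 0.1, (0.1 + 6 * 0.1 + 1) / 7.5)

    @settings(max_examples=200, deadline=None)
    @given(a=reflectance, b=reflectance)
    def test_normalized_differences_bounded(self, a, b):
        """Any normalized difference of positive reflectances lies in [-1, 1]."""
        for val in (ec.lswi(a, b), ec.rendvi(a, b), ec.ndsvi(a, b)):
            assert -1.0 <= val <= 1.0


class TestStatDescriptors:
    def test_interpolated_percentiles_and_population_std(self):
        stats = ec.stat_descriptors(np.array([1, 2, 3, 4, 5], float))
        assert stats["p15"] == pytest.approx(1.6)
        assert stats["p90"] == pytest.approx(4.6)
        assert stats["stdDev"] == pytest.approx(np.sqrt(2.0))

    def test_constant_series(self):
        stats = ec.stat_descriptors(np.full(16, 0.7))
        assert all(stats[s] == pytest.approx(0.7)
                   for s in ("min", "max", "p15", "p50", "p90"))
        assert stats["stdDev"] == 0.0

    def test_singleton_series(self):
        stats = ec.stat_descriptors(np.array([0.3]))
        assert stats["min"] == stats["max"] == stats["p50"] == 0.3
        assert stats["stdDev"] == 0.0

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ec.stat_descriptors(np.array([]))

    def test_against_independent_oracle(self):
        """100 random series vs a hand-rolled order-statistic interpolator."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            series = rng.random(rng.integers(2, 30))
            stats = ec.stat_descriptors(series)
            for q in (15, 50, 90):
                assert stats[f"p{q}"] == pytest.approx(
                    percentile_oracle(series, q), abs=1e-12)
            assert stats["stdDev"] == pytest.approx(
                np.sqrt(np.mean((series - series.mean()) ** 2)), abs=1e-12)


class TestHarmonicFit:
    DOYS = WINDOW_CENTERS

    def test_constant_series(self):
        fit = ec.harmonic_fit(np.full(16, 0.42), self.DOYS, order=2)
        assert fit.a0 == pytest.approx(0.42, abs=1e-9)
        assert np.allclose(fit.a, 0, atol=1e-9)
        assert np.allclose(fit.b, 0, atol=1e-9)

    def test_recovers_planted_harmonic(self):
        t = self.DOYS / 365.0
        series = 0.3 + 0.2 * np.cos(2 * np.pi * 1.5 * t) + 0.1 * np.sin(2 * np.pi * 1.5 * t)
        fit = ec.harmonic_fit(series, self.DOYS, order=1)
        assert fit.a0 == pytest.approx(0.3, abs=1e-6)
        assert fit.a[0] == pytest.approx(0.2, abs=1e-6)
        assert fit.b[0] == pytest.approx(0.1, abs=1e-6)
        assert fit.amplitude == pytest.approx(0.223607, abs=1e-6)
        assert fit.phase == pytest.approx(0.463648, abs=1e-6)

    def test_higher_order_terms_vanish_for_pure_first_harmonic(self):
        t = self.DOYS / 365.0
        series = 0.3 + 0.2 * np.cos(2 * np.pi * 1.5 * t) + 0.1 * np.sin(2 * np.pi * 1.5 * t)
        fit = ec.harmonic_fit(series, self.DOYS, order=2)
        assert abs(fit.a[1]) < 1e-6 and abs(fit.b[1]) < 1e-6

    def test_matches_normal_equations_oracle(self):
        """100 random series: lstsq solution equals the brute-force
        normal-equations solve to 1e-9."""
        from earlycrop.optical import _harmonic_design

        rng = np.random.default_rng(23)
        for _ in range(100):
            series = rng.random(16)
            fit = ec.harmonic_fit(series, self.DOYS, order=2)
            X = _harmonic_design(self.DOYS, 2, 1.5)
            beta = np.linalg.solve(X.T @ X, X.T @ series)
            got = np.concatenate(([fit.a0], np.ravel(np.column_stack([fit.a, fit.b]))))
            assert np.allclose(got, beta, atol=1e-9)

    def test_residual_nonincreasing_in_order(self):
        rng = np.random.default_rng(4)
        series = rng.random(16)
        prev = np.inf
        for order in (1, 2, 3):
            fit = ec.harmonic_fit(series, self.DOYS, order=order)
            resid = np.sum((fit.predict(self.DOYS) - series) ** 2)
            assert resid <= prev + 1e-12
            prev = resid

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            ec.harmonic_fit(np.ones(4), self.DOYS[:4], order=2)


class TestPhenology:
    def test_hand_worked_example(self):
        doys = np.array([130, 140, 150, 160, 170, 180], float)
        evi = np.array([0.1, 0.2, 0.5, 0.6, 0.4, 0.1])
        ph = ec.phenology(evi, doys)
        assert ph.sos == 150 and ph.eos == 170 and ph.los == 20
        assert ph.evi_at_sos == pytest.approx(0.5)
        assert ph.evi_at_eos == pytest.approx(0.4)
        assert ph.cum_evi == pytest.approx(1.5)

    def test_strictly_increasing_series_ends_at_last_doy(self):
        doys = np.arange(130, 190, 10, dtype=float)
        ph = ec.phenology(np.linspace(0.1, 0.6, 6), doys)
        assert ph.eos == doys[-1]

    def test_constant_series_degenerate(self):
        with pytest.raises(DegeneratePhenologyError):
            ec.phenology(np.full(8, 0.4), np.arange(8, dtype=float))

    def test_plateau_policy_collapses_to_max_window(self):
        res = phenology_matrix(np.array([[0.4, 0.4, 0.1]]), np.array([125., 135., 145.]),
                               degenerate="plateau")
        assert res["SOS"][0] == 125 and res["EOS"][0] == 135

    def test_recovery_on_noise_free_double_logistic(self):
        """SOS/EOS land within one 10-day window of the dense curve's own
        median-threshold crossings."""
        from scipy.special import expit

        dense = np.arange(121.0, 281.0, 0.1)
        def curve(t):
            return 0.1 + 0.5 * expit(0.12 * (t - 175)) * expit(-0.12 * (t - 250))

        sampled = curve(WINDOW_CENTERS)
        ph = ec.phenology(sampled, WINDOW_CENTERS)
        thr = np.median(sampled)
        above = curve(dense) > thr
        sos_true = dense[np.argmax(above)]
        eos_true = dense[len(above) - 1 - np.argmax(above[::-1])]
        assert abs(ph.sos - sos_true) <= 10
        assert abs(ph.eos - eos_true) <= 10


class TestPeakComposites:
    def _params(self, evi_rows, n=3):
        rng = np.random.default_rng(0)
        params = {name: rng.random((evi_rows.shape[0], evi_rows.shape[1]))
                  for name in OPTICAL_PARAMS}
        params["EVI"] = evi_rows
        return params

    def test_unique_maximum(self):
        evi = np.zeros((1, 16))
        evi[0, 9] = 1.0
        params = self._params(evi)
        peaks = peak_composites(params)
        assert peaks["Red_EVI"][0] == params["Red"][0, 9]

    def test_tie_breaks_to_earliest_window(self):
        evi = np.zeros((1, 16))
        evi[0, [8, 10]] = 1.0
        params = self._params(evi)
        assert peak_composites(params)["Blue_EVI"][0] == params["Blue"][0, 8]

    def test_constant_series_picks_first_window(self):
        params = self._params(np.full((1, 16), 0.5))
        assert peak_composites(params)["SWIR1_EVI"][0] == params["SWIR1"][0, 0]


class TestFeatureBlock:
    def test_exactly_94_named_features(self, noisefree_scene):
        from earlycrop import pipeline

        bundle = pipeline.composite_scene(noisefree_scene)
        filled = {k: np.where(np.isnan(v), 0, v) for k, v in bundle.optical.items()}
        feats = build_optical_features(filled)
        assert feats.shape[1] == 94
        assert not feats.isna().any().any()
        extended = build_optical_features(filled, include_pheno_evi=True)
        assert extended.shape[1] == 96

    def test_identical_series_identical_features(self):
        rng = np.random.default_rng(8)
        bands = {b: np.tile(rng.uniform(0.05, 0.5, 16), (2, 1))
                 for b in ("blue", "green", "red", "re1", "re2", "re3",
                           "nir", "swir1", "swir2")}
        feats = build_optical_features(bands)
        assert feats.iloc[0].equals(feats.iloc[1])

    def test_soybean_drier_than_rice_in_lswi(self, noisefree_scene):
        """The flooding signature drives median LSWI: rice > soybean."""
        from earlycrop import pipeline

        bundle = pipeline.composite_scene(noisefree_scene)
        feats = build_optical_features(bundle.optical)
        labels = noisefree_scene.labels
        soy = feats.loc[labels == "soybean", "LSWI_p50"].mean()
        rice = feats.loc[labels == "rice", "LSWI_p50"].mean()
        assert soy < rice
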