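"""Feature registry contracts, band decomposition and feature values."""

import numpy as np
import pytest
from scipy import signal as sps

from neuroads import (
    DEFAULT_BANDS,
    build_feature_matrix,
    compute_base_features,
    compute_ratio_features,
    decompose_bands,
    default_registry,
)
from neuroads.features import BASE_FEATURES, RATIO_FEATURES, FeatureRegistry
from neuroads.types import EPOC_X_CHANNELS, ParameterError, StimulusEpoch

FS = 128.0


def make_epoch(data, **kw):
    defaults = dict(subject_id="S01", ad_id="water_comic", topic="water",
                    style="comic", sampling_rate=FS, rating=7)
    defaults.update(kw)
    return StimulusEpoch(data=data, **defaults)


class TestRegistry:
    def test_count_contracts(self):
        reg = default_registry()
        assert len(reg.base_features) == 41
        assert len(RATIO_FEATURES) == 183
        assert reg.per_channel_count == 470
        assert len(reg.columns(EPOC_X_CHANNELS)) == 6580

    def test_statistical_and_spectral_split(self):
        from neuroads.features import SPECTRAL_FEATURES, STATISTICAL_FEATURES
        assert len(STATISTICAL_FEATURES) == 30
        assert len(SPECTRAL_FEATURES) == 11

    def test_band_definitions(self):
        edges = [(b.name, b.low, b.high) for b in DEFAULT_BANDS]
        assert edges == [("delta", 0.0, 4.0), ("theta", 4.0, 8.0),
                         ("alpha", 8.0, 12.0), ("beta_1", 12.0, 20.0),
                         ("beta_2", 20.0, 32.0), ("gamma", 32.0, 64.0)]

    def test_wrong_base_count_rejected(self):
        with pytest.raises(ParameterError):
            FeatureRegistry(DEFAULT_BANDS, BASE_FEATURES[:40], RATIO_FEATURES)

    def test_json_roundtrip(self, tmp_path):
        reg = default_registry()
        path = tmp_path / "registry.json"
        reg.to_json(path)
        assert FeatureRegistry.from_json(path) == reg

    def test_column_name_grammar(self):
        reg = default_registry()
        cols = reg.columns(EPOC_X_CHANNELS)
        parsed = [FeatureRegistry.parse_column(c) for c in cols]
        channels = {p[0] for p in parsed}
        signals = {p[1] for p in parsed}
        assert channels == set(EPOC_X_CHANNELS)
        assert signals == {"broadband", "delta", "theta", "alpha",
                           "beta_1", "beta_2", "gamma", "crossband"}
        base = [p for p in parsed if p[1] != "crossband"]
        assert len(base) == 14 * 7 * 41


class TestDecomposeBands:
    def test_single_tone_lands_in_alpha(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        with pytest.warns(UserWarning, match="gamma"):
            bands = decompose_bands(x, FS)
        total = sum(v.var() for v in bands.values())
        assert bands["alpha"].var() / total >= 0.90

    def test_two_tone_split(self):
        t = np.arange(int(30 * FS)) / FS
        x = (np.sin(2 * np.pi * 5.0 * t) + np.sin(2 * np.pi * 25.0 * t))[None, :]
        bands = decompose_bands(x, FS)
        assert bands["theta"].var() == pytest.approx(0.5, rel=0.10)
        assert bands["beta_2"].var() == pytest.approx(0.5, rel=0.10)

    def test_band_order_fixed(self):
        x = np.random.default_rng(0).standard_normal((2, 1024))
        bands = decompose_bands(x, FS)
        assert list(bands) == ["delta", "theta", "alpha", "beta_1", "beta_2", "gamma"]

    def test_band_above_nyquist_is_error(self):
        from neuroads.features import BandDefinition
        x = np.zeros((1, 1024))
        with pytest.raises(ParameterError):
            decompose_bands(x, 64.0, (BandDefinition("hf", 40.0, 60.0),))


class TestBaseFeatures:
    def test_zero_signal_conventions(self):
        vals = compute_base_features(np.zeros((1, 1024)), FS)[0]
        named = dict(zip(BASE_FEATURES, vals))
        for key in ("mean", "std", "rms", "peak_to_peak", "hist_entropy",
                    "crest_factor", "total_power", "spectral_entropy"):
            assert named[key] == 0.0

    def test_white_noise_sample_statistics(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((1, 8192))
        vals = dict(zip(BASE_FEATURES, compute_base_features(x, FS)[0]))
        assert vals["variance"] == pytest.approx(1.0, rel=0.05)
        assert abs(vals["skewness"]) < 0.1

    def test_matches_direct_formulas(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500) * 3 + 1
        vals = dict(zip(BASE_FEATURES, compute_base_features(x[None, :], FS)[0]))
        assert vals["mean"] == pytest.approx(x.mean())
        assert vals["std"] == pytest.approx(x.std())
        assert vals["rms"] == pytest.approx(np.sqrt((x ** 2).mean()))
        assert vals["iqr"] == pytest.approx(np.percentile(x, 75) - np.percentile(x, 25))
        assert vals["energy"] == pytest.approx((x ** 2).sum())
        assert vals["hjorth_mobility"] == pytest.approx(
            np.sqrt(np.diff(x).var() / x.var()))

    def test_too_short_signal_is_error(self):
        with pytest.raises(ParameterError, match="64"):
            compute_base_features(np.zeros((1, 32)), FS)

    def test_pure_tone_spectral_peak(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        vals = dict(zip(BASE_FEATURES, compute_base_features(x, FS)[0]))
        assert vals["peak_freq"] == pytest.approx(10.0, abs=0.5)
        assert vals["median_freq"] == pytest.approx(10.0, abs=0.5)


class TestRatioFeatures:
    @staticmethod
    def banded_noise(variances, seconds=30.0, seed=0):
        """Independent band-limited components with exact planted variances."""
        rng = np.random.default_rng(seed)
        n = int(seconds * FS)
        out = {}
        for b, v in zip(DEFAULT_BANDS, variances):
            lo = max(b.low, 0.3)
            hi = min(b.high, 0.99 * FS / 2)
            sos = sps.butter(4, [lo, hi], btype="bandpass", fs=FS, output="sos")
            x = sps.sosfiltfilt(sos, rng.standard_normal(n))
            x = (x - x.mean()) / x.std() * np.sqrt(v)
            out[b.name] = x[None, :]
        return out

    def test_per_channel_total_is_470(self):
        assert 41 * 7 + len(RATIO_FEATURES) == 470

    def test_pure_alpha_tone_limits(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        with pytest.warns(UserWarning, match="gamma"):
            bands = decompose_bands(x, FS)
        vals = dict(zip(RATIO_FEATURES, compute_ratio_features(bands)[0]))
        assert vals["rel_power_alpha"] > 0.95
        for other in ("delta", "theta", "beta_1", "beta_2", "gamma"):
            assert vals[f"rel_power_{other}"] < 0.05
        assert vals["abs_ratio_alpha_over_beta_1"] > 100

    def test_planted_variances_recovered(self):
        bands = self.banded_noise([4.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        vals = dict(zip(RATIO_FEATURES, compute_ratio_features(bands)[0]))
        assert vals["rel_power_delta"] == pytest.approx(4 / 9, rel=0.10)
        assert vals["abs_ratio_delta_over_theta"] == pytest.approx(4.0, rel=0.10)

    def test_engagement_ratios_present(self):
        assert "cmp_beta_over_alpha_abs" in RATIO_FEATURES
        assert "cmp_beta_over_alpha_theta_abs" in RATIO_FEATURES

    def test_zero_band_power_is_error(self):
        bands = {b.name: np.zeros((1, 1024)) for b in DEFAULT_BANDS}
        with pytest.raises(ParameterError):
            compute_ratio_features(bands)


class TestFeatureMatrix:
    def test_matrix_shape_and_determinism(self, small_clean_epochs):
        fm = build_feature_matrix(small_clean_epochs[:4])
        assert fm.shape == (4, 6580)
        assert not fm.isna().any().any()
        twice = build_feature_matrix([small_clean_epochs[0], small_clean_epochs[0]])
        np.testing.assert_array_equal(twice.iloc[0].to_numpy(), twice.iloc[1].to_numpy())

    def test_missing_channel_is_error(self, small_clean_epochs):
        ep = small_clean_epochs[0]
        other = StimulusEpoch(
            subject_id=ep.subject_id, ad_id=ep.ad_id, topic=ep.topic, style=ep.style,
            data=ep.data[:13], sampling_rate=ep.sampling_rate,
            channel_labels=ep.channel_labels[:13], rating=ep.rating)
        with pytest.raises(ParameterError, match="channel"):
            build_feature_matrix([ep, other])

    def test_scale_invariance_of_relative_features(self, small_clean_epochs):
        """Scaling a signal by c scales power features by c^2 and leaves
        relative powers and all power ratios unchanged."""
        ep = small_clean_epochs[0]
        scaled = StimulusEpoch(
            subject_id=ep.subject_id, ad_id=ep.ad_id, topic=ep.topic, style=ep.style,
            data=ep.data * 3.0, sampling_rate=ep.sampling_rate,
            channel_labels=ep.channel_labels, rating=ep.rating)
        fm = build_feature_matrix([ep, scaled])
        a, b = fm.iloc[0], fm.iloc[1]
        for ch in ("AF3", "O2"):
            assert b[f"{ch}__broadband__variance"] == pytest.approx(
                9.0 * a[f"{ch}__broadband__variance"], rel=1e-6)
            for col in (f"{ch}__crossband__rel_power_alpha",
                        f"{ch}__crossband__abs_ratio_alpha_over_theta",
                        f"{ch}__crossband__cmp_beta_over_alpha_abs"):
                assert b[col] == pytest.approx(a[col], rel=1e-6)

    def test_band_power_consistent_with_welch_integral(self):
        """Absolute band power via filtered variance agrees with integrating
        the Welch PSD over the band on stationary noise."""
        rng = np.random.default_rng(9)
        x = rng.standard_normal((1, int(60 * FS)))
        bands = decompose_bands(x, FS)
        f, p = sps.welch(x[0], fs=FS, nperseg=int(4 * FS))
        for b in DEFAULT_BANDS[1:-1]:  # interior bands, clean edges
            var_power = bands[b.name].var()
            mask = (f >= b.low) & (f < b.high)
            welch_power = np.trapezoid(p[mask], f[mask])
            assert var_power == pytest.approx(welch_power, rel=0.10)
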