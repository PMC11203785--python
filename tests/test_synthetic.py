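"""Tests for the spectrum simulator: analytic expectation, Poisson draws,
and ground-truth construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import palsfv
from palsfv import (
    AcquisitionSettings,
    GroundTruth,
    expected_spectrum,
    simulate_spectrum,
    truth_from_sample,
)


class TestExpectedSpectrum:
    def test_pure_exponential_channel_ratio(self):
        """Without IRF or background a single component is a pure
        exponential: counts at t and t + dt are in the ratio exp(-dt/tau),
        giving exactly 1/e one lifetime apart."""
        # 6.1 ps channels make tau = 1.83 ns an exact 300 channels
        s = AcquisitionSettings(channel_width=6.1, irf_fwhm=0.0)
        truth = GroundTruth(components=((1.83, 1.0),))
        mu = expected_spectrum(s, truth)
        j = 2000
        ratio = mu[j + 300] / mu[j]
        assert ratio == pytest.approx(np.exp(-1.0), rel=1e-9)

    @pytest.mark.parametrize(
        "settings_kwargs, truth_kwargs",
        [
            ({}, {}),
            ({"background_fraction": 0.1}, {}),
            ({"irf_fwhm": 0.0}, {}),
            ({}, {"source_term": (0.382, 0.10)}),
            ({"background_fraction": 0.25}, {"tau3": 5.0}),
        ],
    )
    def test_normalization_and_nonnegativity(self, settings_kwargs, truth_kwargs):
        """Expected counts are non-negative channel-wise and integrate to
        total_counts within 0.1% for lifetimes up to 5 ns."""
        tau3 = truth_kwargs.pop("tau3", 1.83)
        s = AcquisitionSettings(**settings_kwargs)
        truth = truth_from_sample(tau3, 9.01, **truth_kwargs)
        mu = expected_spectrum(s, truth)
        assert np.all(mu >= 0)
        assert mu.sum() == pytest.approx(s.total_counts, rel=1e-3)

    def test_tail_slope_recovers_o_ps_lifetime(self, default_settings):
        """Beyond 4 ns the shorter components are dead and the log-spectrum
        is linear with slope -1/tau3: a log-linear regression on the
        analytic tail recovers 1.83 ns within 1%."""
        truth = truth_from_sample(1.83, 9.01)
        mu = expected_spectrum(default_settings, truth)
        t = (
            np.arange(default_settings.n_channels)
            - default_settings.t0_channel
        ) * default_settings.channel_width * 1e-3
        sel = (t > 4.0) & (t < 12.0)
        slope = np.polyfit(t[sel], np.log(mu[sel]), 1)[0]
        assert -1.0 / slope == pytest.approx(1.83, rel=0.01)

    def test_monotone_tail(self, default_settings, mean_truth):
        """With zero background the expectation decreases strictly beyond
        t0 + 3 IRF sigma, all the way to the last channel."""
        mu = expected_spectrum(default_settings, mean_truth)
        sigma_ch = default_settings.irf_sigma / default_settings.channel_width
        start = int(np.ceil(default_settings.t0_channel + 3 * sigma_ch)) + 1
        assert np.all(np.diff(mu[start:]) < 0)

    def test_unresolvable_lifetime_rejected(self, default_settings):
        truth = GroundTruth(components=((0.0001, 0.5), (1.83, 0.5)))
        with pytest.raises(ValueError, match="one-tenth of a channel"):
            expected_spectrum(default_settings, truth)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        tau3=st.floats(0.6, 5.0),
        i3=st.floats(0.5, 30.0),
        bg=st.floats(0.0, 0.3),
    )
    def test_normalization_property(self, tau3, i3, bg):
        s = AcquisitionSettings(background_fraction=bg)
        mu = expected_spectrum(s, truth_from_sample(tau3, i3))
        assert mu.sum() == pytest.approx(s.total_counts, rel=1e-3)
        assert mu.min() >= 0


class TestSimulateSpectrum:
    def test_seeded_determinism(self, default_settings):
        t1 = truth_from_sample(1.83, 9.01, seed=123)
        a = simulate_spectrum(default_settings, t1)
        b = simulate_spectrum(default_settings, t1)
        assert np.array_equal(a.counts, b.counts)
        c = simulate_spectrum(
            default_settings, truth_from_sample(1.83, 9.01, seed=124)
        )
        assert not np.array_equal(a.counts, c.counts)

    def test_total_counts_within_poisson_scatter(self, simulated_spectrum):
        total = simulated_spectrum.settings.total_counts
        assert abs(simulated_spectrum.total_counts - total) < 4 * np.sqrt(total)

    def test_poisson_dispersion(self, default_settings, mean_truth):
        """Across 200 replicate simulations the channel-wise variance
        matches the channel-wise mean (index of dispersion 1)."""
        mu = expected_spectrum(default_settings, mean_truth)
        rng = np.random.default_rng(2024)
        draws = rng.poisson(mu, size=(200, mu.size))
        sel = mu >= 5.0
        ratio = draws[:, sel].var(axis=0, ddof=1) / draws[:, sel].mean(axis=0)
        assert ratio.mean() == pytest.approx(1.0, abs=0.03)

    def test_metadata_attached(self, simulated_spectrum, mean_truth):
        assert simulated_spectrum.metadata["seed"] == mean_truth.seed
        assert simulated_spectrum.metadata["truth_digest"] == mean_truth.digest()


class TestTruthFromSample:
    @pytest.mark.parametrize(
        "tau3, i3, expected",
        [
            (1.83, 9.01, ((0.125, 0.03003), (0.40, 0.87987), (1.83, 0.0901))),
            (1.86, 8.96, ((0.125, 0.02987), (0.40, 0.88053), (1.86, 0.0896))),
        ],
    )
    def test_intensity_split(self, tau3, i3, expected):
        """The p-Ps channel takes one third of the o-Ps intensity (1:3
        positronium spin statistics); the free-positron channel absorbs
        the rest."""
        truth = truth_from_sample(tau3, i3)
        assert len(truth.components) == 3
        for (t_got, i_got), (t_exp, i_exp) in zip(truth.components, expected):
            assert t_got == pytest.approx(t_exp)
            assert i_got == pytest.approx(i_exp, abs=1e-5)

    def test_zero_i3_degenerates(self):
        """No o-Ps means no p-Ps either: only the free-positron component
        survives."""
        truth = truth_from_sample(1.83, 0.0)
        assert truth.components == ((0.40, 1.0),)

    def test_excessive_i3_rejected(self):
        with pytest.raises(ValueError, match="75"):
            truth_from_sample(1.83, 80.0)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"channel_width": 0.0},
            {"n_channels": 1},
            {"total_counts": 0},
            {"t0_channel": 9000},
            {"irf_fwhm": -1.0},
            {"background_fraction": 1.0},
        ],
    )
    def test_bad_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AcquisitionSettings(**kwargs)

    @pytest.mark.parametrize(
        "components, source",
        [
            (((0.4, 0.5), (0.125, 0.5)), None),       # not increasing
            (((0.125, 0.6), (0.4, 0.6)), None),       # sum != 1
            (((0.125, -0.1), (0.4, 1.1)), None),      # negative intensity
            (((0.125, 0.5), (0.4, 0.5)), (0.382, 0.5)),  # source frac > 0.25
        ],
    )
    def test_bad_truth_rejected(self, components, source):
        with pytest.raises(ValueError):
            GroundTruth(components=components, source_term=source)


class TestSpectrumFiles:
    def test_write_read_round_trip(self, simulated_spectrum, tmp_path):
        path = tmp_path / "spec.txt"
        palsfv.write_spectrum(simulated_spectrum, path)
        back = palsfv.read_spectrum(path)
        assert np.array_equal(back.counts, simulated_spectrum.counts)
        assert back.settings == simulated_spectrum.settings

    def test_missing_metadata_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("# n_channels 4\n0 1\n1 2\n2 3\n3 4\n")
        with pytest.raises(ValueError, match="metadata"):
            palsfv.read_spectrum(path)
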