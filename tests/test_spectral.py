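"""Spectral-feature contracts: Parseval scaling, difference-spectrum algebra,
alpha-peak detection, band powers, theta/beta ratio and deviation flags."""

import numpy as np
import pandas as pd
import pytest

from qeegnfb.core import BANDS, Band, EEGRecording, PowerSpectrum
from qeegnfb.spectral import (
    band_power,
    compute_qeeg_flags,
    compute_spectrum,
    detect_iapf,
    difference_spectrum,
    individualize_theta_band,
    theta_beta_ratio,
)

FS = 500.0


def _rec(x: np.ndarray, labels=("Fz",), condition="EC") -> EEGRecording:
    if x.ndim == 1:
        x = x[None, :]
    return EEGRecording(list(labels), FS, x, condition)


def _flat_spectrum(power_by_band, freqs=None, label="Fz"):
    """Synthetic spectrum with constant bin power inside given bands."""
    freqs = freqs if freqs is not None else np.arange(0, 250.5, 0.5)
    p = np.zeros_like(freqs)
    for (lo, hi), val in power_by_band.items():
        p[(freqs >= lo) & (freqs < hi)] = val
    return PowerSpectrum(freqs, p[None, :], [label], n_epochs=1)


class TestComputeSpectrum:
    def test_zero_signal_zero_power(self):
        spec = compute_spectrum(_rec(np.zeros(5000)))
        assert np.all(spec.power == 0)

    def test_sinusoid_peak_on_grid(self):
        t = np.arange(10 * FS) / FS
        spec = compute_spectrum(_rec(np.sin(2 * np.pi * 10.0 * t)))
        assert spec.freqs[np.argmax(spec.power[0])] == 10.0

    def test_parseval_white_noise(self, rng):
        x = rng.standard_normal(int(60 * FS)) * 3.0
        spec = compute_spectrum(_rec(x))
        assert spec.power[0].sum() == pytest.approx(np.var(x), rel=0.05)

    def test_frequency_grid_half_hz(self):
        spec = compute_spectrum(_rec(np.zeros(4000)))
        assert spec.df == 0.5 and spec.freqs[0] == 0.0

    def test_channel_order_invariance_and_quadratic_scaling(self, rng):
        x = rng.standard_normal((2, 4000))
        a = compute_spectrum(_rec(x, labels=("Fz", "Cz")))
        b = compute_spectrum(_rec(x[::-1], labels=("Cz", "Fz")))
        assert np.allclose(a.channel("Fz"), b.channel("Fz"))
        c = compute_spectrum(_rec(3.0 * x, labels=("Fz", "Cz")))
        assert np.allclose(c.power, 9.0 * a.power)

    def test_artifact_epoch_excluded(self, rng):
        x = rng.standard_normal(6000)
        x[2500] = 500.0  # one glitched 2000 ms epoch out of six
        spec = compute_spectrum(_rec(x))
        assert spec.n_epochs == 5

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="epoch"):
            compute_spectrum(_rec(np.zeros(500)))


class TestDifferenceSpectrum:
    def test_equal_inputs_zero(self, rng):
        s = compute_spectrum(_rec(rng.standard_normal(4000)))
        assert np.all(difference_spectrum(s, s).power == 0)

    def test_antisymmetry(self, rng):
        a = compute_spectrum(_rec(rng.standard_normal(4000)))
        b = compute_spectrum(_rec(rng.standard_normal(4000)))
        assert np.allclose(
            difference_spectrum(a, b).power, -difference_spectrum(b, a).power
        )

    def test_matches_elementwise_loop(self, rng):
        a = compute_spectrum(_rec(rng.standard_normal(4000)))
        b = compute_spectrum(_rec(rng.standard_normal(4000)))
        d = difference_spectrum(a, b)
        for i in range(d.freqs.size):
            assert d.power[0, i] == a.power[0, i] - b.power[0, i]

    def test_grid_mismatch_rejected(self, rng):
        a = compute_spectrum(_rec(rng.standard_normal(4000)))
        other = PowerSpectrum(a.freqs[:-1], a.power[:, :-1], ["Fz"])
        with pytest.raises(ValueError):
            difference_spectrum(a, other)


class TestDetectIapf:
    def test_single_bump(self):
        spec = _flat_spectrum({(9.5, 10.5): 5.0, (0.5, 30): 0.1})
        spec.power[0, spec.freqs == 10.0] = 8.0
        iapf, edge = detect_iapf(spec, "Fz")
        assert iapf == 10.0 and not edge

    def test_monotone_decreasing_flags_edge(self):
        freqs = np.arange(0, 30.5, 0.5)
        p = 1.0 / (freqs + 1.0)
        spec = PowerSpectrum(freqs, p[None, :], ["Fz"])
        iapf, edge = detect_iapf(spec, "Fz")
        assert iapf == 6.0 and edge

    def test_tie_breaks_to_lowest_frequency(self):
        spec = _flat_spectrum({(6, 13.5): 1.0})
        iapf, _ = detect_iapf(spec, "Fz")
        assert iapf == 6.0

    def test_negative_maximum_flags_edge(self):
        freqs = np.arange(0, 30.5, 0.5)
        spec = PowerSpectrum(freqs, -np.ones((1, freqs.size)), ["Fz"])
        _, edge = detect_iapf(spec, "Fz")
        assert edge

    def test_missing_site_rejected(self):
        spec = _flat_spectrum({(6, 13): 1.0})
        with pytest.raises(KeyError):
            detect_iapf(spec, "Pz")


class TestBandPower:
    def test_sinusoid_captured_by_alpha_band(self):
        t = np.arange(20 * FS) / FS
        spec = compute_spectrum(_rec(np.sin(2 * np.pi * 10.0 * t)))
        total = spec.power[0].sum()
        assert band_power(spec, "Fz", BANDS["alpha"]) >= 0.95 * total
        assert band_power(spec, "Fz", BANDS["theta"]) <= 0.01 * total

    def test_additivity_of_disjoint_bands(self, rng):
        spec = compute_spectrum(_rec(rng.standard_normal(8000)))
        a, b = Band("a", 4, 8), Band("b", 8, 13)
        union = Band("u", 4, 13)
        assert band_power(spec, "Fz", a) + band_power(spec, "Fz", b) == pytest.approx(
            band_power(spec, "Fz", union), rel=1e-12
        )

    def test_band_outside_grid_rejected(self, rng):
        spec = compute_spectrum(_rec(rng.standard_normal(4000)))
        with pytest.raises(ValueError, match="outside"):
            band_power(spec, "Fz", Band("hf", 200, 400))


class TestThetaBetaRatio:
    def test_equal_band_powers_unit_ratio(self):
        spec = _flat_spectrum({(4, 8): 2.0, (13, 21): 1.0})
        assert theta_beta_ratio(spec, "Fz") == pytest.approx(1.0)

    def test_pure_one_over_f_matches_analytic_integral(self):
        freqs = np.arange(0, 250.5, 0.5)
        p = np.zeros_like(freqs)
        p[1:] = 1.0 / freqs[1:]
        spec = PowerSpectrum(freqs, p[None, :], ["Fz"])
        got = theta_beta_ratio(spec, "Fz")
        expected = np.log(8 / 4) / np.log(21 / 13)  # ∫1/f over the two bands
        assert got == pytest.approx(expected, rel=0.05)

    def test_zero_beta_power_flagged_nan(self):
        spec = _flat_spectrum({(4, 8): 1.0})
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(theta_beta_ratio(spec, "Fz"))


class TestThetaSubband:
    @pytest.mark.parametrize("peak,expected", [(5.0, "4-6"), (7.0, "5-8")])
    def test_peak_selects_subband(self, peak, expected):
        freqs = np.arange(0, 30.5, 0.5)
        p = 1.0 / (freqs + 1.0)
        p[freqs == peak] += 2.0
        spec = PowerSpectrum(freqs, p[None, :], ["Fz"])
        sub, no_peak = individualize_theta_band(spec, "Fz")
        assert sub == expected and not no_peak

    def test_peakless_one_over_f_defaults(self):
        freqs = np.arange(0, 30.5, 0.5)
        p = 1.0 / (freqs + 1.0)
        spec = PowerSpectrum(freqs, p[None, :], ["Fz"])
        sub, no_peak = individualize_theta_band(spec, "Fz")
        assert sub == "default" and no_peak


class TestQeegFlags:
    @staticmethod
    def _ref_and_specs(theta_z=0.0):
        sites = ["Fz", "FCz", "Cz", "C3", "C4", "Pz", "Oz"]
        ref = pd.DataFrame(
            [dict(band=b, site=s, mean=10.0, sd=2.0)
             for b in ("theta", "alpha", "beta") for s in sites]
        )
        freqs = np.arange(0, 250.5, 0.5)
        # bin power chosen so each 8-bin (4 Hz) band sums to the reference mean
        base = np.full(freqs.size, 10.0 / 8.0)
        power = np.tile(base, (len(sites), 1))
        theta_mask = (freqs >= 4) & (freqs < 8)
        for s in ("Fz", "FCz", "Cz"):
            power[sites.index(s), theta_mask] = (10.0 + theta_z * 2.0) / 8.0
        spec = PowerSpectrum(freqs, power, sites)
        eo = PowerSpectrum(freqs, np.tile(base, (len(sites), 1)) , sites)
        # occipital alpha dominates mu by default
        eo.power[sites.index("Oz"), (freqs >= 8) & (freqs < 13)] = 5.0
        rec = EEGRecording(sites, FS, np.random.default_rng(0).standard_normal(
            (len(sites), int(30 * FS))) * 5.0, "EC")
        return eo, spec, rec, ref

    def test_reference_mean_spectra_flag_nothing(self):
        eo, ec, rec, ref = self._ref_and_specs(theta_z=0.0)
        flags = compute_qeeg_flags(eo, ec, rec, ref)
        assert not flags["excess_slowing"] and not flags["frontal_alpha_excess"]
        assert not flags["mu_excess"]

    def test_elevated_theta_flags_slowing(self):
        eo, ec, rec, ref = self._ref_and_specs(theta_z=2.5)
        assert compute_qeeg_flags(eo, ec, rec, ref)["excess_slowing"]

    def test_slowing_monotone_in_theta(self):
        for z_lo, z_hi in [(1.6, 3.0), (2.0, 5.0)]:
            eo, ec_lo, rec, ref = self._ref_and_specs(theta_z=z_lo)
            _, ec_hi, _, _ = self._ref_and_specs(theta_z=z_hi)
            lo = compute_qeeg_flags(eo, ec_lo, rec, ref)["excess_slowing"]
            hi = compute_qeeg_flags(eo, ec_hi, rec, ref)["excess_slowing"]
            assert hi >= lo and lo  # raising theta never clears the flag

    def test_injected_spindles_detected_with_center(self, base_params):
        from dataclasses import replace

        from qeegnfb.synthetic import make_resting_eeg

        p = replace(base_params, spindle_freq=22.0, spindle_rate=12.0)
        rec = make_resting_eeg(p, "EC", 120, seed=42)
        eo, ec, _, ref = self._ref_and_specs()
        flags = compute_qeeg_flags(eo, ec, rec, ref)
        assert flags["beta_spindles"]
        assert flags["beta_spindle_center_hz"] == pytest.approx(22.0, abs=1.0)

    def test_missing_reference_names_fields(self):
        eo, ec, rec, _ = self._ref_and_specs()
        with pytest.raises(ValueError, match="band"):
            compute_qeeg_flags(eo, ec, rec, pd.DataFrame({"x": [1]}))
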