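"""Fourier representation of pulse trains and FFT broadband impedance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from stimtwin.circuits import Capacitor, Resistor, Series, circuit_impedance
from stimtwin.spectra import SampledSignal
from stimtwin.synthetic import generate_transients
from stimtwin.waveforms import (PulseTrain, broadband_impedance, dc_component,
                                fourier_coefficients, max_harmonic_amplitude,
                                synthesize_time_domain)


class TestPulseTrainValidation:
    def test_phases_must_fit_in_period(self):
        with pytest.raises(ValueError, match="period"):
            PulseTrain("voltage", 1.0, 5e-3, 130.0, shape="biphasic_symmetric")

    @pytest.mark.parametrize("field,value", [
        ("amplitude", -1.0), ("pulse_width", 0.0), ("frequency", -5.0),
    ])
    def test_positive_fields(self, field, value):
        kwargs = dict(mode="voltage", amplitude=1.0, pulse_width=60e-6,
                      frequency=130.0)
        kwargs[field] = value
        with pytest.raises(ValueError):
            PulseTrain(**kwargs)


class TestFourierCoefficients:
    def test_square_wave_closed_form(self):
        # 50% duty: |c_1| = 1/pi, even harmonics vanish
        sq = PulseTrain("voltage", 1.0, 0.5 / 130.0, 130.0)
        c = fourier_coefficients(sq, 8).coefficients
        assert abs(c[1]) == pytest.approx(1.0 / math.pi, rel=1e-12)
        assert abs(c[2]) < 1e-15

    def test_dbs_pulse_dc_component(self):
        # 6.5 mA, 60 us, 130 Hz monophasic: mean current 50.7 uA
        t = PulseTrain("current", 6.5e-3, 60e-6, 130.0)
        assert dc_component(t) * 1e6 == pytest.approx(50.7, abs=1e-9)
        assert fourier_coefficients(t, 2).coefficients[0].real * 1e6 == \
            pytest.approx(50.7, abs=1e-9)

    def test_fundamental_matches_quadrature(self):
        # independent oracle: numerical quadrature of the Fourier integral
        A, tau, f0 = 2.0, 600e-6, 130.0
        t = np.linspace(0.0, 1.0 / f0, 400_001)
        x = np.where(np.mod(t, 1 / f0) < tau, A, 0.0)
        c1 = np.trapezoid(x * np.exp(-2j * np.pi * f0 * t), t) * f0
        train = PulseTrain("voltage", A, tau, f0)
        c = fourier_coefficients(train, 2).coefficients
        assert 2 * abs(c[1]) == pytest.approx(2 * abs(c1), rel=1e-6)
        assert 2 * abs(c[1]) == pytest.approx(0.309, abs=5e-4)

    def test_polarity_flips_sign(self):
        t_pos = PulseTrain("voltage", 1.0, 60e-6, 130.0)
        t_neg = PulseTrain("voltage", 1.0, 60e-6, 130.0,
                           onset_polarity="negative")
        c_pos = fourier_coefficients(t_pos, 5).coefficients
        c_neg = fourier_coefficients(t_neg, 5).coefficients
        assert np.allclose(c_pos, -c_neg)

    @given(tau_frac=hst.floats(0.01, 0.45), gap_frac=hst.floats(0.0, 0.05))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_biphasic_superposition_relation(self, tau_frac, gap_frac):
        # |c_n^bi| = 2 |c_n^mono| |sin(pi n f0 (tau + gap))|
        f0 = 130.0
        tau, gap = tau_frac / f0, gap_frac / f0
        mono = PulseTrain("voltage", 1.0, tau, f0)
        bi = PulseTrain("voltage", 1.0, tau, f0, shape="biphasic_symmetric",
                        interphase_gap=gap)
        n = np.arange(1, 40)
        cm = np.abs(fourier_coefficients(mono, 39).coefficients[1:])
        cb = np.abs(fourier_coefficients(bi, 39).coefficients[1:])
        expected = 2 * cm * np.abs(np.sin(np.pi * n * f0 * (tau + gap)))
        assert np.allclose(cb, expected, rtol=1e-10, atol=1e-14)

    def test_biphasic_dominates_at_higher_harmonics(self):
        # charge balance suppresses low frequencies: the dominant biphasic
        # component sits above the monophasic one (which is the fundamental)
        mono = PulseTrain("voltage", 1.0, 60e-6, 130.0)
        bi = PulseTrain("voltage", 1.0, 60e-6, 130.0,
                        shape="biphasic_symmetric")
        am = fourier_coefficients(mono, 300).one_sided_amplitudes()[1:]
        ab = fourier_coefficients(bi, 300).one_sided_amplitudes()[1:]
        assert np.argmax(ab) > np.argmax(am)


class TestDcComponent:
    def test_monophasic_product_rule(self):
        t = PulseTrain("voltage", 1.0, 600e-6, 130.0)
        assert dc_component(t) == pytest.approx(0.078, abs=1e-12)

    @given(amp=hst.floats(1e-3, 10), tau_frac=hst.floats(0.01, 0.45))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_biphasic_always_charge_balanced(self, amp, tau_frac):
        t = PulseTrain("current", amp, tau_frac / 130.0, 130.0,
                       shape="biphasic_symmetric")
        assert dc_component(t) == 0.0


class TestMaxHarmonicAmplitude:
    def test_linearity_screening_600us(self):
        # brute-force oracle over many harmonics
        train1 = PulseTrain("voltage", 1.0, 600e-6, 130.0)
        brute = np.max(
            fourier_coefficients(train1, 10_000).one_sided_amplitudes()[1:])
        assert max_harmonic_amplitude(train1) == pytest.approx(brute, rel=1e-12)
        assert max_harmonic_amplitude(train1) == pytest.approx(0.154, abs=1e-3)
        train2 = PulseTrain("voltage", 2.0, 600e-6, 130.0)
        assert max_harmonic_amplitude(train2) == pytest.approx(0.309, abs=1e-3)
        assert max_harmonic_amplitude(train2) > 0.25  # above linearity limit
        assert max_harmonic_amplitude(train1) < 0.25

    def test_amplitude_scaling_is_linear(self):
        # short pulses spread energy over many harmonics: larger n_max needed
        t1 = PulseTrain("voltage", 1.0, 60e-6, 130.0)
        t2 = PulseTrain("voltage", 2.0, 60e-6, 130.0)
        assert max_harmonic_amplitude(t2, n_max=6000) == pytest.approx(
            2 * max_harmonic_amplitude(t1, n_max=6000), rel=1e-12)

    def test_undecayed_tail_raises(self):
        t = PulseTrain("voltage", 1.0, 60e-6, 130.0)
        with pytest.raises(ValueError, match="n_max"):
            max_harmonic_amplitude(t, n_max=20)


class TestSynthesis:
    def test_constant_spectrum(self):
        from stimtwin.spectra import HarmonicSpectrum

        spec = HarmonicSpectrum(f0=130.0, coefficients=np.array([1.0 + 0j]))
        sig = synthesize_time_domain(spec, 1 / (130.0 * 64), 2)
        assert np.allclose(sig.values, 1.0)
        assert sig.values.size == 128

    def test_fft_round_trip(self):
        train = PulseTrain("voltage", 2.0, 600e-6, 130.0)
        spec = fourier_coefficients(train, 200)
        dt = 1 / (130.0 * 2048)
        sig = synthesize_time_domain(spec, dt, 3)
        X = np.fft.rfft(sig.values) / sig.values.size
        # harmonic n sits on bin 3n (3 periods)
        recovered = X[3 * np.arange(201)]
        assert np.max(np.abs(recovered - spec.coefficients)) < 1e-10

    def test_parseval_consistency(self):
        train = PulseTrain("voltage", 1.0, 600e-6, 130.0)
        spec = fourier_coefficients(train, 400)
        sig = synthesize_time_domain(spec, 1 / (130.0 * 2048), 1)
        two_sided = np.abs(spec.coefficients[0]) ** 2 + \
            2 * np.sum(np.abs(spec.coefficients[1:]) ** 2)
        mean_square = np.mean(sig.values ** 2)
        assert mean_square == pytest.approx(two_sided, rel=1e-8)

    def test_gibbs_overshoot_near_nine_percent(self):
        sq = PulseTrain("voltage", 1.0, 0.5 / 130.0, 130.0)
        spec = fourier_coefficients(sq, 401)
        sig = synthesize_time_domain(spec, 1 / (130.0 * 2 ** 16), 1)
        overshoot = sig.values.max() - 1.0
        assert overshoot == pytest.approx(0.0895, abs=0.003)

    def test_nyquist_violation_raises(self):
        train = PulseTrain("voltage", 1.0, 600e-6, 130.0)
        spec = fourier_coefficients(train, 200)
        with pytest.raises(ValueError, match="Nyquist"):
            synthesize_time_domain(spec, 1 / (130.0 * 256), 1)

    def test_nonmatching_dt_raises(self):
        from stimtwin.spectra import HarmonicSpectrum

        spec = HarmonicSpectrum(f0=130.0, coefficients=np.array([0.0j, 1.0]))
        with pytest.raises(ValueError, match="divide"):
            synthesize_time_domain(spec, 1.1e-4, 1)


class TestBroadbandImpedance:
    def test_pure_resistor(self):
        train = PulseTrain("voltage", 1.0, 600e-6, 130.0)
        sig = synthesize_time_domain(fourier_coefficients(train, 100),
                                     1 / (130.0 * 1024), 2)
        i = SampledSignal(sig.t0, sig.dt, sig.values / 50.0, "current")
        z = broadband_impedance(sig, i)
        assert len(z) > 5
        assert np.allclose(z.values, 50.0, rtol=1e-9)

    def test_series_rc_closed_form(self):
        model = Series([Resistor(150.0), Capacitor(10e-6)])
        train = PulseTrain("voltage", 1.0, 600e-6, 130.0)
        u, i, _ = generate_transients(model, train, n_periods=10)
        z = broadband_impedance(u, i, f0=130.0)
        expected = circuit_impedance(model, z.frequencies).values
        assert np.max(np.abs(z.values / expected - 1)) < 1e-6

    def test_known_circuit_oracle_equivalence(self, chamber_circuit):
        train = PulseTrain("voltage", 2.0, 60e-6, 130.0,
                           shape="biphasic_symmetric")
        u, i, _ = generate_transients(chamber_circuit, train, n_periods=10)
        z = broadband_impedance(u, i, f0=130.0)
        expected = circuit_impedance(chamber_circuit, z.frequencies).values
        assert np.max(np.abs(z.values / expected - 1)) < 1e-6

    def test_truncation_removes_weak_harmonic(self):
        f0, dt = 100.0, 1 / (100.0 * 512)
        t = np.arange(512) * dt
        i_vals = np.cos(2 * np.pi * f0 * t) + 0.08 * np.cos(2 * np.pi * 3 * f0 * t)
        u = SampledSignal(0.0, dt, 25.0 * i_vals, "voltage")
        i = SampledSignal(0.0, dt, i_vals, "current")
        z = broadband_impedance(u, i, truncation_ratio=0.1)
        assert f0 in z.frequencies
        assert 3 * f0 not in z.frequencies

    def test_mismatched_sampling_raises(self):
        u = SampledSignal(0.0, 1e-4, np.ones(64), "voltage")
        i = SampledSignal(0.0, 2e-4, np.ones(64), "current")
        with pytest.raises(ValueError, match="share"):
            broadband_impedance(u, i)

    def test_all_truncated_raises(self):
        u = SampledSignal(0.0, 1e-4, np.zeros(64) + 1.0, "voltage")
        i = SampledSignal(0.0, 1e-4, np.zeros(64), "current")
        with pytest.raises(ValueError, match="truncated"):
            broadband_impedance(u, i)
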