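"""Equivalent-circuit evaluation, fitting, KK validity, networks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from stimtwin.circuits import (CPE, Capacitor, Inductor, NetworkConfig,
                               Parallel, Parameter, Resistor, Series,
                               circuit_dc_impedance, circuit_from_dict,
                               circuit_impedance, circuit_to_dict,
                               cutoff_frequency, default_chamber_circuit,
                               fit_spectrum, kramers_kronig_validate,
                               network_impedance, refit_drift_subset)
from stimtwin.spectra import ImpedanceSpectrum
from stimtwin.synthetic import NoiseSpec, generate_eis


class TestCircuitImpedance:
    def test_lone_resistor_measured_medium_value(self):
        z = circuit_impedance(Resistor(166.56), [10.0, 130.0, 1e5]).values
        assert np.allclose(z, 166.56 + 0j)

    def test_series_rc_closed_form(self):
        R, C = 150.0, 10e-6
        f = 1.0 / (2 * math.pi * R * C)
        z = circuit_impedance(Series([Resistor(R), Capacitor(C)]), [f]).values[0]
        assert z == pytest.approx(R - 1j * R, rel=1e-12)

    def test_cpe_alpha_one_is_capacitor(self):
        f = np.logspace(-1, 7, 17)
        z_cpe = circuit_impedance(CPE(3e-6, 1.0), f).values
        z_cap = circuit_impedance(Capacitor(3e-6), f).values
        assert np.allclose(z_cpe, z_cap, rtol=1e-14)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError, match="circuit_dc_impedance"):
            circuit_impedance(Resistor(1.0), [0.0, 10.0])


class TestDcImpedance:
    def test_blocking_capacitor(self):
        assert math.isinf(circuit_dc_impedance(Series([Resistor(10), Capacitor(1e-6)])))

    def test_parallel_rc_passes_through_resistor(self):
        m = Series([Resistor(10.0), Parallel([Resistor(20.0), Capacitor(1e-6)])])
        assert circuit_dc_impedance(m) == pytest.approx(30.0)

    def test_chamber_default_blocks_dc(self, chamber_circuit):
        # CPE interface in the series path: infinite DC impedance, so a
        # voltage-controlled monophasic train passes zero mean current
        assert math.isinf(circuit_dc_impedance(chamber_circuit))

    def test_inductor_shorts_at_dc(self):
        m = Parallel([Inductor(1e-6), Resistor(100.0)])
        assert circuit_dc_impedance(m) == 0.0


class TestFitSpectrum:
    def test_clean_round_trip(self, fit_test_circuit):
        truth = fit_test_circuit()
        f = np.logspace(0, 6, 61)
        spec = circuit_impedance(truth, f)
        guess = fit_test_circuit()
        for _, p in guess.parameters():
            p.value *= 1.3
        fit = fit_spectrum(guess, spec)
        assert fit.success
        for (_, pg), (_, pt) in zip(guess.parameters(), truth.parameters()):
            assert pg.value == pytest.approx(pt.value, rel=1e-3)

    def test_residual_zero_at_fixed_point(self, fit_test_circuit):
        model = fit_test_circuit()
        spec = circuit_impedance(model, np.logspace(0, 6, 41))
        fit = fit_spectrum(model, spec)
        assert fit.residual < 1e-10

    def test_fit_idempotence(self, fit_test_circuit):
        truth = fit_test_circuit()
        spec = generate_eis(truth, np.logspace(0, 6, 61), NoiseSpec(0.01, seed=3))
        model = fit_test_circuit()
        fit_spectrum(model, spec)
        before = {n: p.value for n, p in model.parameters()}
        fit_spectrum(model, spec)
        for n, p in model.parameters():
            assert p.value == pytest.approx(before[n], rel=1e-7)

    def test_under_determined_rejected(self, fit_test_circuit):
        model = fit_test_circuit()
        spec = circuit_impedance(model, np.logspace(0, 6, 5))
        with pytest.raises(ValueError, match="under-determined"):
            fit_spectrum(model, spec)

    def test_monte_carlo_three_sigma_recovery(self, fit_test_circuit):
        # R_medium within 3 standard errors in >= 95/100 noisy replicates
        hits = 0
        for seed in range(100):
            truth = fit_test_circuit()
            spec = generate_eis(truth, np.logspace(0, 6, 51),
                                NoiseSpec(0.01, seed=seed))
            model = fit_test_circuit()
            model.find_role("medium_resistance").value = 120.0
            fit_spectrum(model, spec)
            p = model.find_role("medium_resistance")
            if p.stderr and abs(p.value - 150.0) <= 3 * p.stderr:
                hits += 1
        assert hits >= 95


class TestRefitDriftSubset:
    def test_recovers_scaled_medium_resistance(self, chamber_circuit):
        drifted = chamber_circuit.copy()
        drifted.find_role("medium_resistance").value *= 1.15
        spec = circuit_impedance(drifted, np.logspace(1, 6, 51))
        work = chamber_circuit.copy()
        refit_drift_subset(work, spec)
        factor = (work.find_role("medium_resistance").value
                  / chamber_circuit.find_role("medium_resistance").value)
        assert factor == pytest.approx(1.15, rel=5e-3)

    def test_unchanged_spectrum_keeps_calibration(self, chamber_circuit):
        spec = circuit_impedance(chamber_circuit, np.logspace(1, 6, 51))
        work = chamber_circuit.copy()
        fit = refit_drift_subset(work, spec)
        assert fit.residual < 1e-8
        for role in ("lead_inductance", "medium_resistance",
                     "double_layer_capacitance"):
            assert work.find_role(role).value == pytest.approx(
                chamber_circuit.find_role(role).value, rel=1e-4)

    def test_out_of_subset_change_elevates_residual(self):
        # change a parameter the refit cannot touch (charge-transfer R):
        # the free subset cannot absorb it
        calibrated = default_chamber_circuit(R_ct=2000.0)
        drifted = default_chamber_circuit(R_ct=600.0)
        spec = circuit_impedance(drifted, np.logspace(0, 5, 51))
        work = calibrated.copy()
        fit = refit_drift_subset(work, spec)
        assert fit.residual > 1e-3

    def test_missing_role_tags_rejected(self):
        model = Series([Resistor(100.0), Capacitor(1e-6)])
        spec = circuit_impedance(model, np.logspace(0, 5, 31))
        with pytest.raises(ValueError, match="lead_inductance"):
            refit_drift_subset(model, spec)

    def test_only_tagged_parameters_move(self, chamber_circuit):
        drifted = chamber_circuit.copy()
        drifted.find_role("medium_resistance").value *= 1.1
        spec = circuit_impedance(drifted, np.logspace(1, 6, 51))
        work = chamber_circuit.copy()
        alpha_before = work.find_role("double_layer_capacitance")
        # alpha of the CPE is a separate (fixed) parameter
        fit = refit_drift_subset(work, spec)
        assert set(fit.params) == {
            n for n, p in work.parameters()
            if p.role in ("lead_inductance", "medium_resistance",
                          "double_layer_capacitance")
        }


class TestKramersKronig:
    def test_causal_spectra_pass(self, chamber_circuit, fit_test_circuit):
        for model in (chamber_circuit, fit_test_circuit()):
            spec = circuit_impedance(model, np.logspace(0, 6.5, 61))
            kk = kramers_kronig_validate(spec, f_low=10.0, f_high=1e6)
            assert kk.valid[kk.in_range].all()

    def test_range_premask_always_recorded(self, fit_test_circuit):
        spec = circuit_impedance(fit_test_circuit(), np.logspace(-1, 7, 61))
        kk = kramers_kronig_validate(spec, f_low=10.0, f_high=1e6)
        assert (~kk.in_range).any()
        assert not kk.valid[~kk.in_range].any()

    def test_single_corruption_flagged_exactly(self, fit_test_circuit):
        spec = circuit_impedance(fit_test_circuit(), np.logspace(0, 6, 61))
        z = spec.values.copy()
        z[30] = 1.5 * z[30].real + 1j * z[30].imag
        kk = kramers_kronig_validate(
            ImpedanceSpectrum(spec.frequencies, z), f_low=1.0, f_high=1e6)
        flagged = np.nonzero(kk.in_range & ~kk.valid)[0]
        assert list(flagged) == [30]

    def test_too_few_points_rejected(self):
        spec = circuit_impedance(Resistor(10.0), np.logspace(1, 3, 5))
        with pytest.raises(ValueError, match="10"):
            kramers_kronig_validate(spec)


class TestNetworkImpedance:
    def test_six_wells_series_table_value(self):
        z = network_impedance(166.11, NetworkConfig(6, "series"))
        assert z == pytest.approx(996.66, abs=5e-3)

    def test_six_wells_parallel_table_value(self):
        z = network_impedance(166.11, NetworkConfig(6, "parallel"))
        assert z == pytest.approx(27.685, abs=5e-3)
        assert round(z, 2) == 27.69

    def test_single_well_identity(self):
        z = 100.0 - 25.0j
        assert network_impedance(z, NetworkConfig(1, "single", 0.0)) == z

    def test_shunt_added_in_series(self):
        z = network_impedance(30.0, NetworkConfig(1, "single", 100.0))
        assert z == pytest.approx(130.0)

    def test_interval_worst_case_rule(self):
        lo, hi = network_impedance((166.11, 184.04), NetworkConfig(6, "series"))
        assert lo == pytest.approx(6 * 166.11)
        assert hi == pytest.approx(6 * 184.04)

    @given(z=hst.floats(1.0, 1e4), n=hst.integers(1, 12))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_network_law(self, z, n):
        assert network_impedance(z, NetworkConfig(n, "series")) == \
            pytest.approx(n * z)
        assert network_impedance(z, NetworkConfig(n, "parallel")) == \
            pytest.approx(z / n)


class TestCutoffFrequency:
    def test_series_rc_closed_form(self):
        R, C = 159.15, 10e-6
        fc = cutoff_frequency(Series([Resistor(R), Capacitor(C)]))
        assert fc == pytest.approx(1.0 / (2 * math.pi * R * C), rel=1e-4)

    def test_chamber_cutoff_in_expected_band(self, chamber_circuit):
        fc = cutoff_frequency(chamber_circuit)
        assert 1e3 < fc < 1e4

    def test_larger_capacitance_lowers_cutoff(self):
        fcs = [cutoff_frequency(Series([Resistor(100.0), Capacitor(c)]))
               for c in (1e-6, 3e-6, 1e-5)]
        assert fcs[0] > fcs[1] > fcs[2]

    def test_no_crossing_reported(self):
        with pytest.raises(ValueError, match="phase"):
            cutoff_frequency(Resistor(10.0))


class TestSerialization:
    def test_round_trip_preserves_structure_and_roles(self, chamber_circuit):
        d = circuit_to_dict(chamber_circuit)
        clone = circuit_from_dict(d)
        f = np.logspace(0, 6, 21)
        assert np.allclose(clone.impedance(f), chamber_circuit.impedance(f))
        for role in ("lead_inductance", "medium_resistance",
                     "double_layer_capacitance"):
            assert clone.find_role(role).value == \
                chamber_circuit.find_role(role).value

    def test_bounds_and_flags_survive(self):
        m = Series([Resistor(Parameter(10.0, min=1.0, max=100.0, vary=False))])
        clone = circuit_from_dict(circuit_to_dict(m))
        p = clone.children[0].R
        assert (p.min, p.max, p.vary) == (1.0, 100.0, False)

    def test_parameter_bounds_enforced(self):
        with pytest.raises(ValueError, match="bounds"):
            Parameter(5.0, min=10.0)
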