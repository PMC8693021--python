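"""Synthetic-data generators with known ground truth.

Every stage of the pipeline is testable offline: impedance spectra come from
closed-form circuit evaluation plus measurement noise (1% proportional
complex Gaussian by default — the accuracy class of a good potentiostat),
transients from the exact Fourier-series synthesis through a known circuit,
and drift scenarios rescale the medium resistance over epochs (emulating a
thermal transient) and inject DC contamination.

Generation never reuses the fitting code paths it is meant to test: spectra
are evaluated in closed form and transients synthesized analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .circuits import CircuitModel, circuit_impedance
from .spectra import ImpedanceSpectrum, SampledSignal
from .waveforms import PulseTrain, fourier_coefficients, synthesize_time_domain
from .prediction import predict_transient, harmonics_for_energy

__all__ = [
    "NoiseSpec",
    "DriftScenario",
    "generate_eis",
    "generate_transients",
    "generate_drift_epochs",
    "recovery_harness",
]


@dataclass
class NoiseSpec:
    """Measurement-noise description for the generators."""

    amplitude: float = 0.01  # relative (proportional) or absolute (additive)
    kind: str = "proportional_gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("noise amplitude must be >= 0")
        if self.kind not in ("proportional_gaussian", "additive_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")


@dataclass
class DriftScenario:
    """Medium-resistance drift over a session (thermal relaxation).

    The resistance at epoch time ``t`` is
    ``R(t) = R0 * (1 + (initial_factor - 1) * exp(-t/time_constant))`` — an
    exponential relaxation from ``initial_factor * R0`` back to baseline,
    e.g. a 1.15 initial factor emulates a medium ~7.5 degC colder than the
    incubator that re-equilibrates over ~30 min.
    """

    initial_factor: float = 1.15
    time_constant: float = 1800.0  # s
    dc_contamination: float = 0.0  # V, added to the controlled voltage
    epoch_times: tuple = tuple(600.0 * k for k in range(13))  # 2 h, 10 min grid

    def __post_init__(self) -> None:
        if self.initial_factor <= 0 or self.time_constant <= 0:
            raise ValueError("profile must stay positive")

    def factor_at(self, t: float) -> float:
        return 1.0 + (self.initial_factor - 1.0) * math.exp(-t / self.time_constant)


def generate_eis(
    model: CircuitModel, frequencies, noise: NoiseSpec | None = None
) -> ImpedanceSpectrum:
    """Closed-form spectrum of ``model`` with measurement noise."""
    spec = circuit_impedance(model, frequencies)
    if noise is None or noise.amplitude == 0:
        return spec
    rng = np.random.default_rng(noise.seed)
    n = len(spec)
    re = rng.standard_normal(n)
    im = rng.standard_normal(n)
    if noise.kind == "proportional_gaussian":
        # independent perturbation of real and imaginary parts, scaled by |Z|
        z = spec.values + noise.amplitude * np.abs(spec.values) * (re + 1j * im)
    else:
        z = spec.values + noise.amplitude * (re + 1j * im)
    return ImpedanceSpectrum(spec.frequencies, z)


def generate_transients(
    model: CircuitModel,
    train: PulseTrain,
    dt: float | None = None,
    n_periods: int = 10,
    noise: NoiseSpec | None = None,
    r_medium_factor: float = 1.0,
    dc_contamination: float = 0.0,
) -> tuple[SampledSignal, SampledSignal, dict]:
    """Synthesize an (u, i) oscilloscope pair from a known circuit.

    The controlled signal is the ideal pulse train (plus optional DC
    contamination on a controlled voltage); the complementary signal is the
    exact linear-circuit response.  ``r_medium_factor`` rescales the
    medium-resistance leaf before generation (drift emulation).  Additive
    noise is scaled by each signal's peak.  Returns ``(u, i, truth)`` with
    the ground-truth parameter values.
    """
    work = model.copy()
    if r_medium_factor != 1.0:
        p = work.find_role("medium_resistance")
        p.value = p.value * r_medium_factor
    n_max = harmonics_for_energy(train)
    if dt is None:
        dt = 1.0 / (train.frequency * 2 ** int(np.ceil(np.log2(4 * n_max))))
    controlled = synthesize_time_domain(
        fourier_coefficients(train, n_max), dt, n_periods,
        quantity=train.mode,
    )
    complementary = predict_transient(train, work, n_max=n_max, dt=dt,
                                      n_periods=n_periods)
    if train.mode == "voltage":
        u, i = controlled, complementary
    else:
        u, i = complementary, controlled
    if dc_contamination:
        u = SampledSignal(u.t0, u.dt, u.values + dc_contamination, "voltage")
    if noise is not None and noise.amplitude > 0:
        rng = np.random.default_rng(noise.seed)
        scale_u = noise.amplitude * np.max(np.abs(u.values))
        scale_i = noise.amplitude * np.max(np.abs(i.values))
        u = SampledSignal(u.t0, u.dt, u.values + scale_u * rng.standard_normal(u.values.size), "voltage")
        i = SampledSignal(i.t0, i.dt, i.values + scale_i * rng.standard_normal(i.values.size), "current")
    truth = {name: p.value for name, p in work.parameters()}
    truth["r_medium_factor"] = r_medium_factor
    truth["dc_contamination"] = dc_contamination
    return u, i, truth


def generate_drift_epochs(
    model: CircuitModel,
    train: PulseTrain,
    scenario: DriftScenario,
    dt: float | None = None,
    n_periods: int = 10,
    noise: NoiseSpec | None = None,
):
    """Yield ``(timestamp, u, i)`` epochs following a drift scenario."""
    base_seed = 0 if noise is None else noise.seed
    for k, t in enumerate(scenario.epoch_times):
        ep_noise = None
        if noise is not None:
            ep_noise = NoiseSpec(noise.amplitude, noise.kind,
                                 seed=base_seed + 1000 + k)
        u, i, _ = generate_transients(
            model, train, dt=dt, n_periods=n_periods, noise=ep_noise,
            r_medium_factor=scenario.factor_at(t),
            dc_contamination=scenario.dc_contamination,
        )
        yield t, u, i


def recovery_harness(
    stage,
    n_seeds: int = 100,
    noise_levels=(0.0, 0.01),
    **kwargs,
) -> pd.DataFrame:
    """Seeded parameter-recovery study for a pipeline stage.

    ``stage`` is one of ``{"fit_spectrum", "refit_drift_subset",
    "fit_chrono"}``.  For each noise level and seed the corresponding
    generator draws a synthetic data set, the stage re-estimates the
    generating parameters, and the harness tabulates per-parameter bias,
    RMSE and (where standard errors are available) 95% CI coverage.
    """
    runners = {
        "fit_spectrum": _run_fit_spectrum,
        "refit_drift_subset": _run_refit_drift,
        "fit_chrono": _run_fit_chrono,
    }
    if stage not in runners:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(runners)}")
    rows = []
    for level in noise_levels:
        results = [runners[stage](level, seed, **kwargs) for seed in range(n_seeds)]
        names = results[0][0].keys()
        for name in names:
            est = np.array([r[0][name] for r in results])
            true = np.array([r[1][name] for r in results])
            err = est / true - 1.0
            cover = np.array(
                [r[2].get(name) is not None and
                 abs(r[0][name] - r[1][name]) <= 1.96 * r[2][name]
                 for r in results]
            )
            has_se = np.array([r[2].get(name) is not None for r in results])
            rows.append({
                "stage": stage,
                "noise": level,
                "parameter": name,
                "bias": float(np.mean(err)),
                "rmse": float(np.sqrt(np.mean(err ** 2))),
                "median_abs_err": float(np.median(np.abs(err))),
                "coverage": float(np.mean(cover[has_se])) if has_se.any() else np.nan,
                "n_seeds": n_seeds,
            })
    return pd.DataFrame(rows)


# -- stage runners -----------------------------------------------------------


def _default_fit_circuit():
    from .circuits import CPE, Parallel, Parameter, Resistor, Series

    return Series([
        Resistor(Parameter(150.0, min=1.0, role="medium_resistance")),
        Parallel([
            CPE(Parameter(2e-5, min=1e-9), Parameter(0.85, min=0.3, max=1.0)),
            Resistor(Parameter(5000.0, min=1.0)),
        ]),
    ])


def _run_fit_spectrum(level, seed, f_low=1.0, f_high=1e6, n_per_decade=8):
    from .circuits import fit_spectrum

    truth_model = _default_fit_circuit()
    truth = {n: p.value for n, p in truth_model.parameters()}
    n_pts = int(n_per_decade * math.log10(f_high / f_low)) + 1
    f = np.logspace(math.log10(f_low), math.log10(f_high), n_pts)
    spec = generate_eis(truth_model, f, NoiseSpec(level, seed=seed))
    guess = _default_fit_circuit()
    rng = np.random.default_rng(seed + 10_000)
    for _, p in guess.parameters():
        if p.vary:
            p.value = float(np.clip(p.value * rng.uniform(0.7, 1.4), p.min, p.max))
    fit = fit_spectrum(guess, spec)
    est = {n: p.value for n, p in guess.parameters()}
    se = {n: (p.stderr if p.vary else None) for n, p in guess.parameters()}
    return est, truth, se


def _run_refit_drift(level, seed, factor_range=(0.9, 1.2)):
    from .circuits import default_chamber_circuit

    calibrated = default_chamber_circuit()
    rng = np.random.default_rng(seed)
    factor = rng.uniform(*factor_range)
    drifted = calibrated.copy()
    drifted.find_role("medium_resistance").value *= factor
    # EIS-style grid, 10 Hz - 5 MHz: the inductive branch only shows at the
    # top of the band
    f = np.logspace(1, math.log10(5e6), 58)
    spec = generate_eis(drifted, f, NoiseSpec(level, seed=seed))
    from .circuits import refit_drift_subset

    work = calibrated.copy()
    fit = refit_drift_subset(work, spec)
    est, truth, se = {}, {}, {}
    for role in ("lead_inductance", "medium_resistance",
                 "double_layer_capacitance"):
        est[role] = work.find_role(role).value
        truth[role] = drifted.find_role(role).value
        se[role] = work.find_role(role).stderr
    return est, truth, se


def _run_fit_chrono(level, seed, a=2e-5, b=1e-5, c=50.0):
    from .monitoring import fit_chrono

    t = np.linspace(1.0, 600.0, 600)
    y = a / np.sqrt(t) + b * np.exp(-t / c)
    rng = np.random.default_rng(seed)
    y = y * (1 + level * rng.standard_normal(t.size))
    m = fit_chrono(t, y)
    return (
        {"a": m.a, "b": m.b, "c": m.c},
        {"a": a, "b": b, "c": c},
        {"a": None, "b": None, "c": None},
    )
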