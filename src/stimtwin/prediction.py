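"""Forward prediction of stimulation transients and cell-level fields.

Combines the three calibrated sub-models:

* the pulse train's exact Fourier series (``waveforms``),
* the fitted equivalent circuit of chamber + leads (``circuits``),
* the reference field solution ``(I_0, E_0)`` of the chamber (``fem``),

to predict the complementary electrical signal (current under voltage
control, voltage under current control) and the electric field the cells
experience, with worst-case error bounds propagated as intervals.

Two field-estimation routes are provided, mirroring how the chamber is used
in practice:

* **current-conductivity**: the measured current times the computed medium
  resistance gives the medium voltage drop, hence the field; the resistance
  interval must carry the conductivity uncertainty.
* **voltage-divider**: the medium's share of the applied voltage follows
  from the impedance ratio ``Z_medium / Z_total`` per harmonic; the
  conductivity error cancels, so the bounds are tighter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuits import CircuitModel, circuit_dc_impedance
from .spectra import HarmonicSpectrum, SampledSignal
from .uq import PredictionInterval
from .waveforms import PulseTrain, fourier_coefficients, synthesize_time_domain

__all__ = [
    "FieldEstimateSeries",
    "scale_reference",
    "medium_resistance",
    "predict_transient",
    "voltage_divider",
    "field_from_current",
    "field_from_divider",
    "harmonics_for_energy",
]


@dataclass
class FieldEstimateSeries:
    """Time series of the estimated field with lower/upper bounds (V/m)."""

    times: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    method: str  # {current_conductivity, voltage_divider}

    def __post_init__(self) -> None:
        if self.method not in ("current_conductivity", "voltage_divider"):
            raise ValueError(f"unknown method {self.method!r}")
        if np.any(self.lower > self.mean + 1e-12) or np.any(
            self.mean > self.upper + 1e-12
        ):
            raise ValueError("bounds must satisfy lower <= mean <= upper")


def scale_reference(I_0: float, U: float, sigma: float,
                    U_0: float = 1.0, sigma_0: float = 1.0) -> float:
    """Current at voltage ``U`` and conductivity ``sigma`` from the reference
    solve: ``I = (sigma/sigma_0) (U/U_0) I_0`` (exact linear scaling)."""
    if I_0 <= 0 or U <= 0 or sigma <= 0:
        raise ValueError("I_0, U and sigma must be > 0")
    return (sigma / sigma_0) * (U / U_0) * I_0


def medium_resistance(I_0: float, sigma: float,
                      U_0: float = 1.0, sigma_0: float = 1.0) -> float:
    """Medium resistance ``R = (sigma_0/sigma) (U_0/I_0)``; voltage drops out."""
    if I_0 <= 0 or sigma <= 0:
        raise ValueError("I_0 and sigma must be > 0")
    return (sigma_0 / sigma) * (U_0 / I_0)


def harmonics_for_energy(train: PulseTrain, tail_energy: float = 1e-3,
                         n_cap: int = 20000) -> int:
    """Smallest harmonic count whose omitted tail carries less than
    ``tail_energy`` of the AC signal energy (Parseval)."""
    spec = fourier_coefficients(train, n_cap)
    e = np.abs(spec.coefficients[1:]) ** 2
    total = e.sum()
    cum = np.cumsum(e)
    n = int(np.searchsorted(cum, (1.0 - tail_energy) * total)) + 1
    return max(n, 10)


def predict_transient(
    train: PulseTrain,
    model: CircuitModel,
    n_max: int | None = None,
    dt: float | None = None,
    n_periods: int = 1,
) -> SampledSignal:
    """Predict the complementary signal of a pulse train through a circuit.

    Voltage-controlled trains predict the current ``I(w_n) = U(w_n)/Z(w_n)``;
    current-controlled trains predict the voltage ``U = Z I``.  The DC bin
    uses the circuit's DC limit explicitly: a DC-blocking circuit passes zero
    mean current, so a voltage-controlled monophasic train yields a predicted
    current with zero mean — the blocked DC component reappears as a negative
    offset during the off-phase.
    """
    if n_max is None:
        n_max = harmonics_for_energy(train)
    if dt is None:
        dt = 1.0 / (train.frequency * 2 ** int(np.ceil(np.log2(4 * n_max))))
    spec = fourier_coefficients(train, n_max)
    f_n = spec.harmonic_frequencies[1:]
    z_n = model.impedance(f_n)
    z_dc = circuit_dc_impedance(model)
    if train.mode == "voltage":
        out_ac = spec.coefficients[1:] / z_n
        out_dc = 0.0 if np.isinf(z_dc) else spec.coefficients[0].real / z_dc
        quantity = "current"
    else:
        out_ac = spec.coefficients[1:] * z_n
        i_dc = spec.coefficients[0].real
        if np.isinf(z_dc):
            if abs(i_dc) > 0:
                raise ValueError(
                    "current-controlled train has a DC component but the "
                    "circuit blocks DC: the required voltage offset is "
                    "unbounded in the linear model"
                )
            out_dc = 0.0
        else:
            out_dc = i_dc * z_dc
        quantity = "voltage"
    out = HarmonicSpectrum(
        f0=train.frequency,
        coefficients=np.concatenate([[complex(out_dc)], out_ac]),
    )
    return synthesize_time_domain(out, dt, n_periods, quantity=quantity)


def voltage_divider(
    u_spectrum: HarmonicSpectrum, model: CircuitModel
) -> HarmonicSpectrum:
    """Medium share of the applied voltage, per harmonic.

    ``U_medium(w_n) = Z_medium(w_n) / Z_total(w_n) * U_in(w_n)``.  The medium
    is the leaf tagged ``medium_resistance``; every other element of the
    model — interfaces, leads and an explicit shunt resistor if present —
    participates in ``Z_total``.
    """
    r_med = model.find_role("medium_resistance")  # KeyError if missing
    f_n = u_spectrum.harmonic_frequencies[1:]
    z_tot = model.impedance(f_n)
    z_med = np.full(f_n.shape, r_med.value, dtype=complex)
    c = np.empty_like(u_spectrum.coefficients)
    c[1:] = u_spectrum.coefficients[1:] * z_med / z_tot
    z_dc = circuit_dc_impedance(model)
    c[0] = (
        0.0
        if np.isinf(z_dc)
        else u_spectrum.coefficients[0].real * r_med.value / z_dc
    )
    return HarmonicSpectrum(f0=u_spectrum.f0, coefficients=c)


def _interval_product(x: np.ndarray, lo: float, hi: float):
    """Per-sample interval bounds of ``x * [lo, hi]`` for same-sign factors."""
    lower = np.where(x >= 0, x * lo, x * hi)
    upper = np.where(x >= 0, x * hi, x * lo)
    return lower, upper


def field_from_current(
    i: SampledSignal,
    R_interval: PredictionInterval,
    E_interval: PredictionInterval,
    U_0: float = 1.0,
) -> FieldEstimateSeries:
    """Field estimate by the current-conductivity method.

    Per sample: ``U(t) = i(t) R`` and ``E(t) = (U(t)/U_0) E_0``.  ``R`` must
    be the conductivity-adjusted resistance interval; ``E_interval`` the
    field-per-volt interval from the geometry UQ.  Interval arithmetic pairs
    low*low / high*high for same-sign currents (bounds swap with the sign).
    """
    if R_interval.kind != "resistance":
        raise ValueError("R_interval must be of kind 'resistance'")
    if E_interval.kind != "field":
        raise ValueError("E_interval must be of kind 'field'")
    r_lo = R_interval.adjusted_low if R_interval.adjusted_low is not None else R_interval.low
    r_hi = R_interval.adjusted_high if R_interval.adjusted_high is not None else R_interval.high
    r_mid = 0.5 * (r_lo + r_hi)
    e_mid = 0.5 * (E_interval.low + E_interval.high)
    x = i.values
    lower, upper = _interval_product(x, r_lo * E_interval.low / U_0,
                                     r_hi * E_interval.high / U_0)
    return FieldEstimateSeries(
        times=i.times,
        mean=x * r_mid * e_mid / U_0,
        lower=lower,
        upper=upper,
        method="current_conductivity",
    )


def field_from_divider(
    train: PulseTrain,
    model: CircuitModel,
    E_interval: PredictionInterval,
    dt: float | None = None,
    n_periods: int = 1,
    n_max: int | None = None,
    U_0: float = 1.0,
) -> FieldEstimateSeries:
    """Field estimate by the voltage-divider method.

    Synthesizes ``U_medium(t)`` from the divider spectrum, then
    ``E(t) = (U_medium(t)/U_0) E_0`` with the UQ field bounds only — the
    conductivity uncertainty cancels in the impedance ratio, which is this
    method's advantage over the current-conductivity route.
    """
    if train.mode != "voltage":
        raise ValueError("voltage-divider estimates need a voltage-controlled train")
    if E_interval.kind != "field":
        raise ValueError("E_interval must be of kind 'field'")
    if n_max is None:
        n_max = harmonics_for_energy(train)
    if dt is None:
        dt = 1.0 / (train.frequency * 2 ** int(np.ceil(np.log2(4 * n_max))))
    u_in = fourier_coefficients(train, n_max)
    u_med = voltage_divider(u_in, model)
    sig = synthesize_time_domain(u_med, dt, n_periods, quantity="voltage")
    x = sig.values
    e_mid = 0.5 * (E_interval.low + E_interval.high)
    lower, upper = _interval_product(x, E_interval.low / U_0,
                                     E_interval.high / U_0)
    return FieldEstimateSeries(
        times=sig.times,
        mean=x * e_mid / U_0,
        lower=lower,
        upper=upper,
        method="voltage_divider",
    )
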