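"""In-situ monitoring of recorded stimulation data.

During stimulation only the voltage and current transients are observable.
This module turns them into diagnostics:

* **chronoamperometry** (DC stimulation): the current decays as a
  superposition of a faradaic diffusion-limited term ``a / sqrt(t)`` and a
  nonfaradaic capacitive term ``b exp(-t/c)``; the decomposition separates
  electrode-surface chemistry from double-layer charging.
* **DC contamination**: a nominally charge-balanced pulse train with a small
  constant offset (stimulator coupling artefacts) — detected as the mean
  over whole periods.
* **drift tracking**: per recording epoch, the broadband impedance is
  refitted over the identifiable subset (lead inductance, medium resistance,
  double-layer capacitance); the medium-resistance track converts to a
  temperature estimate via the conductivity's ~2%/degC temperature
  coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import curve_fit

from .circuits import CircuitModel, refit_drift_subset
from .spectra import SampledSignal
from .waveforms import PulseTrain, broadband_impedance, crop_to_integer_periods
from .prediction import predict_transient

__all__ = [
    "ChronoModel",
    "DriftReport",
    "fit_chrono",
    "decompose_chrono",
    "dc_offset",
    "infer_temperature_shift",
    "drift_report",
]

#: Temperature coefficient of the medium conductivity, per degC.
ALPHA_CONDUCTIVITY = 0.02

#: Default alarm thresholds (fractions / volts).
IMPEDANCE_DEVIATION_ALARM = 0.03
DC_OFFSET_ALARM = 0.020


@dataclass
class ChronoModel:
    """Fitted chronoamperometry response ``I(t) = a/sqrt(t) + b exp(-t/c)``."""

    a: float  # A sqrt(s), faradaic (diffusion-limited) magnitude
    b: float  # A, nonfaradaic (capacitive) magnitude
    c: float  # s, capacitive decay time
    residual: float = 0.0  # RMS relative to peak current
    converged: bool = True

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.c <= 0:
            raise ValueError("a, b and c must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.a / np.sqrt(t) + self.b * np.exp(-t / self.c)


def fit_chrono(times, currents) -> ChronoModel:
    """Positive-constrained nonlinear least squares of the chrono model.

    Initial guesses: the mean over the last decade of the record seeds the
    capacitive level ``b``, the first-point excess seeds ``a`` and one third
    of the record length seeds ``c``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(currents, dtype=float)
    if t.size < 10:
        raise ValueError("need at least 10 samples")
    if np.any(t <= 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times must be positive and strictly increasing")

    def f(t, a, b, c):
        return a / np.sqrt(t) + b * np.exp(-t / c)

    # The two components are strongly correlated, so a plain descent from a
    # heuristic start can stall in a shallow local minimum.  Profile over the
    # only nonlinear parameter: for fixed c, (a, b) is a linear LSQ; scan c
    # over a log grid and polish the best triple.
    inv_sqrt = 1.0 / np.sqrt(t)
    best = None
    for c_try in np.geomspace(t[0], 10.0 * t[-1], 40):
        A = np.column_stack([inv_sqrt, np.exp(-t / c_try)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        if np.any(coef <= 0):
            continue
        sse = float(np.sum((A @ coef - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, coef[0], coef[1], c_try)
    if best is None:
        b0 = max(float(np.mean(y[t >= t[-1] / 10.0])), 1e-12)
        a0 = max((float(y[0]) - b0) * math.sqrt(t[0]), 1e-12)
        p0 = (a0, b0, t[-1] / 3.0)
    else:
        p0 = best[1:]
    try:
        popt, _ = curve_fit(
            f, t, y, p0=p0,
            bounds=([1e-15, 1e-15, 1e-9], [np.inf] * 3),
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
            x_scale=np.abs(p0),
        )
        ok = True
    except RuntimeError:
        popt, ok = p0, False
    resid = float(np.sqrt(np.mean((f(t, *popt) - y) ** 2)) / np.max(np.abs(y)))
    return ChronoModel(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
                       residual=resid, converged=ok)


def decompose_chrono(model: ChronoModel, t):
    """Split the fitted current into (faradaic, nonfaradaic) series.

    The two parts sum to the model exactly on any grid.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be > 0")
    return model.a / np.sqrt(t), model.b * np.exp(-t / model.c)


def dc_offset(signal: SampledSignal, f0: float | None = None) -> float:
    """Mean of a signal over a whole number of periods (DC contamination)."""
    if f0 is not None:
        signal = crop_to_integer_periods(signal, f0)
    return float(np.mean(signal.values))


def infer_temperature_shift(
    R_obs: float,
    R_ref: float,
    alpha: float = ALPHA_CONDUCTIVITY,
    peak_to_peak_proxy: bool = False,
) -> float:
    """Temperature deficit from a medium-resistance change.

    The medium conductivity grows by about ``alpha`` (2%/degC) per degree, so
    under a spatially homogeneous temperature change,
    ``dT = ((R_obs - R_ref)/R_ref) / alpha`` — positive dT means a *colder*
    (more resistive) medium.

    Peak-to-peak voltages of short current-controlled pulses may stand in for
    the resistances, but only when the signal is dominated by the ohmic
    medium resistance (short pulse widths, frequencies above the interface
    cutoff); acknowledge that regime explicitly with
    ``peak_to_peak_proxy=True`` when passing voltages.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if R_obs <= 0 or R_ref <= 0:
        raise ValueError("resistances (or proxies) must be > 0")
    del peak_to_peak_proxy  # semantic flag only
    return ((R_obs - R_ref) / R_ref) / alpha


@dataclass
class EpochRecord:
    """Per-epoch diagnostics of the drift monitor."""

    timestamp: float
    params: dict[str, float]
    peak_to_peak: float
    dc_offset: float
    deviation: float  # RMS(measured - predicted) / peak over one period
    delta_T: float
    residual: float
    alarms: list = dc_field(default_factory=list)
    error: str | None = None


@dataclass
class DriftReport:
    """Time-ordered drift diagnostics for a stimulation session."""

    epochs: list
    reference_R_medium: float
    thresholds: dict

    def delta_T_track(self) -> np.ndarray:
        return np.array([e.delta_T for e in self.epochs if e.error is None])


def drift_report(
    epochs,
    reference_model: CircuitModel,
    train: PulseTrain,
    truncation_ratio: float = 0.1,
    deviation_alarm: float = IMPEDANCE_DEVIATION_ALARM,
    dc_alarm: float = DC_OFFSET_ALARM,
) -> DriftReport:
    """Monitor a stream of recording epochs against the calibrated model.

    ``epochs`` yields ``(timestamp, u, i)`` with ``u``/``i`` SampledSignals.
    Per epoch: broadband impedance -> constrained refit of the drift subset
    -> medium-resistance track -> temperature estimate; plus peak-to-peak,
    DC offset of the controlled signal and the relative deviation of the
    measured complementary signal from the reference-model prediction.
    Failing epochs are recorded, not fatal.
    """
    ref_R = reference_model.find_role("medium_resistance").value
    records = []
    for ts, u, i in epochs:
        try:
            measured = i if train.mode == "voltage" else u
            spec = broadband_impedance(u, i, truncation_ratio, f0=train.frequency)
            work = reference_model.copy()
            fit = refit_drift_subset(work, spec)
            r_med = work.find_role("medium_resistance").value
            pred = predict_transient(
                train,
                reference_model,
                dt=measured.dt,
                n_periods=max(1, int(round(measured.duration * train.frequency))),
            )
            n = min(pred.values.size, measured.values.size)
            dev = float(
                np.sqrt(np.mean((measured.values[:n] - pred.values[:n]) ** 2))
                / np.max(np.abs(measured.values[:n]))
            )
            # DC contamination shows up in the voltage (stimulator coupling);
            # it barely affects the current, so the voltage is what to watch
            off = dc_offset(u, f0=train.frequency)
            rec = EpochRecord(
                timestamp=ts,
                params=dict(fit.params),
                peak_to_peak=float(np.ptp(measured.values)),
                dc_offset=off,
                deviation=dev,
                delta_T=infer_temperature_shift(r_med, ref_R),
                residual=fit.residual,
            )
            if dev > deviation_alarm:
                rec.alarms.append("impedance_deviation")
            if abs(off) > dc_alarm:
                rec.alarms.append("dc_offset")
            records.append(rec)
        except Exception as exc:  # noqa: BLE001 — epoch failures are data
            records.append(EpochRecord(
                timestamp=ts, params={}, peak_to_peak=math.nan,
                dc_offset=math.nan, deviation=math.nan, delta_T=math.nan,
                residual=math.nan, error=str(exc),
            ))
    return DriftReport(
        epochs=records,
        reference_R_medium=ref_R,
        thresholds={"deviation": deviation_alarm, "dc_offset": dc_alarm},
    )
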