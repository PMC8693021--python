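"""Rectangular stimulation pulse trains in the frequency domain.

Mono- and biphasic rectangular pulse trains are represented exactly by their
Fourier series; a biphasic (charge-balanced) pulse is the superposition of a
positive monophasic pulse and a time-shifted negated copy, so its
coefficients follow from the monophasic ones by a phase factor.  Recorded
voltage/current transients are turned into broadband impedance spectra by
FFT division with amplitude truncation against noise.

Conventions
-----------
Fourier series :math:`x(t) = \\sum_{n=-\\infty}^{\\infty} c_n e^{j2\\pi n f_0 t}`;
for a real signal :math:`c_{-n} = \\overline{c_n}` and the one-sided amplitude
at harmonic ``n >= 1`` is ``2 |c_n|``.  The positive phase of a pulse starts
at ``t = 0``; for biphasic pulses the negative phase follows after the
interphase gap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .spectra import HarmonicSpectrum, ImpedanceSpectrum, SampledSignal

__all__ = [
    "PulseTrain",
    "fourier_coefficients",
    "dc_component",
    "max_harmonic_amplitude",
    "synthesize_time_domain",
    "broadband_impedance",
    "crop_to_integer_periods",
]

#: Default harmonic count; rectangular-pulse amplitudes decay like 1/n so a
#: couple of thousand harmonics put the tail far below measurement noise.
DEFAULT_N_MAX = 2000


@dataclass
class PulseTrain:
    """Specification of a rectangular stimulation pulse train.

    Parameters
    ----------
    mode : {"voltage", "current"}
        Controlled quantity; ``amplitude`` is in V or A accordingly.
    amplitude : float
        Pulse amplitude (> 0); the polarity is carried separately.
    pulse_width : float
        Width of one phase, seconds.
    frequency : float
        Repetition frequency f0, Hz.
    shape : {"monophasic", "biphasic_symmetric"}
    interphase_gap : float
        Delay between the two phases of a biphasic pulse, seconds.
    onset_polarity : {"positive", "negative"}
        Sign of the first phase.
    """

    mode: str
    amplitude: float
    pulse_width: float
    frequency: float
    shape: str = "monophasic"
    interphase_gap: float = 0.0
    onset_polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.mode not in ("voltage", "current"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.shape not in ("monophasic", "biphasic_symmetric"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.onset_polarity not in ("positive", "negative"):
            raise ValueError(f"unknown onset_polarity {self.onset_polarity!r}")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.pulse_width <= 0 or self.frequency <= 0:
            raise ValueError("pulse_width and frequency must be > 0")
        if self.interphase_gap < 0:
            raise ValueError("interphase_gap must be >= 0")
        if self.occupied_time > 1.0 / self.frequency + 1e-15:
            raise ValueError(
                "pulse phases do not fit in one period: "
                f"occupied {self.occupied_time:.3g} s > T = {1.0/self.frequency:.3g} s"
            )

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def occupied_time(self) -> float:
        """Active time per period (both phases + gap for biphasic)."""
        if self.shape == "monophasic":
            return self.pulse_width
        return 2.0 * self.pulse_width + self.interphase_gap

    @property
    def sign(self) -> float:
        return 1.0 if self.onset_polarity == "positive" else -1.0

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Ideal time-domain waveform at times ``t`` (exact, no truncation)."""
        tau, gap, T = self.pulse_width, self.interphase_gap, self.period
        tm = np.mod(np.asarray(t, dtype=float), T)
        out = np.where(tm < tau, self.amplitude, 0.0)
        if self.shape == "biphasic_symmetric":
            start = tau + gap
            out = out - np.where((tm >= start) & (tm < start + tau), self.amplitude, 0.0)
        return self.sign * out


def fourier_coefficients(train: PulseTrain, n_max: int = DEFAULT_N_MAX) -> HarmonicSpectrum:
    """Exact Fourier coefficients ``c_0 .. c_n_max`` of a pulse train.

    For a monophasic pulse of amplitude A starting at t = 0,

    .. math:: c_n = A \\frac{\\tau}{T} e^{-j\\pi n f_0 \\tau}
              \\operatorname{sinc}(n f_0 \\tau),

    with ``sinc(x) = sin(pi x)/(pi x)``.  A symmetric biphasic pulse is the
    superposition of the monophasic pulse and its negated copy delayed by
    ``tau + gap``, i.e. the monophasic coefficients times
    ``1 - exp(-j 2 pi n f0 (tau + gap))``.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    tau, f0, A = train.pulse_width, train.frequency, train.amplitude
    n = np.arange(n_max + 1)
    c = A * tau * f0 * np.exp(-1j * math.pi * n * f0 * tau) * np.sinc(n * f0 * tau)
    if train.shape == "biphasic_symmetric":
        c = c * (1.0 - np.exp(-2j * math.pi * n * f0 * (tau + train.interphase_gap)))
    c = train.sign * c
    c[0] = c[0].real
    return HarmonicSpectrum(f0=f0, coefficients=c)


def dc_component(train: PulseTrain) -> float:
    """Zero-frequency Fourier component (mean value) of the train.

    ``A * tau * f0`` for monophasic pulses (signed by onset polarity); exactly
    zero for charge-balanced symmetric biphasic pulses.
    """
    if train.shape == "biphasic_symmetric":
        return 0.0
    return train.sign * train.amplitude * train.pulse_width * train.frequency


def max_harmonic_amplitude(
    train: PulseTrain,
    n_max: int = DEFAULT_N_MAX,
    tail_decay: float = 0.01,
) -> float:
    """Largest one-sided harmonic amplitude ``max_n 2|c_n|`` for ``n >= 1``.

    Used to screen a waveform against a linearity limit of the
    electrode-electrolyte interface (250 mV by default elsewhere).  Raises if
    the tail of the spectrum has not decayed below ``tail_decay`` times the
    maximum, which would mean ``n_max`` is too small to trust the maximum.
    """
    spec = fourier_coefficients(train, n_max=n_max)
    amps = spec.one_sided_amplitudes()[1:]
    peak = float(np.max(amps))
    # Rectangular pulses decay ~1/n with sinc zeros: judge the tail by the
    # maximum over the last 5% of harmonics, not a single (possibly null) bin.
    tail_n = max(1, int(0.05 * amps.size))
    tail = float(np.max(amps[-tail_n:]))
    if tail > tail_decay * peak:
        raise ValueError(
            f"harmonic tail has not decayed (tail {tail:.3g} vs peak {peak:.3g}); "
            "increase n_max"
        )
    return peak


def synthesize_time_domain(
    spectrum: HarmonicSpectrum,
    dt: float,
    n_periods: int = 1,
    t0: float = 0.0,
    quantity: str = "voltage",
) -> SampledSignal:
    """Evaluate a truncated Fourier series on a uniform grid.

    The grid spans exactly ``n_periods`` fundamental periods; ``dt`` must
    divide the period to within rounding so harmonics land on FFT bins.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    T = 1.0 / spectrum.f0
    n_per = T / dt
    N_per = round(n_per)
    if N_per < 2 or abs(n_per - N_per) > 1e-6 * n_per:
        raise ValueError(
            f"dt = {dt:.3g} s does not divide the period T = {T:.3g} s "
            f"(T/dt = {n_per:.6g})"
        )
    if spectrum.n_max * spectrum.f0 >= 0.5 / dt:
        raise ValueError(
            "Nyquist violation: highest harmonic "
            f"{spectrum.n_max * spectrum.f0:.3g} Hz >= 1/(2 dt) = {0.5/dt:.3g} Hz"
        )
    # Harmonics fall exactly on the FFT bins of one period, so the series
    # x(t) = c0 + sum_n 2 Re(c_n exp(j 2 pi n f0 t)) is an inverse rFFT of
    # one period, tiled; a t0 offset is a per-harmonic phase factor.
    c = spectrum.coefficients.copy()
    if t0 != 0.0:
        n = np.arange(c.size)
        c = c * np.exp(2j * math.pi * n * spectrum.f0 * t0)
    X = np.zeros(N_per // 2 + 1, dtype=complex)
    X[: c.size] = c
    x_period = np.fft.irfft(X * N_per, N_per)
    x = np.tile(x_period, n_periods)
    return SampledSignal(t0=t0, dt=dt, values=x, quantity=quantity)


def crop_to_integer_periods(signal: SampledSignal, f0: float) -> SampledSignal:
    """Crop a signal to the largest whole number of periods of ``f0``.

    Warns when more than one sample is discarded (FFT bins then sit exactly
    on the harmonics, which is the windowless design used throughout).
    """
    T = 1.0 / f0
    n_per = T / signal.dt
    if signal.values.size * signal.dt < T * (1 - 1e-9):
        raise ValueError("signal shorter than one period")
    k = int(math.floor(signal.values.size / n_per + 1e-9))
    N = int(round(k * n_per))
    dropped = signal.values.size - N
    if dropped > 1:
        warnings.warn(
            f"cropping {dropped} samples to reach an integer number of periods",
            stacklevel=2,
        )
    if dropped <= 0:
        return signal
    return SampledSignal(signal.t0, signal.dt, signal.values[:N], signal.quantity)


def broadband_impedance(
    u: SampledSignal,
    i: SampledSignal,
    truncation_ratio: float = 0.1,
    f0: float | None = None,
) -> ImpedanceSpectrum:
    """Broadband impedance ``Z(f_k) = U(f_k) / I(f_k)`` from a transient pair.

    Both signals are Fourier transformed (no window; pass ``f0`` to crop to an
    integer number of periods first) and the ratio is kept only at bins whose
    current amplitude reaches ``truncation_ratio`` times the maximum current
    amplitude — the standard noise-truncation rule for rectangular-pulse
    broadband impedance spectroscopy.  The zero-frequency bin is included only
    if the DC current passes the same threshold.
    """
    if not (0 <= truncation_ratio < 1):
        raise ValueError("truncation_ratio must be in [0, 1)")
    if u.quantity != "voltage" or i.quantity != "current":
        raise ValueError("expected a (voltage, current) pair")
    if abs(u.t0 - i.t0) > 1e-12 + 1e-9 * u.dt or abs(u.dt - i.dt) > 1e-12 * u.dt:
        raise ValueError("u and i must share t0 and dt")
    if u.values.size != i.values.size:
        raise ValueError("u and i must have the same length")
    if f0 is not None:
        u = crop_to_integer_periods(u, f0)
        i = crop_to_integer_periods(i, f0)
    N = u.values.size
    U = np.fft.rfft(u.values) / N
    I = np.fft.rfft(i.values) / N
    freqs = np.fft.rfftfreq(N, d=u.dt)
    amp_i = np.abs(I)
    keep = amp_i >= truncation_ratio * np.max(amp_i)
    keep &= amp_i > 0
    if not np.any(keep):
        raise ValueError("all frequency bins truncated; no impedance estimate possible")
    return ImpedanceSpectrum(freqs[keep], U[keep] / I[keep])
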