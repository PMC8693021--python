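"""Frequency- and time-domain containers shared across the package.

The containers are deliberately light: plain dataclasses over numpy arrays
with CSV round-trips matching the oscilloscope / potentiostat export
conventions used throughout (columns ``time_s,value`` for signals and
``frequency_Hz,real,imag`` for spectra).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SampledSignal", "ImpedanceSpectrum", "HarmonicSpectrum"]


@dataclass
class SampledSignal:
    """A uniformly sampled real signal (voltage or current).

    Parameters
    ----------
    t0 : float
        Time of the first sample in seconds.
    dt : float
        Sampling interval in seconds, > 0.
    values : ndarray
        Real samples, length >= 2.
    quantity : {"voltage", "current"}
        Physical quantity carried by ``values`` (V or A).
    """

    t0: float
    dt: float
    values: np.ndarray
    quantity: str = "voltage"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("values must be a 1-D array of length >= 2")
        if self.quantity not in ("voltage", "current"):
            raise ValueError(f"unknown quantity {self.quantity!r}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * self.values.size

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, quantity: str = "voltage") -> "SampledSignal":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ValueError(f"{path}: missing required column 'time_s'")
        t = df["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6, atol=0):
            raise ValueError(f"{path}: sampling is not uniform")
        col = "value" if "value" in df.columns else df.columns[1]
        return cls(t0=t[0], dt=float(dt[0]), values=df[col].to_numpy(dtype=float),
                   quantity=quantity)


@dataclass
class ImpedanceSpectrum:
    """Complex impedance samples on a strictly increasing frequency grid."""

    frequencies: np.ndarray  # Hz
    values: np.ndarray  # complex, Ohm

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.frequencies.shape != self.values.shape:
            raise ValueError("frequencies and values must have the same shape")
        if self.frequencies.size and np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.frequencies.size and self.frequencies[0] < 0:
            raise ValueError("frequencies must be >= 0")

    def __len__(self) -> int:
        return self.frequencies.size

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase_deg(self) -> np.ndarray:
        return np.degrees(np.angle(self.values))

    def restrict(self, f_low: float, f_high: float) -> "ImpedanceSpectrum":
        m = (self.frequencies >= f_low) & (self.frequencies <= f_high)
        return ImpedanceSpectrum(self.frequencies[m], self.values[m])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "frequency_Hz": self.frequencies,
                "real": self.values.real,
                "imag": self.values.imag,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ImpedanceSpectrum":
        df = pd.read_csv(path)
        for col in ("frequency_Hz", "real", "imag"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        order = np.argsort(df["frequency_Hz"].to_numpy())
        f = df["frequency_Hz"].to_numpy(dtype=float)[order]
        z = (df["real"].to_numpy(dtype=float) + 1j * df["imag"].to_numpy(dtype=float))[order]
        return cls(f, z)


@dataclass
class HarmonicSpectrum:
    """Two-sided Fourier series of a real periodic signal.

    ``coefficients[n]`` is :math:`c_n` for harmonic ``n`` of the fundamental
    ``f0`` under the convention :math:`x(t) = \\sum_n c_n e^{j 2\\pi n f_0 t}`
    with :math:`c_{-n} = \\overline{c_n}` implied (real signal).  The one-sided
    amplitude at harmonic ``n >= 1`` is ``2 |c_n|``.
    """

    f0: float
    coefficients: np.ndarray = field(default_factory=lambda: np.zeros(1, complex))

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        if self.f0 <= 0:
            raise ValueError("f0 must be > 0")
        if self.coefficients.ndim != 1 or self.coefficients.size < 1:
            raise ValueError("coefficients must be a non-empty 1-D array")
        if abs(self.coefficients[0].imag) > 1e-12 * max(
            1.0, np.max(np.abs(self.coefficients))
        ):
            raise ValueError("c_0 must be real for a real signal")
        self.coefficients[0] = self.coefficients[0].real

    @property
    def n_max(self) -> int:
        return self.coefficients.size - 1

    @property
    def harmonic_frequencies(self) -> np.ndarray:
        return self.f0 * np.arange(self.coefficients.size)

    def one_sided_amplitudes(self) -> np.ndarray:
        """Amplitudes ``[|c_0|, 2|c_1|, 2|c_2|, ...]``."""
        amps = 2.0 * np.abs(self.coefficients)
        amps[0] = abs(self.coefficients[0].real)
        return amps

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "frequency_Hz": self.harmonic_frequencies,
                "real": self.coefficients.real,
                "imag": self.coefficients.imag,
            }
        ).to_csv(path, index=False)
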