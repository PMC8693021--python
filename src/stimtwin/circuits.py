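"""Equivalent-circuit impedance models of the stimulation chamber.

The chamber (cell-culture medium + two electrode-electrolyte interfaces +
leads) is described by a composition tree of lumped elements: resistors,
inductors, capacitors and constant-phase elements (CPE), combined in series
or parallel.  The module provides

* closed-form impedance evaluation (AC and the DC limit),
* weighted complex nonlinear least-squares fitting of measured spectra,
* a linear Kramers-Kronig validity test (Voigt-ladder measurement model),
* a constrained "drift" refit that frees only lead inductance, medium
  resistance and double-layer capacitance — the parameter subset that can be
  identified from stimulation pulses alone,
* well-network arithmetic (n wells in series/parallel plus a shunt) with
  worst-case interval propagation,
* the capacitive-to-resistive cutoff frequency (-45 degree phase crossing).

Because both interfaces are electrically indistinguishable in a two-electrode
measurement, they are lumped into a single interface block.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import lmfit

from .spectra import ImpedanceSpectrum

__all__ = [
    "Parameter",
    "Resistor",
    "Inductor",
    "Capacitor",
    "CPE",
    "Series",
    "Parallel",
    "CircuitModel",
    "FitResult",
    "NetworkConfig",
    "KKResult",
    "circuit_impedance",
    "circuit_dc_impedance",
    "fit_spectrum",
    "refit_drift_subset",
    "kramers_kronig_validate",
    "network_impedance",
    "cutoff_frequency",
    "default_chamber_circuit",
    "circuit_to_dict",
    "circuit_from_dict",
]


@dataclass
class Parameter:
    """A fittable element parameter with bounds and a fixed/free flag."""

    value: float
    min: float = 0.0
    max: float = math.inf
    vary: bool = True
    role: str | None = None
    stderr: float | None = None

    def __post_init__(self) -> None:
        if not (self.min <= self.value <= self.max):
            raise ValueError(
                f"value {self.value} outside bounds [{self.min}, {self.max}]"
            )


class CircuitModel:
    """Base class for circuit tree nodes (elements and compositions)."""

    def impedance(self, frequencies: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def dc_impedance(self) -> float:
        raise NotImplementedError

    def parameters(self):
        """Yield ``(path_name, Parameter)`` pairs, depth-first."""
        yield from self._parameters("p")

    def _parameters(self, prefix):
        raise NotImplementedError

    def find_role(self, role: str) -> Parameter:
        for _, p in self.parameters():
            if p.role == role:
                return p
        raise KeyError(f"no parameter tagged with role {role!r}")

    def has_role(self, role: str) -> bool:
        try:
            self.find_role(role)
            return True
        except KeyError:
            return False

    def copy(self) -> "CircuitModel":
        return copy.deepcopy(self)


class _Element(CircuitModel):
    _param_names: tuple[str, ...] = ()

    def _parameters(self, prefix):
        for name in self._param_names:
            yield f"{prefix}_{name}", getattr(self, name)


class Resistor(_Element):
    _param_names = ("R",)

    def __init__(self, R: float | Parameter, role: str | None = None):
        self.R = R if isinstance(R, Parameter) else Parameter(R, role=role)
        if role is not None:
            self.R.role = role

    def impedance(self, frequencies):
        f = np.asarray(frequencies, dtype=float)
        return np.full(f.shape, self.R.value, dtype=complex)

    def dc_impedance(self):
        return self.R.value


class Inductor(_Element):
    _param_names = ("L",)

    def __init__(self, L: float | Parameter, role: str | None = None):
        self.L = L if isinstance(L, Parameter) else Parameter(L, role=role)
        if role is not None:
            self.L.role = role

    def impedance(self, frequencies):
        f = np.asarray(frequencies, dtype=float)
        return 2j * math.pi * f * self.L.value

    def dc_impedance(self):
        return 0.0


class Capacitor(_Element):
    _param_names = ("C",)

    def __init__(self, C: float | Parameter, role: str | None = None):
        self.C = C if isinstance(C, Parameter) else Parameter(C, role=role)
        if role is not None:
            self.C.role = role

    def impedance(self, frequencies):
        f = np.asarray(frequencies, dtype=float)
        return 1.0 / (2j * math.pi * f * self.C.value)

    def dc_impedance(self):
        return math.inf


class CPE(_Element):
    """Constant-phase element ``Z = 1 / (Q (j omega)^alpha)``.

    ``Q`` in S s^alpha; ``alpha`` in (0, 1].  ``alpha = 1`` is numerically a
    capacitor with C = Q.
    """

    _param_names = ("Q", "alpha")

    def __init__(
        self,
        Q: float | Parameter,
        alpha: float | Parameter = 1.0,
        role: str | None = None,
    ):
        self.Q = Q if isinstance(Q, Parameter) else Parameter(Q, role=role)
        if role is not None:
            self.Q.role = role
        self.alpha = (
            alpha if isinstance(alpha, Parameter) else Parameter(alpha, min=1e-3, max=1.0)
        )
        if not (0 < self.alpha.value <= 1.0):
            raise ValueError("alpha must be in (0, 1]")

    def impedance(self, frequencies):
        f = np.asarray(frequencies, dtype=float)
        return 1.0 / (self.Q.value * (2j * math.pi * f) ** self.alpha.value)

    def dc_impedance(self):
        return math.inf


class Series(CircuitModel):
    def __init__(self, children: list[CircuitModel]):
        if not children:
            raise ValueError("series node needs at least one child")
        self.children = list(children)

    def impedance(self, frequencies):
        return sum(c.impedance(frequencies) for c in self.children)

    def dc_impedance(self):
        total = 0.0
        for c in self.children:
            z = c.dc_impedance()
            if math.isinf(z):
                return math.inf
            total += z
        return total

    def _parameters(self, prefix):
        for k, c in enumerate(self.children):
            yield from c._parameters(f"{prefix}s{k}")


class Parallel(CircuitModel):
    def __init__(self, children: list[CircuitModel]):
        if not children:
            raise ValueError("parallel node needs at least one child")
        self.children = list(children)

    def impedance(self, frequencies):
        y = sum(1.0 / c.impedance(frequencies) for c in self.children)
        return 1.0 / y

    def dc_impedance(self):
        y = 0.0
        for c in self.children:
            z = c.dc_impedance()
            if not math.isinf(z):
                if z == 0.0:
                    return 0.0
                y += 1.0 / z
        return math.inf if y == 0.0 else 1.0 / y

    def _parameters(self, prefix):
        for k, c in enumerate(self.children):
            yield from c._parameters(f"{prefix}p{k}")


# ---------------------------------------------------------------------------
# evaluation


def circuit_impedance(model: CircuitModel, frequencies) -> ImpedanceSpectrum:
    """Evaluate the model impedance on a strictly positive frequency grid."""
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if np.any(f <= 0):
        raise ValueError(
            "frequencies must be > 0; use circuit_dc_impedance for the DC limit"
        )
    return ImpedanceSpectrum(f, model.impedance(f))


def circuit_dc_impedance(model: CircuitModel) -> float:
    """DC (omega -> 0) limit of the impedance; ``math.inf`` when blocking.

    Capacitors and CPEs open, inductors short.  An infinite result means the
    circuit blocks DC current entirely (zero predicted DC current under
    voltage control).
    """
    return model.dc_impedance()


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Outcome of a spectrum fit."""

    params: dict[str, float]
    stderr: dict[str, float | None]
    residual: float  # mean |Z_fit - Z| / |Z|
    success: bool
    n_free: int
    excluded: np.ndarray = dc_field(default_factory=lambda: np.zeros(0, bool))
    message: str = ""


def _collect_free(model: CircuitModel):
    return [(name, p) for name, p in model.parameters() if p.vary]


def fit_spectrum(
    model: CircuitModel,
    spectrum: ImpedanceSpectrum,
    weighting: str = "modulus",
    exclude: np.ndarray | None = None,
) -> FitResult:
    """Weighted complex nonlinear least squares of a circuit to a spectrum.

    Minimises ``sum_k w_k |Z_model(f_k) - Z_k|^2`` with ``w_k = 1/|Z_k|^2``
    (modulus weighting; ``weighting="none"`` for unweighted).  The model's
    parameter values are updated in place with the best fit; the residual
    metric reported is the mean relative deviation with respect to ``|Z|``.
    """
    if weighting not in ("modulus", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    free = _collect_free(model)
    if not free:
        raise ValueError("model has no free parameters")
    mask = np.ones(len(spectrum), dtype=bool)
    if exclude is not None:
        mask &= ~np.asarray(exclude, dtype=bool)
    f = spectrum.frequencies[mask]
    z = spectrum.values[mask]
    if f.size < 2 * len(free):
        raise ValueError(
            f"under-determined fit: {f.size} points for {len(free)} free parameters "
            "(need at least 2x)"
        )
    w = 1.0 / np.abs(z) if weighting == "modulus" else np.ones_like(f)

    lp = lmfit.Parameters()
    for name, p in free:
        lp.add(name, value=p.value, min=p.min, max=p.max)

    def apply(values):
        for name, p in free:
            p.value = float(values[name])

    def residual(pars):
        apply(pars.valuesdict())
        zm = model.impedance(f)
        d = (zm - z) * w
        return np.concatenate([d.real, d.imag])

    out = lmfit.minimize(residual, lp, method="least_squares")
    apply(out.params.valuesdict())
    stderr = {}
    for name, p in free:
        p.stderr = out.params[name].stderr
        stderr[name] = out.params[name].stderr
    rel = float(np.mean(np.abs(model.impedance(f) - z) / np.abs(z)))
    return FitResult(
        params={name: p.value for name, p in free},
        stderr=stderr,
        residual=rel,
        success=bool(out.success),
        n_free=len(free),
        excluded=~mask,
        message=getattr(out, "message", ""),
    )


DRIFT_ROLES = ("lead_inductance", "medium_resistance", "double_layer_capacitance")


def refit_drift_subset(model: CircuitModel, spectrum: ImpedanceSpectrum,
                       weighting: str = "modulus") -> FitResult:
    """Refit only the drift-identifiable subset of a calibrated model.

    Broadband spectra from stimulation pulses carry information in a limited
    frequency band, so a full refit is ill-posed.  Only the parameters tagged
    ``lead_inductance``, ``medium_resistance`` and ``double_layer_capacitance``
    are freed; everything else stays at its calibrated value.
    """
    tagged = []
    for role in DRIFT_ROLES:
        try:
            tagged.append(model.find_role(role))
        except KeyError as exc:
            raise ValueError(
                f"model lacks a parameter tagged {role!r}, required for drift refit"
            ) from exc
    saved = [(p, p.vary) for _, p in model.parameters()]
    try:
        for _, p in model.parameters():
            p.vary = False
        for p in tagged:
            p.vary = True
        return fit_spectrum(model, spectrum, weighting=weighting)
    finally:
        for p, v in saved:
            p.vary = v


# ---------------------------------------------------------------------------
# Kramers-Kronig validity


@dataclass
class KKResult:
    """Outcome of the linear Kramers-Kronig test."""

    valid: np.ndarray  # bool per input point (False outside f-range)
    residuals: np.ndarray  # relative residual per point (nan outside range)
    in_range: np.ndarray  # bool: point inside [f_low, f_high]
    n_elements: int
    threshold: float


def kramers_kronig_validate(
    spectrum: ImpedanceSpectrum,
    f_low: float = 10.0,
    f_high: float = 1e6,
    threshold: float = 0.01,
    per_decade: int = 7,
    fit_inductance: bool = True,
    fit_capacitance: bool = True,
) -> KKResult:
    """Linear Kramers-Kronig test of a measured impedance spectrum.

    Fits the KK-compliant measurement model — a ladder of Voigt ``R || C``
    elements with log-spaced time constants spanning the measured range, plus
    a series resistance, an optional series inductance and an optional series
    capacitance (needed for DC-blocking spectra) — by linear
    least squares with modulus weighting.  The ladder resistances may take
    either sign (standard lin-KK practice); any causal linear spectrum can be
    reproduced this way, so points whose relative residual exceeds
    ``threshold`` indicate non-causal/corrupted data.  Points outside
    ``[f_low, f_high]`` are pre-masked and never marked valid.
    """
    n = len(spectrum)
    if n < 10:
        raise ValueError("need at least 10 frequency points for the KK test")
    in_range = (spectrum.frequencies >= f_low) & (spectrum.frequencies <= f_high)
    f = spectrum.frequencies[in_range]
    z = spectrum.values[in_range]
    if f.size < 10:
        raise ValueError("fewer than 10 points inside [f_low, f_high]")
    w = 2.0 * math.pi * f
    decades = math.log10(f[-1] / f[0])

    def ladder_residuals(n_tau: int, fit_mask: np.ndarray) -> np.ndarray:
        taus = np.logspace(math.log10(1.0 / w[-1]), math.log10(1.0 / w[0]), n_tau)
        cols = [np.ones_like(f, dtype=complex)]  # series R
        if fit_inductance:
            cols.append(1j * w)  # series L
        if fit_capacitance:
            cols.append(1.0 / (1j * w))  # series 1/C (blocking spectra)
        for tau in taus:
            cols.append(1.0 / (1.0 + 1j * w * tau))
        A = np.column_stack(cols)
        weight = 1.0 / np.abs(z)
        Am, zm, wm = A[fit_mask], z[fit_mask], weight[fit_mask]
        Aw = np.concatenate([Am.real * wm[:, None], Am.imag * wm[:, None]])
        bw = np.concatenate([zm.real * wm, zm.imag * wm])
        coef, *_ = np.linalg.lstsq(Aw, bw, rcond=None)
        return np.abs(A @ coef - z) / np.abs(z)

    prev_res = None
    n_tau = max(3, int(math.ceil(per_decade * decades)))
    fit_all = np.ones(f.size, dtype=bool)
    for _ in range(4):
        res = ladder_residuals(n_tau, fit_all)
        mean_res = float(np.mean(res))
        if prev_res is not None and mean_res > 0.8 * prev_res:
            break  # residual stabilised
        prev_res = mean_res
        best = res
        best_n = n_tau
        n_tau += max(3, int(3 * decades))
    # Outlier-exclusion pass: a single corrupted point drags the weighted fit
    # and smears residuals onto its neighbours; refit on the conforming subset
    # and judge every point against that fit.
    for _ in range(3):
        outliers = best > threshold
        if not outliers.any() or outliers.all():
            break
        res = ladder_residuals(best_n, ~outliers)
        if np.array_equal(res > threshold, outliers):
            best = res
            break
        best = res
    residuals = np.full(n, np.nan)
    residuals[in_range] = best
    valid = np.zeros(n, dtype=bool)
    valid[in_range] = best <= threshold
    return KKResult(valid=valid, residuals=residuals, in_range=in_range,
                    n_elements=best_n, threshold=threshold)


# ---------------------------------------------------------------------------
# well networks


@dataclass
class NetworkConfig:
    """How the identical wells of the plate are wired together."""

    n_wells: int = 1
    connection: str = "single"  # {series, parallel, single}
    shunt_resistance: float = 0.0  # Ohm, in series with the total
    include_lead_inductance: bool = True

    def __post_init__(self) -> None:
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if self.connection not in ("series", "parallel", "single"):
            raise ValueError(f"unknown connection {self.connection!r}")
        if self.shunt_resistance < 0:
            raise ValueError("shunt_resistance must be >= 0")


def network_impedance(z_single, config: NetworkConfig):
    """Total impedance of ``n`` nominally identical wells plus a shunt.

    ``z_single`` may be a complex scalar or a ``(low, high)`` interval.  For
    intervals the worst-case rule is used: the lower bound assumes every well
    has the minimal single-well impedance and vice versa, so series maps
    ``low -> n*low`` and parallel ``low -> low/n``.
    """
    def combine(z):
        if config.connection == "series":
            total = config.n_wells * z
        elif config.connection == "parallel":
            total = z / config.n_wells
        else:
            total = z
        return total + config.shunt_resistance

    if isinstance(z_single, tuple):
        low, high = z_single
        if np.real(low) > np.real(high):
            raise ValueError("interval must be (low, high)")
        return (combine(low), combine(high))
    return combine(z_single)


# ---------------------------------------------------------------------------
# cutoff frequency


def cutoff_frequency(
    model: CircuitModel, f_min: float = 0.1, f_max: float = 1e7
) -> float:
    """Frequency of the capacitive-to-resistive transition.

    Defined as the -45 degree crossing of the total-impedance phase,
    root-bracketed on a log-frequency grid between ``f_min`` and ``f_max``.
    """
    from scipy.optimize import brentq

    grid = np.logspace(math.log10(f_min), math.log10(f_max), 600)
    phase = np.angle(model.impedance(grid), deg=True)
    g = phase + 45.0
    sign_change = np.nonzero(np.diff(np.sign(g)) != 0)[0]
    if sign_change.size == 0:
        raise ValueError(
            "no -45 degree phase crossing in "
            f"[{f_min:g}, {f_max:g}] Hz (phase range "
            f"[{phase.min():.1f}, {phase.max():.1f}] deg)"
        )
    k = sign_change[0]

    def fun(logf):
        return float(np.angle(model.impedance(np.array([10.0 ** logf])), deg=True)[0] + 45.0)

    return 10.0 ** brentq(fun, math.log10(grid[k]), math.log10(grid[k + 1]))


# ---------------------------------------------------------------------------
# defaults + serialization


def default_chamber_circuit(
    R_medium: float = 166.56,
    L_lead: float = 1.0e-6,
    Q_dl: float = 2.2e-6,
    alpha_dl: float = 0.8,
    R_ct: float | None = None,
    shunt_resistance: float | None = None,
) -> CircuitModel:
    """Representative calibrated chamber circuit.

    ``series[L_lead, R_medium, EEI]`` with the (lumped) electrode-electrolyte
    interface ``EEI = CPE`` by default — a blocking interface whose DC
    impedance is infinite, matching the observed suppression of DC current
    under voltage control.  Pass ``R_ct`` to add a faradaic charge-transfer
    path in parallel with the CPE, and ``shunt_resistance`` to include a
    series measurement shunt.

    The default values give a medium resistance equal to the fitted
    experimental single-well value (166.56 Ohm) and a capacitive-to-resistive
    cutoff in the 1-10 kHz band.
    """
    eei: CircuitModel = CPE(
        Parameter(Q_dl, min=1e-12, role="double_layer_capacitance"),
        Parameter(alpha_dl, min=0.3, max=1.0, vary=False),
    )
    if R_ct is not None:
        eei = Parallel([eei, Resistor(Parameter(R_ct, min=1e-3, role="charge_transfer"))])
    children = [
        Inductor(Parameter(L_lead, min=0.0, max=1e-3, role="lead_inductance")),
        Resistor(Parameter(R_medium, min=1e-3, role="medium_resistance")),
        eei,
    ]
    if shunt_resistance is not None:
        children.append(
            Resistor(Parameter(shunt_resistance, vary=False, role="shunt_resistance"))
        )
    return Series(children)


_ELEMENT_TYPES = {"R": Resistor, "L": Inductor, "C": Capacitor, "CPE": CPE}


def _param_to_dict(p: Parameter) -> dict:
    d = {"value": p.value, "vary": p.vary}
    if p.min != 0.0:
        d["min"] = p.min
    if not math.isinf(p.max):
        d["max"] = p.max
    if p.role is not None:
        d["role"] = p.role
    return d


def _param_from_dict(d) -> Parameter:
    if isinstance(d, (int, float)):
        return Parameter(float(d))
    return Parameter(
        value=float(d["value"]),
        min=float(d.get("min", 0.0)),
        max=float(d.get("max", math.inf)),
        vary=bool(d.get("vary", True)),
        role=d.get("role"),
    )


def circuit_to_dict(model: CircuitModel) -> dict:
    """Serialise a circuit tree to a plain nested dict (YAML/JSON friendly)."""
    if isinstance(model, Series):
        return {"series": [circuit_to_dict(c) for c in model.children]}
    if isinstance(model, Parallel):
        return {"parallel": [circuit_to_dict(c) for c in model.children]}
    if isinstance(model, Resistor):
        return {"type": "R", "R": _param_to_dict(model.R)}
    if isinstance(model, Inductor):
        return {"type": "L", "L": _param_to_dict(model.L)}
    if isinstance(model, Capacitor):
        return {"type": "C", "C": _param_to_dict(model.C)}
    if isinstance(model, CPE):
        return {"type": "CPE", "Q": _param_to_dict(model.Q),
                "alpha": _param_to_dict(model.alpha)}
    raise TypeError(f"cannot serialise {type(model).__name__}")


def circuit_from_dict(d: dict) -> CircuitModel:
    """Inverse of :func:`circuit_to_dict`."""
    if "series" in d:
        return Series([circuit_from_dict(c) for c in d["series"]])
    if "parallel" in d:
        return Parallel([circuit_from_dict(c) for c in d["parallel"]])
    t = d.get("type")
    if t == "R":
        return Resistor(_param_from_dict(d["R"]))
    if t == "L":
        return Inductor(_param_from_dict(d["L"]))
    if t == "C":
        return Capacitor(_param_from_dict(d["C"]))
    if t == "CPE":
        return CPE(_param_from_dict(d["Q"]), _param_from_dict(d["alpha"]))
    raise ValueError(f"unknown circuit node: {d!r}")
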