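"""Point-collocation polynomial-chaos uncertainty propagation.

Geometry and handling parameters of the chamber (electrode spacing, bottom
length, electrode heights, meniscus shape, medium volume) are uncertain;
each is modelled as an independent uniform distribution.  A polynomial-chaos
surrogate of total order ``p`` (default 4) is regressed onto model responses
at low-discrepancy (Hammersley) collocation nodes; means, variances and
first-order Sobol indices follow exactly from the expansion coefficients by
orthonormality, and percentiles by cheap sampling of the surrogate.

The collocation design uses ``N = 2 (M + 1)`` nodes with
``M = binom(p + d, d)`` basis terms — twice-oversampled regression, the
standard point-collocation rule.  For the chamber's six geometric parameters
at order 4 this gives 422 model runs; for the reduced three-parameter study
(spacing, bottom length, volume) 72 runs.

Only uniform distributions are implemented (orthonormal Legendre basis); the
``UncertainParameter`` container carries a distribution tag for future
extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from itertools import combinations_with_replacement

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = [
    "UncertainParameter",
    "UQResult",
    "PredictionInterval",
    "n_collocation_runs",
    "collocation_design",
    "fit_surrogate",
    "surrogate_stats",
    "adjust_for_conductivity",
    "PCExpansion",
    "DEFAULT_GEOMETRY_PARAMETERS",
    "REDUCED_GEOMETRY_PARAMETERS",
]


@dataclass
class UncertainParameter:
    """An uncertain scalar input with a uniform distribution."""

    name: str
    lower: float
    upper: float
    distribution: str = "uniform"

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValueError(f"{self.name}: lower bound must be < upper bound")
        if self.distribution != "uniform":
            raise NotImplementedError(
                "only uniform distributions are implemented"
            )


#: Chamber uncertainty assumptions: manufacturing (geometric) + handling.
DEFAULT_GEOMETRY_PARAMETERS = [
    UncertainParameter("electrode_height_1", 0.01, 1.5),
    UncertainParameter("electrode_height_2", 0.01, 1.5),
    UncertainParameter("bottom_length", 21.0, 22.3),
    UncertainParameter("electrode_spacing", 23.0, 25.0),
    UncertainParameter("meniscus_decay", 1.95, 2.05),
    UncertainParameter("meniscus_height_max", 1.8, 2.5),
]

#: Reduced study: the three parameters that dominate the current uncertainty.
REDUCED_GEOMETRY_PARAMETERS = [
    UncertainParameter("electrode_spacing", 23.0, 25.0),
    UncertainParameter("bottom_length", 21.0, 22.3),
    UncertainParameter("medium_volume", 3.4, 3.6),
]


@dataclass
class UQResult:
    """Surrogate-derived statistics for one observable."""

    observable: str
    mean: float
    variance: float
    sobol_first: dict[str, float]
    percentile_5: float
    percentile_95: float
    n_runs: int
    order: int
    percentile_convergence: float = 0.0  # rel. diff between sample sizes

    def __post_init__(self) -> None:
        if self.variance < -1e-12:
            raise ValueError("variance must be >= 0")
        for k, s in self.sobol_first.items():
            if not (-1e-9 <= s <= 1.0 + 1e-9):
                raise ValueError(f"Sobol index for {k} outside [0, 1]: {s}")
        total = sum(self.sobol_first.values())
        if total > 1.02:
            raise ValueError(f"first-order Sobol indices sum to {total} > 1.02")


@dataclass
class PredictionInterval:
    """A 90% prediction interval, optionally widened for conductivity."""

    low: float
    high: float
    kind: str  # {current, resistance, field}
    adjusted_low: float | None = None
    adjusted_high: float | None = None

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("low must be <= high")
        if self.kind not in ("current", "resistance", "field"):
            raise ValueError(f"unknown quantity kind {self.kind!r}")


def n_collocation_runs(order: int, n_params: int) -> int:
    """Number of model evaluations of the collocation design: 2 (M + 1),
    with M = binom(order + n_params, n_params) basis terms."""
    if order < 0 or n_params < 1:
        raise ValueError("order must be >= 0 and n_params >= 1")
    return 2 * (math.comb(order + n_params, n_params) + 1)


def _hammersley(n: int, d: int, seed: int | None = None) -> np.ndarray:
    """Hammersley point set in [0, 1]^d with a seeded Cranley-Patterson shift."""
    primes = [2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43]
    if d - 1 > len(primes):
        raise ValueError("too many dimensions for the prime table")
    pts = np.empty((n, d))
    pts[:, 0] = (np.arange(n) + 0.5) / n
    for j in range(1, d):
        base = primes[j - 1]
        idx = np.arange(n) + 1
        col = np.zeros(n)
        f = 1.0 / base
        i = idx.copy()
        while np.any(i > 0):
            col += f * (i % base)
            i //= base
            f /= base
        pts[:, j] = col
    if seed is not None:
        shift = np.random.default_rng(seed).random(d)
        pts = np.mod(pts + shift, 1.0)
    return pts


def collocation_design(
    params: list[UncertainParameter], order: int = 4, seed: int = 42
) -> np.ndarray:
    """Collocation nodes, shape ``(n_runs, n_params)``, inside the bounds."""
    if not params:
        raise ValueError("need at least one parameter")
    d = len(params)
    n = n_collocation_runs(order, d)
    u = _hammersley(n, d, seed=seed)
    lo = np.array([p.lower for p in params])
    hi = np.array([p.upper for p in params])
    return lo + u * (hi - lo)


def _multi_indices(order: int, d: int) -> list[tuple[int, ...]]:
    """All multi-indices of total degree <= order, graded order, zeros first."""
    out = [(0,) * d]
    for deg in range(1, order + 1):
        for combo in combinations_with_replacement(range(d), deg):
            idx = [0] * d
            for c in combo:
                idx[c] += 1
            out.append(tuple(idx))
    return out


def _eval_basis(x01: np.ndarray, indices) -> np.ndarray:
    """Orthonormal Legendre tensor basis on [0,1]^d at points ``x01``."""
    t = 2.0 * x01 - 1.0  # to [-1, 1]
    n, d = x01.shape
    max_deg = max(max(i) for i in indices)
    # uni[j][k] = sqrt(2k+1) P_k(t_j) per dimension
    uni = np.empty((d, max_deg + 1, n))
    for k in range(max_deg + 1):
        coef = np.zeros(k + 1)
        coef[k] = 1.0
        for j in range(d):
            uni[j, k] = math.sqrt(2 * k + 1) * npleg.legval(t[:, j], coef)
    B = np.empty((n, len(indices)))
    for m, idx in enumerate(indices):
        col = np.ones(n)
        for j, k in enumerate(idx):
            if k:
                col = col * uni[j, k]
        B[:, m] = col
    return B


@dataclass
class PCExpansion:
    """A fitted polynomial-chaos expansion over a uniform box."""

    params: list[UncertainParameter]
    order: int
    indices: list = dc_field(default_factory=list)
    coefficients: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))
    n_runs: int = 0
    lstsq_residual: float = 0.0

    def _to_unit(self, x: np.ndarray) -> np.ndarray:
        lo = np.array([p.lower for p in self.params])
        hi = np.array([p.upper for p in self.params])
        return (x - lo) / (hi - lo)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        B = _eval_basis(self._to_unit(x), self.indices)
        return B @ self.coefficients


def fit_surrogate(
    nodes: np.ndarray,
    responses: np.ndarray,
    params: list[UncertainParameter],
    order: int = 4,
) -> PCExpansion:
    """Least-squares regression of model responses onto the PC basis."""
    nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
    responses = np.asarray(responses, dtype=float)
    if nodes.shape[0] != responses.shape[0]:
        raise ValueError("one response per node required")
    indices = _multi_indices(order, len(params))
    if nodes.shape[0] < len(indices):
        raise ValueError(
            f"rank deficiency: {nodes.shape[0]} nodes for {len(indices)} basis terms"
        )
    exp = PCExpansion(params=params, order=order, indices=indices)
    B = _eval_basis(exp._to_unit(nodes), indices)
    coef, res, rank, _ = np.linalg.lstsq(B, responses, rcond=None)
    if rank < len(indices):
        raise ValueError("rank-deficient collocation design")
    exp.coefficients = coef
    exp.n_runs = nodes.shape[0]
    exp.lstsq_residual = float(np.sqrt(res[0]) if res.size else 0.0)
    return exp


def surrogate_stats(
    expansion: PCExpansion,
    observable: str = "observable",
    n_samples: tuple[int, int] = (10_000, 100_000),
    seed: int = 42,
    convergence_warn: float = 0.005,
) -> UQResult:
    """Mean/variance/Sobol from coefficients; percentiles by sampling.

    Mean is the constant coefficient; variance the sum of squared non-constant
    coefficients (orthonormal basis); the first-order Sobol index of parameter
    ``i`` sums the squared coefficients of basis terms involving only ``i``.
    The 5th/95th percentiles are estimated by sampling the surrogate at both
    sample sizes; a relative difference above ``convergence_warn`` triggers a
    warning.
    """
    import warnings

    c = expansion.coefficients
    mean = float(c[0])
    var = float(np.sum(c[1:] ** 2))
    d = len(expansion.params)
    sobol = {}
    for j, p in enumerate(expansion.params):
        s = 0.0
        for m, idx in enumerate(expansion.indices):
            if idx[j] > 0 and all(k == 0 for jj, k in enumerate(idx) if jj != j):
                s += c[m] ** 2
        sobol[p.name] = s / var if var > 0 else 0.0
    rng = np.random.default_rng(seed)
    lo = np.array([p.lower for p in expansion.params])
    hi = np.array([p.upper for p in expansion.params])
    percs = []
    for n in n_samples:
        x = lo + rng.random((n, d)) * (hi - lo)
        y = expansion(x)
        percs.append(np.percentile(y, [5.0, 95.0]))
    p5, p95 = percs[-1]
    scale = max(abs(p5), abs(p95), 1e-300)
    conv = float(np.max(np.abs(percs[-1] - percs[0])) / scale)
    if conv > convergence_warn:
        warnings.warn(
            f"percentile estimates differ by {conv:.2%} between sample sizes",
            stacklevel=2,
        )
    return UQResult(
        observable=observable,
        mean=mean,
        variance=var,
        sobol_first=sobol,
        percentile_5=float(p5),
        percentile_95=float(p95),
        n_runs=expansion.n_runs,
        order=expansion.order,
        percentile_convergence=conv,
    )


def adjust_for_conductivity(
    interval: PredictionInterval, sigma_rel_uncertainty: float = 0.02
) -> PredictionInterval:
    """Widen a prediction interval by the conductivity uncertainty.

    Currents and fields scale with the conductivity, so the bounds multiply
    by ``(1 -+ u)``; resistances scale with its inverse, so they divide by
    ``(1 +- u)``.
    """
    u = sigma_rel_uncertainty
    if u >= 1:
        raise ValueError("relative conductivity uncertainty must be < 1")
    if u < 0:
        raise ValueError("relative conductivity uncertainty must be >= 0")
    if interval.kind == "resistance":
        lo, hi = interval.low / (1 + u), interval.high / (1 - u)
    else:
        lo, hi = interval.low * (1 - u), interval.high * (1 + u)
    return PredictionInterval(
        low=interval.low, high=interval.high, kind=interval.kind,
        adjusted_low=lo, adjusted_high=hi,
    )
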