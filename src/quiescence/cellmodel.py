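"""Scaled cell population model with quiescence.

A cell arriving at the cell-cycle checkpoint commits to division with
probability beta1(E) (taking one unit of time, surviving with probability
e^{-mu}) or goes quiescent with probability beta2(E) = 1 - beta1(E);
quiescent cells re-enter the cycle at rate G(E).  The environmental
variable E (think: oxygen) is set quasi-statically by consumption, with
proliferating and quiescent cells weighted theta : 1 - theta:

    p(t) = 2 beta1(E(t)) e^{-mu} p(t-1) + G(E(t)) Q(t)
    Q'(t) = 2 beta2(E(t)) e^{-mu} p(t-1) - (mu + G(E(t))) Q(t)
    E(t) = 1 / (1 + theta * int_0^1 p(t-a) e^{-mu a} da + (1-theta) Q(t))

The expected number of checkpoint arrivals produced per arrival at fixed
environment E is

    R0(E) = 2 e^{-mu} (beta1(E) mu + G(E)) / (mu + G(E)),

and the nontrivial steady state Ebar is the unique root of R0(E) = 1 when
R0(0) < 1 < R0(1) and the monotonicity hypothesis
beta1'(E)(mu + G(E)) + G'(E)(1 - beta1(E)) > 0 holds on (0, 1).
Linearization about the steady state yields the scalar characteristic
equation lambda = a1 + (a2 + a3 lambda) e^{-lambda} with coefficients

    a1 = -mu - G(Ebar) + A(Ebar) (1 - 2 theta)/(1 - l theta)
    a2 = 2 e^{-mu} (mu beta1(Ebar) + G(Ebar) + A(Ebar) (3 theta/2 - 1)/(1 - l theta))
    a3 = 2 e^{-mu} beta1(Ebar)

where l = (3 e^{-mu} - 2)/(2 e^{-mu} - 1) and
A(Ebar) = (2 e^{-mu} mu/(2 e^{-mu} - 1) beta1'(Ebar) + G'(Ebar)) Ebar (1 - Ebar).
They satisfy the transcritical identity a1 + a2 = (1 - 2 e^{-mu}) A(Ebar).
"""

from __future__ import annotations

import cmath
import json
import math
import tomllib
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal

import numpy as np

from .chareq import Coefficients, char_value
from .dpartition import RegionVerdict, classify_point

__all__ = [
    "ResponseFunction",
    "CellModel",
    "SteadyState",
    "ModelError",
    "ExtinctionError",
    "UnboundedGrowthError",
    "HypothesisError",
    "R0",
    "solve_steady_state",
    "linearization_coeffs",
    "char_matrix_det",
    "assess_stability",
    "trivial_state_matrix_det",
    "load_model",
    "model_to_dict",
    "steady_state_report",
]


class ModelError(ValueError):
    """Invalid model specification or failed steady-state precondition."""


class ExtinctionError(ModelError):
    """R0(1) <= 1: the trivial state is stable and the population dies out."""


class UnboundedGrowthError(ModelError):
    """R0(0) >= 1: the population grows beyond any bound."""


class HypothesisError(ModelError):
    """The monotonicity hypothesis for uniqueness of the steady state fails."""


Family = Literal["constant", "hill_increasing", "linear_clamped"]

_FD_STEP = 1e-6


@dataclass(frozen=True)
class ResponseFunction:
    """Environmental response from a small parametric family.

    constant:        params (c,)              -> c
    hill_increasing: params (vmax, n, half)   -> vmax E^n / (E^n + half^n)
    linear_clamped:  params (a, b)            -> a + b E, clipped to >= 0

    Custom callables are accepted via ``family='custom'`` with ``func`` (and
    optionally ``deriv``); without an analytic derivative a central
    difference with step 1e-6 is used and a warning is issued.
    """

    family: str
    params: tuple[float, ...] = ()
    func: Callable[[float], float] | None = None
    deriv: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        n_expected = {"constant": 1, "hill_increasing": 3, "linear_clamped": 2}
        if self.family in n_expected:
            if len(self.params) != n_expected[self.family]:
                raise ModelError(
                    f"{self.family} takes {n_expected[self.family]} parameter(s)"
                )
            if self.family == "hill_increasing":
                vmax, n, half = self.params
                if vmax < 0 or n <= 0 or half <= 0:
                    raise ModelError("hill_increasing requires vmax>=0, n>0, half>0")
        elif self.family == "custom":
            if self.func is None:
                raise ModelError("custom response requires func")
            if self.deriv is None:
                warnings.warn(
                    "custom response without analytic derivative: using "
                    "central differences with step 1e-6",
                    stacklevel=2,
                )
        else:
            raise ModelError(f"unknown response family {self.family!r}")

    def value(self, E: float) -> float:
        if self.family == "constant":
            return self.params[0]
        if self.family == "hill_increasing":
            vmax, n, half = self.params
            if E <= 0.0:
                return 0.0
            # vmax / (1 + (half/E)^n), stable for extreme exponents
            t = n * (math.log(half) - math.log(E))
            if t > 700.0:
                return 0.0
            return vmax / (1.0 + math.exp(t))
        if self.family == "linear_clamped":
            a, b = self.params
            return max(a + b * E, 0.0)
        return float(self.func(E))  # type: ignore[misc]

    def derivative(self, E: float) -> float:
        if self.family == "constant":
            return 0.0
        if self.family == "hill_increasing":
            vmax, n, half = self.params
            if E == 0.0:
                return float("inf") if n < 1 else (vmax / half if n == 1 else 0.0)
            # vmax n r / (E (1 + r)^2) with r = (half/E)^n
            t = n * (math.log(half) - math.log(E))
            if abs(t) > 350.0:  # r/(1+r)^2 ~ exp(-|t|)
                return vmax * n * math.exp(-abs(t)) / E
            r = math.exp(t)
            return vmax * n * r / (E * (1.0 + r) ** 2)
        if self.family == "linear_clamped":
            a, b = self.params
            return b if a + b * E > 0 else 0.0
        if self.deriv is not None:
            return float(self.deriv(E))
        return (self.value(E + _FD_STEP) - self.value(E - _FD_STEP)) / (2 * _FD_STEP)


@dataclass(frozen=True)
class CellModel:
    """Death rate mu, consumption weight theta, and the responses beta1, G.

    beta2 is never stored: beta2(E) = 1 - beta1(E).  The delay is 1 by the
    time scaling.  Validation checks beta1 range in [0, 1) and G > 0 on a
    grid over [0, 1]; pass validate=False for boundary/diagnostic
    constructions (e.g. beta1 == 1).
    """

    death_rate: float
    theta: float
    beta1: ResponseFunction
    G: ResponseFunction
    validate: bool = True

    def __post_init__(self) -> None:
        if self.death_rate < 0 or not math.isfinite(self.death_rate):
            raise ModelError("death_rate must be finite and >= 0")
        if not 0.0 <= self.theta <= 1.0:
            raise ModelError("theta must lie in [0, 1]")
        if self.validate:
            Es = np.linspace(0.0, 1.0, 101)
            b = np.array([self.beta1.value(E) for E in Es])
            g = np.array([self.G.value(E) for E in Es])
            if b.min() < 0 or b.max() >= 1.0:
                raise ModelError("beta1 must take values in [0, 1)")
            if g.min() < 0 or (g.max() == 0 and self.death_rate == 0):
                raise ModelError("G must be nonnegative (positive if mu = 0)")

    @property
    def survival(self) -> float:
        """2 e^{-mu}: expected progeny per committed division."""
        return 2.0 * math.exp(-self.death_rate)

    @property
    def ell(self) -> float:
        """l = (3 e^{-mu} - 2)/(2 e^{-mu} - 1), in (-inf, 1) when
        2 e^{-mu} > 1."""
        em = math.exp(-self.death_rate)
        return (3.0 * em - 2.0) / (2.0 * em - 1.0)


@dataclass(frozen=True)
class SteadyState:
    """Nontrivial steady state and its linearization ingredients."""

    Ebar: float
    pbar: float
    Qbar: float
    K: float
    l: float
    A: float


def R0(E: float, m: CellModel) -> float:
    """Basic reproduction number at fixed environment E."""
    mu = m.death_rate
    g = m.G.value(E)
    if mu == 0.0 and g == 0.0:
        raise ModelError("R0 undefined for mu = 0 with G(E) = 0")
    return m.survival * (m.beta1.value(E) * mu + g) / (mu + g)


def _check_hypothesis(m: CellModel, grid_n: int = 1001) -> None:
    """Grid surrogate for beta1'(E)(mu+G(E)) + G'(E)(1-beta1(E)) > 0 on
    (0, 1)."""
    mu = m.death_rate
    Es = np.linspace(0.0, 1.0, grid_n)
    vals = np.array(
        [
            m.beta1.derivative(E) * (mu + m.G.value(E))
            + m.G.derivative(E) * (1.0 - m.beta1.value(E))
            for E in Es
        ]
    )
    interior = vals[1:-1]
    # strictly positive responses can underflow to 0 at the ends of [0, 1]
    # (e.g. steep Hill); reject only genuine violations: a negative value,
    # or a response flat on all of (0, 1)
    if interior.min() < 0 or not (interior > 0).any():
        raise HypothesisError(
            "monotonicity hypothesis beta1'(E)(mu+G(E)) + G'(E)(1-beta1(E)) > 0 "
            "fails on (0, 1): steady-state uniqueness is not guaranteed"
        )


def solve_steady_state(m: CellModel, tol: float = 1e-12) -> SteadyState:
    """Unique nontrivial steady state: Ebar solves R0(E) = 1 by bisection on
    [0, 1]; then

        K = (1/Ebar - 1) / ((1 - 2 e^{-mu} beta1(Ebar)) (1 - l theta))
        (pbar, Qbar) = (1/Ebar - 1)/(1 - l theta) * (mu/(2 e^{-mu} - 1), 1)

    Requires R0(0) < 1 < R0(1) (which forces 2 e^{-mu} > 1) and the
    monotonicity hypothesis; distinct errors identify the extinction regime
    (R0(1) <= 1), the unbounded growth regime (R0(0) >= 1), and a
    hypothesis failure.
    """
    mu = m.death_rate
    if R0(1.0, m) <= 1.0:
        raise ExtinctionError(
            "R0(1) <= 1: extinction regime, no nontrivial steady state"
        )
    if R0(0.0, m) >= 1.0:
        raise UnboundedGrowthError(
            "R0(0) >= 1: unbounded growth regime, no nontrivial steady state"
        )
    _check_hypothesis(m)

    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if R0(mid, m) < 1.0:
            lo = mid
        else:
            hi = mid
    Ebar = 0.5 * (lo + hi)

    em = math.exp(-mu)
    b1 = m.beta1.value(Ebar)
    if not 2.0 * em * b1 < 1.0:
        raise ModelError("inconsistent state: 2 e^{-mu} beta1(Ebar) >= 1")
    l = m.ell
    denom = 1.0 - l * m.theta
    K = (1.0 / Ebar - 1.0) / ((1.0 - 2.0 * em * b1) * denom)
    fac = (1.0 / Ebar - 1.0) / denom
    pbar = fac * mu / (2.0 * em - 1.0)
    Qbar = fac
    A = (
        (2.0 * em * mu / (2.0 * em - 1.0)) * m.beta1.derivative(Ebar)
        + m.G.derivative(Ebar)
    ) * Ebar * (1.0 - Ebar)
    return SteadyState(Ebar=Ebar, pbar=pbar, Qbar=Qbar, K=K, l=l, A=A)


def linearization_coeffs(m: CellModel, ss: SteadyState) -> Coefficients:
    """Coefficients (a1, a2, a3) of the scalar characteristic equation at
    the nontrivial steady state (formulas in the module docstring)."""
    mu = m.death_rate
    em = math.exp(-mu)
    g = m.G.value(ss.Ebar)
    b1 = m.beta1.value(ss.Ebar)
    denom = 1.0 - ss.l * m.theta
    a1 = -mu - g + ss.A * (1.0 - 2.0 * m.theta) / denom
    a2 = 2.0 * em * (mu * b1 + g + ss.A * (1.5 * m.theta - 1.0) / denom)
    a3 = 2.0 * em * b1
    return Coefficients(a1, a2, a3)


def _expm1_ratio(z: complex) -> complex:
    """(1 - e^{-z})/z, extended by its limit 1 at z = 0."""
    z = complex(z)
    if abs(z) < 1e-8:
        return 1.0 - z / 2.0 + z * z / 6.0
    if z.imag == 0.0:
        return -math.expm1(-z.real) / z.real
    return (1.0 - cmath.exp(-z)) / z


def char_matrix_det(lam: complex, m: CellModel, ss: SteadyState) -> complex:
    """Determinant of the 2x2 characteristic matrix of the linearized
    (p, Q) system; its zero set coincides with that of the scalar
    characteristic function under linearization_coeffs.  The removable
    singularity at lambda = -mu is filled by the limit of (1-e^{-z})/z."""
    mu = m.death_rate
    em = math.exp(-mu)
    g = m.G.value(ss.Ebar)
    b1 = m.beta1.value(ss.Ebar)
    denom = 1.0 - ss.l * m.theta
    athe = ss.A * m.theta / denom
    aone = ss.A * (1.0 - m.theta) / denom
    el = cmath.exp(-complex(lam))
    q = _expm1_ratio(complex(lam) + mu)
    m11 = 1.0 - 2.0 * em * b1 * el + athe * q
    m12 = -g + aone
    m21 = 2.0 * em * (b1 - 1.0) * el - athe * q
    m22 = complex(lam) + mu + g - aone
    return m11 * m22 - m12 * m21


def trivial_state_matrix_det(E: float, m: CellModel) -> float:
    """Determinant of the steady-state matrix of the frozen-environment
    linear system; equals (mu + G(E)) (R0(E) - 1), so it vanishes exactly
    on the R0(E) = 1 locus."""
    mu = m.death_rate
    em = math.exp(-mu)
    b1 = m.beta1.value(E)
    g = m.G.value(E)
    return (1.0 - 2.0 * em * b1) * (-(mu + g)) - (-g) * (2.0 * em * (1.0 - b1))


def assess_stability(
    m: CellModel, boundary_tol: float = 1e-8
) -> tuple[RegionVerdict, Coefficients, SteadyState]:
    """solve_steady_state -> linearization_coeffs -> classify_point."""
    ss = solve_steady_state(m)
    c = linearization_coeffs(m, ss)
    verdict = classify_point(c.alpha1, c.alpha2, c.alpha3, boundary_tol)
    return verdict, c, ss


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

_MODEL_KEYS = {"death_rate", "theta", "beta1", "G"}
_RF_KEYS = {"family", "params"}


def _response_from_dict(d: dict) -> ResponseFunction:
    unknown = set(d) - _RF_KEYS
    if unknown:
        raise ModelError(f"unknown response keys: {sorted(unknown)}")
    return ResponseFunction(family=d["family"], params=tuple(d["params"]))


def model_from_dict(d: dict) -> CellModel:
    unknown = set(d) - _MODEL_KEYS
    if unknown:
        raise ModelError(f"unknown model config keys: {sorted(unknown)}")
    missing = _MODEL_KEYS - set(d)
    if missing:
        raise ModelError(f"missing model config keys: {sorted(missing)}")
    return CellModel(
        death_rate=float(d["death_rate"]),
        theta=float(d["theta"]),
        beta1=_response_from_dict(d["beta1"]),
        G=_response_from_dict(d["G"]),
    )


def model_to_dict(m: CellModel) -> dict:
    return {
        "death_rate": m.death_rate,
        "theta": m.theta,
        "beta1": {"family": m.beta1.family, "params": list(m.beta1.params)},
        "G": {"family": m.G.family, "params": list(m.G.params)},
    }


def load_model(path: str | Path) -> CellModel:
    """Read a model config from TOML (default) or JSON (.json)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        d = json.loads(path.read_text())
    else:
        with open(path, "rb") as fh:
            d = tomllib.load(fh)
    return model_from_dict(d)


def steady_state_report(m: CellModel) -> dict:
    """JSON-ready report: SteadyState fields plus the coefficients."""
    ss = solve_steady_state(m)
    c = linearization_coeffs(m, ss)
    return {
        "Ebar": ss.Ebar,
        "pbar": ss.pbar,
        "Qbar": ss.Qbar,
        "K": ss.K,
        "l": ss.l,
        "A": ss.A,
        "alpha1": c.alpha1,
        "alpha2": c.alpha2,
        "alpha3": c.alpha3,
    }
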