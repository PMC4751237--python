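"""From coefficient plane to model-parameter planes.

One-parameter study: since R0 is independent of theta, so are Ebar, a3 and
the sum a1 + a2 = (1 - 2 e^{-mu}) A(Ebar); varying theta moves (a1, a2)
along that line, north-west as theta grows (a1 is strictly decreasing in
theta because l < 1).  The line meets the Hopf boundary C0(a3) where

    w/sin(w) (cos w - 1) = (1 - 2 e^{-mu}) / (1 + 2 e^{-mu} beta1(Ebar)) * A(Ebar)

whose left side decreases from 0 to -inf on (0, pi), so the Hopf frequency
w* is unique; the corresponding abscissa is abar1 = c1(w*, a3).  Comparing
abar1 with the theta = 1/2 abscissa -mu - G(Ebar) yields the critical
consumption weight: if -mu - G(Ebar) > abar1 there is a unique
theta_crit in (1/2, 2/3) below which the steady state is unstable.

Two-parameter maps: with beta1 constant (regulation through the quiescence
exit rate G) each boundary point (a1, a2) maps to

    theta  = (a2 - mu a3 + 2 e^{-mu}(a1 + mu))
             / (3 e^{-mu}(a1 + mu) + 2 (a2 - mu a3) - e^{-mu} G(Ebar))
    G'(Ebar) = (a1 + mu + G(Ebar)) / (Ebar (1 - Ebar)) * (1 - l theta)/(1 - 2 theta)

and with G constant (regulation through quiescence entry) the slope
beta1'(Ebar) is the same expression times (2 e^{-mu} - 1)/(2 e^{-mu} mu).
Points at the theta = 1/2 pole are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .chareq import Coefficients
from .dpartition import BoundaryCurve, c_point
from .cellmodel import CellModel, SteadyState, linearization_coeffs

__all__ = [
    "ThetaStudy",
    "ModelPlaneCurve",
    "theta_path",
    "hopf_point",
    "theta_crit",
    "theta_study",
    "map_C0_to_model_plane",
]

_POLE_TOL = 1e-10


@dataclass(frozen=True)
class ThetaStudy:
    """Summary of the one-parameter consumption-weight study."""

    omega_star: float
    alpha1_bar: float
    theta_crit: float | None
    thetas: np.ndarray
    line: np.ndarray  # (n, 2): (a1(theta), a2(theta))


@dataclass(frozen=True)
class ModelPlaneCurve:
    """Image of a boundary curve in a (response slope, theta) plane."""

    case: Literal["g_regulated", "beta1_regulated"]
    source_branch: str
    omega: np.ndarray
    points: np.ndarray  # (n, 2): (slope, theta)
    out_of_range: np.ndarray  # bool, theta outside [0, 1] before reporting
    n_dropped: int  # points at the theta = 1/2 pole


def theta_path(
    m: CellModel, ss: SteadyState, thetas: list[float] | np.ndarray
) -> list[Coefficients]:
    """Coefficients along the theta line: only theta varies, Ebar (hence a3
    and a1 + a2) stays fixed."""
    out = []
    for th in thetas:
        m_th = CellModel(
            death_rate=m.death_rate,
            theta=float(th),
            beta1=m.beta1,
            G=m.G,
            validate=False,
        )
        out.append(linearization_coeffs(m_th, ss))
    return out


def _hopf_lhs(omega: float) -> float:
    # w/sin(w) (cos w - 1): 0 at w=0, decreasing to -inf at w=pi
    if omega == 0.0:
        return 0.0
    return omega / math.sin(omega) * (math.cos(omega) - 1.0)


def hopf_point(m: CellModel, ss: SteadyState) -> tuple[float, float]:
    """Hopf frequency w* in (0, pi) where the theta line crosses C0(a3),
    and the crossing abscissa abar1 = c1(w*, a3)."""
    mu = m.death_rate
    em = math.exp(-mu)
    if not 2.0 * em > 1.0:
        raise ValueError("hopf_point requires 2 e^{-mu} > 1")
    if not ss.A > 0:
        raise ValueError("hopf_point requires A(Ebar) > 0")
    a3 = 2.0 * em * m.beta1.value(ss.Ebar)
    rhs = (1.0 - 2.0 * em) / (1.0 + a3) * ss.A  # < 0

    hi = math.pi - 1e-13
    while _hopf_lhs(hi) > rhs:  # rounding guard at the pole
        hi = (hi + math.pi) / 2
    w = brentq(lambda om: _hopf_lhs(om) - rhs, 0.0, hi, xtol=1e-13)
    a1bar = c_point(w, a3)[0]
    return float(w), float(a1bar)


def _alpha1_of_theta(th: float, mu: float, g: float, A: float, l: float) -> float:
    return -mu - g + A * (1.0 - 2.0 * th) / (1.0 - l * th)


def theta_crit(m: CellModel, ss: SteadyState) -> float | None:
    """Critical consumption weight, or None when the steady state is stable
    on all of theta in [1/2, 1].

    None iff -mu - G(Ebar) < abar1 (the theta = 1/2 point already lies left
    of the Hopf crossing); otherwise the unique theta in (1/2, 2/3) with
    a1(theta) = abar1, by bisection (a1 is strictly decreasing in theta).
    """
    _, a1bar = hopf_point(m, ss)
    mu = m.death_rate
    g = m.G.value(ss.Ebar)
    if -mu - g < a1bar:
        return None
    f = lambda th: _alpha1_of_theta(th, mu, g, ss.A, ss.l) - a1bar
    return float(brentq(f, 0.5, 2.0 / 3.0, xtol=1e-10))


def theta_study(
    m: CellModel, ss: SteadyState, n_theta: int = 201
) -> ThetaStudy:
    """Assemble the one-parameter study on a uniform theta grid on [0, 1]."""
    w, a1bar = hopf_point(m, ss)
    tc = theta_crit(m, ss)
    thetas = np.linspace(0.0, 1.0, n_theta)
    coeffs = theta_path(m, ss, thetas)
    line = np.array([(c.alpha1, c.alpha2) for c in coeffs])
    return ThetaStudy(
        omega_star=w, alpha1_bar=a1bar, theta_crit=tc, thetas=thetas, line=line
    )


def beta1_slope_factor(mu: float) -> float:
    """(2 e^{-mu} - 1)/(2 e^{-mu} mu): ratio of the beta1-regulated slope
    to the g-regulated slope, fully determined by mu."""
    em = math.exp(-mu)
    return (2.0 * em - 1.0) / (2.0 * em * mu)


def map_C0_to_model_plane(
    case: Literal["g_regulated", "beta1_regulated"],
    mu: float,
    Ebar: float,
    g_at_Ebar: float,
    curve: BoundaryCurve,
) -> ModelPlaneCurve:
    """Map a critical curve from the (a1, a2) plane to (slope, theta).

    ``Ebar`` and ``g_at_Ebar`` are the calibrated steady state and the level
    G(Ebar) (for beta1_regulated, G is the constant level itself).  Points
    with |1 - 2 theta| below tolerance (the pole of the slope expression)
    are dropped; thetas outside [0, 1] are kept but flagged.
    """
    em = math.exp(-mu)
    l = (3.0 * em - 2.0) / (2.0 * em - 1.0)
    a3 = curve.alpha3
    a1 = curve.points[:, 0]
    a2 = curve.points[:, 1]

    num = a2 - mu * a3 + 2.0 * em * (a1 + mu)
    den = 3.0 * em * (a1 + mu) + 2.0 * (a2 - mu * a3) - em * g_at_Ebar
    theta = num / den
    keep = np.abs(1.0 - 2.0 * theta) >= _POLE_TOL
    n_dropped = int((~keep).sum())

    theta = theta[keep]
    a1k = a1[keep]
    omega = curve.omega[keep] if curve.omega.size else np.full(keep.sum(), np.nan)
    slope = (
        (a1k + mu + g_at_Ebar)
        / (Ebar * (1.0 - Ebar))
        * (1.0 - l * theta)
        / (1.0 - 2.0 * theta)
    )
    if case == "beta1_regulated":
        slope = slope * beta1_slope_factor(mu)
    elif case != "g_regulated":
        raise ValueError(f"unknown case {case!r}")

    out_of_range = (theta < 0.0) | (theta > 1.0)
    return ModelPlaneCurve(
        case=case,
        source_branch=curve.branch,
        omega=omega,
        points=np.column_stack([slope, theta]),
        out_of_range=out_of_range,
        n_dropped=n_dropped,
    )
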