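"""Worked model instances.

The reference setting used throughout the two-parameter case studies is
mu = 0.5, constant beta1 = 0.5 and steady state Ebar = 0.5.  With beta1
constant the steady-state condition R0(Ebar) = 1 pins the level

    G(Ebar) = (1 - a3) mu / (2 e^{-mu} - 1),   a3 = 2 e^{-mu} beta1,

so a Hill reactivation rate G(E) = vmax E^n / (E^n + half^n) with
half = Ebar is calibrated by choosing vmax to hit that level; the Hill
exponent n then sets the steepness G'(Ebar) = n G(Ebar) / (2 Ebar) without
moving Ebar.  Steep response (large n) destabilizes the steady state for
small theta; shallow response leaves it stable for all theta >= 1/2.
"""

from __future__ import annotations

import math

from .cellmodel import CellModel, ResponseFunction

__all__ = ["make_fixture", "calibrated_g_model", "calibrated_beta1_model"]


def g_level_at_steady_state(mu: float, beta1: float) -> float:
    """G(Ebar) required by R0(Ebar) = 1 for constant beta1."""
    em = math.exp(-mu)
    a3 = 2.0 * em * beta1
    return (1.0 - a3) * mu / (2.0 * em - 1.0)


def calibrated_g_model(
    mu: float = 0.5,
    beta1: float = 0.5,
    Ebar: float = 0.5,
    hill_n: float = 2.0,
    theta: float = 0.8,
) -> CellModel:
    """Constant beta1, Hill G calibrated so the steady state sits at Ebar."""
    target = g_level_at_steady_state(mu, beta1)
    if target <= 0:
        raise ValueError("calibration requires 2 e^{-mu} beta1 < 1 and mu > 0")
    vmax = target * (Ebar**hill_n + Ebar**hill_n) / Ebar**hill_n  # half = Ebar
    return CellModel(
        death_rate=mu,
        theta=theta,
        beta1=ResponseFunction("constant", (beta1,)),
        G=ResponseFunction("hill_increasing", (vmax, hill_n, Ebar)),
    )


def calibrated_beta1_model(
    mu: float = 0.5,
    g_const: float | None = None,
    Ebar: float = 0.5,
    hill_n: float = 2.0,
    theta: float = 0.8,
) -> CellModel:
    """Constant G, Hill beta1 calibrated so the steady state sits at Ebar.

    R0(Ebar) = 1 requires 2 e^{-mu} beta1(Ebar) = 1 + G (1 - 2 e^{-mu})/mu;
    by default G is chosen so that beta1(Ebar) = 0.5 (mirroring the
    reference setting), i.e. G = g_level_at_steady_state(mu, 0.5).
    """
    em = math.exp(-mu)
    if g_const is None:
        g_const = g_level_at_steady_state(mu, 0.5)
    b_target = (1.0 + g_const * (1.0 - 2.0 * em) / mu) / (2.0 * em)
    if not 0.0 < b_target < 1.0:
        raise ValueError("calibration target beta1(Ebar) outside (0, 1)")
    vmax = b_target * 2.0  # Hill with half = Ebar gives value vmax/2 at Ebar
    if vmax >= 1.0:
        vmax = b_target * (Ebar**hill_n + Ebar**hill_n) / Ebar**hill_n
    return CellModel(
        death_rate=mu,
        theta=theta,
        beta1=ResponseFunction("hill_increasing", (vmax, hill_n, Ebar)),
        G=ResponseFunction("constant", (g_const,)),
    )


def make_fixture(name: str, **overrides) -> CellModel:
    """Named worked examples.

    fig4       -- mu=0.5, constant beta1=0.5, Hill G calibrated to Ebar=0.5
                  (moderate steepness, n=2); stable at the default theta=0.8.
    shallow    -- same but n=1: stable for every theta in [1/2, 1].
    steep      -- same but n=100: a critical theta in (1/2, 2/3) exists.
    extinction -- R0(1) < 1 (mu = 1 makes 2 e^{-mu} < 1).
    blowup     -- R0(0) > 1 (constant responses with high reactivation).

    Overrides are forwarded to the underlying constructor (fig4/shallow/
    steep accept mu, beta1, Ebar, hill_n, theta).
    """
    if name == "fig4":
        return calibrated_g_model(**overrides)
    if name == "shallow":
        overrides.setdefault("hill_n", 1.0)
        return calibrated_g_model(**overrides)
    if name == "steep":
        overrides.setdefault("hill_n", 100.0)
        return calibrated_g_model(**overrides)
    if name == "extinction":
        overrides.setdefault("mu", 1.0)
        overrides.setdefault("theta", 0.8)
        return CellModel(
            death_rate=overrides["mu"],
            theta=overrides["theta"],
            beta1=ResponseFunction("constant", (0.5,)),
            G=ResponseFunction("hill_increasing", (1.0, 2.0, 0.5)),
        )
    if name == "blowup":
        overrides.setdefault("mu", 0.1)
        overrides.setdefault("theta", 0.8)
        return CellModel(
            death_rate=overrides["mu"],
            theta=overrides["theta"],
            beta1=ResponseFunction("constant", (0.45,)),
            G=ResponseFunction("constant", (1.0,)),
        )
    raise ValueError(f"unknown fixture {name!r}")
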