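"""The characteristic function Delta(lambda) = lambda - a1 - (a2 + a3*lambda)e^{-lambda}.

This transcendental equation governs linear stability of steady states of a
coupled renewal/delay system with a neutral term a3*lambda*e^{-lambda}.  For
|a3| < 1 every root in the closed right half-plane obeys the a priori bound
|lambda| <= (|a1|+|a2|)/(1-|a3|), which makes exhaustive numerical root
location and argument-principle counting possible on a finite contour.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Coefficients",
    "ComplexRoot",
    "RootCount",
    "ContourError",
    "char_value",
    "char_derivative",
    "modulus_bound",
    "count_unstable_roots",
    "find_roots",
    "multiplicity_at_zero",
]


class ContourError(RuntimeError):
    """A zero of Delta stayed within tolerance of the counting contour."""


@dataclass(frozen=True)
class Coefficients:
    """The triple (a1, a2, a3) of the characteristic equation."""

    alpha1: float
    alpha2: float
    alpha3: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "alpha3"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def region_valid(self) -> bool:
        """True iff |a3| < 1, the regime in which the stability region
        S(a3) is bounded by a half-line and critical curves and the modulus
        bound applies.  Evaluation of Delta itself needs no restriction."""
        return abs(self.alpha3) < 1.0


@dataclass(frozen=True)
class ComplexRoot:
    """A root mu + i*omega of Delta, reported with omega >= 0.

    When omega > 0 the complex conjugate is implied (Delta has real
    coefficients).  ``residual`` is |Delta| at the reported location.
    """

    re: float
    im: float
    residual: float
    multiplicity: int = 1

    def as_complex(self) -> complex:
        return complex(self.re, self.im)


@dataclass(frozen=True)
class RootCount:
    """Result of argument-principle root counting on the right half-plane.

    ``n_unstable`` counts zeros (with multiplicity) with Re lambda > margin;
    zeros within ``margin`` of the imaginary axis are listed in ``marginal``
    and not counted.  Every counted zero has modulus <= ``bound_radius``.
    """

    n_unstable: int
    marginal: tuple[ComplexRoot, ...] = field(default_factory=tuple)
    bound_radius: float = 0.0


def char_value(lam: complex, c: Coefficients) -> complex:
    """Delta(lambda) = lambda - a1 - (a2 + a3*lambda) e^{-lambda}.

    Entire in lambda; commutes with complex conjugation.
    """
    lam = complex(lam)
    return lam - c.alpha1 - (c.alpha2 + c.alpha3 * lam) * cmath.exp(-lam)


def char_derivative(lam: complex, c: Coefficients, order: int = 1) -> complex:
    """Closed-form derivative of Delta of the given order (1, 2 or 3).

    Delta'(lam)  = 1 + (a2 - a3 + a3*lam) e^{-lam}
    Delta''(lam) = (2 a3 - a2 - a3*lam) e^{-lam}
    Delta'''(lam)= (a2 - 3 a3 + a3*lam) e^{-lam}
    """
    lam = complex(lam)
    e = cmath.exp(-lam)
    if order == 1:
        return 1.0 + (c.alpha2 - c.alpha3 + c.alpha3 * lam) * e
    if order == 2:
        return (2.0 * c.alpha3 - c.alpha2 - c.alpha3 * lam) * e
    if order == 3:
        return (c.alpha2 - 3.0 * c.alpha3 + c.alpha3 * lam) * e
    raise ValueError("order must be 1, 2 or 3")


def _char_value_array(lam: np.ndarray, c: Coefficients) -> np.ndarray:
    return lam - c.alpha1 - (c.alpha2 + c.alpha3 * lam) * np.exp(-lam)


def modulus_bound(c: Coefficients) -> float:
    """A priori bound (|a1|+|a2|)/(1-|a3|) on |lambda| for any root with
    Re lambda >= 0; requires |a3| < 1 (for |a3| > 1 there are infinitely
    many right half-plane roots and no such bound exists)."""
    if not c.region_valid:
        raise ValueError(
            "modulus bound undefined for |alpha3| >= 1: the equation has "
            "infinitely many right half-plane roots in that regime"
        )
    return (abs(c.alpha1) + abs(c.alpha2)) / (1.0 - abs(c.alpha3))


def multiplicity_at_zero(c: Coefficients, tol: float = 1e-9) -> int:
    """Multiplicity of lambda = 0 as a root of Delta: 0, 1, 2 or 3.

    lambda = 0 is a root iff a1 + a2 = 0; a double root iff additionally
    a2 = a3 - 1; a triple root iff additionally a3 = -1.  (The Taylor
    coefficients of Delta at 0 are -(a1+a2), 1 - a3 + a2, and a3 - a2/2.)
    Comparisons are exact up to ``tol``.
    """
    if abs(c.alpha1 + c.alpha2) > tol:
        return 0
    if abs(c.alpha2 - (c.alpha3 - 1.0)) > tol:
        return 1
    if abs(c.alpha3 + 1.0) > tol:
        return 2
    return 3


# ---------------------------------------------------------------------------
# Root finding: grid-seeded damped Newton iteration
# ---------------------------------------------------------------------------

_NEWTON_TOL = 1e-12
_NEWTON_MAXIT = 50
_SEED_SPACING = 0.25
_DEDUP_DIST = 1e-6
_MULT_DERIV_TOL = 1e-8


def _newton(seeds: np.ndarray, c: Coefficients) -> np.ndarray:
    """Vectorized damped Newton iteration on Delta from the given seeds."""
    lam = seeds.copy()
    for _ in range(_NEWTON_MAXIT):
        f = _char_value_array(lam, c)
        e = np.exp(-lam)
        df = 1.0 + (c.alpha2 - c.alpha3 + c.alpha3 * lam) * e
        step = np.where(np.abs(df) > 1e-300, f / np.where(df == 0, 1.0, df), 0.0)
        # damp steps larger than one seed cell to keep iterates in basin
        mag = np.abs(step)
        step = np.where(mag > 1.0, step / np.where(mag > 1.0, mag, 1.0), step)
        lam = lam - step
        bad = ~np.isfinite(lam)
        if bad.any():
            lam[bad] = seeds[bad]  # restart diverged iterates (then stall)
    return lam


def find_roots(
    c: Coefficients,
    re_min: float = 0.0,
    tol: float = _NEWTON_TOL,
    im_max: float | None = None,
) -> list[ComplexRoot]:
    """All roots of Delta in the window [re_min, R] x [0, im_max], located
    by Newton iteration from a 0.25-spaced seed grid and deduplicated.
    R = modulus_bound + 1 and im_max defaults to R, so with re_min >= 0 the
    window contains every right half-plane root by the modulus bound (left
    of the axis roots extend arbitrarily high; widen im_max to chase them).
    Roots are reported with Im >= 0.
    """
    if not c.region_valid:
        raise ValueError("find_roots requires |alpha3| < 1")
    radius = modulus_bound(c) + 1.0
    re_hi = radius
    im_hi = radius if im_max is None else im_max

    res = np.arange(re_min - _SEED_SPACING / 2, re_hi + _SEED_SPACING, _SEED_SPACING)
    ims = np.arange(0.0, im_hi + _SEED_SPACING, _SEED_SPACING)
    seeds = (res[:, None] + 1j * ims[None, :]).ravel()

    scale = 1.0 + abs(c.alpha1) + abs(c.alpha2)
    lam = _newton(seeds, c)

    f = np.abs(_char_value_array(lam, c))
    ok = (
        (f < tol * scale)
        & (lam.real >= re_min - 1e-9)
        & (lam.real <= re_hi + 1e-9)
        & (np.abs(lam.imag) <= im_hi + 1e-9)
    )
    cand = lam[ok]
    cand = np.where(np.abs(cand.imag) < _DEDUP_DIST, cand.real + 0j, cand)
    cand = np.where(cand.imag < 0, np.conj(cand), cand)

    roots: list[complex] = []
    for z in sorted(cand.tolist(), key=lambda z: (round(z.real, 9), round(z.imag, 9))):
        if all(abs(z - r) > _DEDUP_DIST for r in roots):
            roots.append(z)

    out = []
    for z in roots:
        z, mult = _refine_multiplicity(z, c)
        out.append(
            ComplexRoot(
                re=float(z.real),
                im=float(z.imag),
                residual=float(abs(char_value(z, c))),
                multiplicity=mult,
            )
        )
    out.sort(key=lambda r: (-r.re, r.im))
    return out


def _refine_multiplicity(z: complex, c: Coefficients) -> tuple[complex, int]:
    """Detect a multiple root and re-polish it with the modified Newton step
    m*f/f' (plain Newton converges only linearly there and stalls ~1e-6
    away, which defeats the derivative-magnitude test)."""
    if abs(char_derivative(z, c, 1)) >= 1e-4:
        return z, 1
    best, mult = z, 1
    for m in (2, 3):
        zz = z
        for _ in range(20):
            df = char_derivative(zz, c, 1)
            if df == 0:
                break
            zz = zz - m * char_value(zz, c) / df
        if abs(char_value(zz, c)) < 1e-11 and all(
            abs(char_derivative(zz, c, j)) < _MULT_DERIV_TOL for j in range(1, m)
        ):
            best, mult = zz, m
    return best, mult


# ---------------------------------------------------------------------------
# Argument-principle counting on a half-disk contour
# ---------------------------------------------------------------------------

_PHASE_CAP = math.pi / 2
_MAX_REFINE = 30
_MAX_NUDGE = 6


def _contour_points(t: np.ndarray, x0: float, radius: float) -> np.ndarray:
    """Boundary of {Re lam >= x0} \\cap {|lam| <= radius}, traversed
    counterclockwise, parameterized by t in [0, 1].

    t in [0, 1/2]: arc of |lam| = radius from angle -phi0 to +phi0,
    t in [1/2, 1]: vertical chord from x0 + i*y0 down to x0 - i*y0,
    with y0 = sqrt(radius^2 - x0^2).
    """
    phi0 = math.acos(min(1.0, x0 / radius))
    y0 = radius * math.sin(phi0)
    pts = np.empty(t.shape, dtype=complex)
    arc = t <= 0.5
    ang = -phi0 + (t[arc] / 0.5) * 2 * phi0
    pts[arc] = radius * np.exp(1j * ang)
    s = (t[~arc] - 0.5) / 0.5
    pts[~arc] = x0 + 1j * (y0 - s * 2 * y0)
    return pts


def _winding_number(c: Coefficients, x0: float, radius: float) -> int:
    """Winding number of Delta along the half-disk boundary, by adaptive
    phase tracking: the parameter grid is refined until every consecutive
    phase increment of Delta is below pi/2, then the increments are summed.
    Raises ContourError if Delta nearly vanishes on the contour.
    """
    scale = 1.0 + abs(c.alpha1) + abs(c.alpha2)
    t = np.linspace(0.0, 1.0, 1024)
    z = _char_value_array(_contour_points(t, x0, radius), c)
    for _ in range(_MAX_REFINE):
        if np.abs(z).min() < 1e-9 * scale:
            raise ContourError("Delta vanishes within tolerance of the contour")
        dphi = np.angle(z[1:] / z[:-1])
        coarse = np.abs(dphi) >= _PHASE_CAP
        if not coarse.any():
            total = dphi.sum()
            w = total / (2 * math.pi)
            if abs(w - round(w)) > 0.25:
                raise ContourError("winding number failed to converge to an integer")
            return int(round(w))
        mids = (t[:-1][coarse] + t[1:][coarse]) / 2
        t = np.sort(np.concatenate([t, mids]))
        z = _char_value_array(_contour_points(t, x0, radius), c)
    raise ContourError("contour refinement did not converge")


def _axis_roots(
    c: Coefficients, margin: float, radius: float
) -> tuple[ComplexRoot, ...]:
    """Roots with |Re lambda| <= margin, sought from seeds on the imaginary
    axis only (any such root is a Newton limit of a nearby axis seed)."""
    seeds = 1j * np.arange(0.0, radius + _SEED_SPACING, _SEED_SPACING)
    scale = 1.0 + abs(c.alpha1) + abs(c.alpha2)
    lam = _newton(seeds, c)
    f = np.abs(_char_value_array(lam, c))
    ok = (f < _NEWTON_TOL * scale) & (np.abs(lam.real) <= margin) & (lam.imag > -margin)
    cand = np.where(np.abs(lam.imag) < _DEDUP_DIST, lam.real + 0j, lam[...])[ok]
    roots: list[complex] = []
    for z in sorted(cand.tolist(), key=lambda z: (round(z.imag, 9), round(z.real, 9))):
        if all(abs(z - r) > _DEDUP_DIST for r in roots):
            roots.append(z)
    out = []
    for z in roots:
        z, mult = _refine_multiplicity(z, c)
        out.append(
            ComplexRoot(
                re=float(z.real),
                im=float(abs(z.imag)),
                residual=float(abs(char_value(z, c))),
                multiplicity=mult,
            )
        )
    return tuple(out)


def count_unstable_roots(c: Coefficients, margin: float = 1e-8) -> RootCount:
    """Number of zeros of Delta (with multiplicity) with Re lambda > margin,
    by the argument principle on the half-disk {Re >= margin,
    |lambda| <= modulus_bound + 1}.  Zeros with |Re lambda| <= margin are
    returned as ``marginal`` and not counted.

    If a zero sits within tolerance of the contour, the flat segment is
    nudged toward the axis (margin/2, margin/4, ...); after the maximum
    number of nudges a ContourError propagates.
    """
    if not c.region_valid:
        raise ValueError("count_unstable_roots requires |alpha3| < 1")
    if margin <= 0:
        raise ValueError("margin must be positive")
    radius = modulus_bound(c) + 1.0

    n = None
    x0 = margin
    for _ in range(_MAX_NUDGE):
        try:
            n = _winding_number(c, x0, radius)
            break
        except ContourError:
            x0 /= 2.0
    if n is None:
        raise ContourError(
            "a zero of Delta remained within tolerance of the contour "
            "after the maximum number of nudges"
        )

    marginal = _axis_roots(c, margin, radius)
    # zeros found in (x0, margin] were counted by the (nudged) contour but
    # are classified marginal, not unstable
    n -= sum(r.multiplicity * (2 if r.im > _DEDUP_DIST else 1)
             for r in marginal if r.re > x0)
    return RootCount(n_unstable=n, marginal=marginal, bound_radius=radius)
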