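"""D-partition of the (a1, a2) coefficient plane for fixed |a3| < 1.

The plane is partitioned by critical-root loci: the half-line
L(a3) = {a2 = -a1, a1 <= 1 - a3}, where lambda = 0 is a root, and the
curves

    c1(w, a3) = w/sin(w) (cos w - a3),
    c2(w, a3) = w/sin(w) (a3 cos w - 1),

traced for w in [0, pi) (the curve C0 bounding the stability region) and
for w in ((2k-1)pi, 2k pi) resp. (2k pi, (2k+1)pi) (the curves Ck-, Ck+),
where a conjugate pair +-iw sits on the imaginary axis.  The stability
region S(a3) is the open set {a1 < 1 - a3, phi(a1) < a2 < -a1}, where
phi parameterizes C0 by a1 (legitimate because c1 is strictly decreasing
in w).  L and C0 meet at the corner (1 - a3, a3 - 1), where lambda = 0 is
a double root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .chareq import Coefficients, count_unstable_roots

__all__ = [
    "BoundaryCurve",
    "RegionVerdict",
    "c_point",
    "corner",
    "build_curve",
    "c0_height",
    "classify_point",
    "dc2_sign_change",
    "curves_to_frame",
    "classify_grid",
]

Branch = Literal["L", "C0", "Ck_plus", "Ck_minus"]

_OMEGA_EPS = 1e-6
_BISECT_XTOL = 1e-12
_NEAR_TOL = 1e-8


def _w_over_sin(omega: float) -> float:
    # w/sin(w), removable at w = 0
    if omega == 0.0:
        return 1.0
    return omega / math.sin(omega)


def corner(alpha3: float) -> tuple[float, float]:
    """The intersection point (1 - a3, a3 - 1) of L(a3) and C0(a3)."""
    return (1.0 - alpha3, alpha3 - 1.0)


def c_point(omega: float, alpha3: float) -> tuple[float, float]:
    """(c1, c2) at frequency omega; at omega = 0 the removable limit
    (1 - a3, a3 - 1) is returned.  omega = m*pi, m >= 1, are poles and
    rejected."""
    m = round(omega / math.pi)
    if m >= 1 and abs(omega - m * math.pi) < 1e-14 * max(1.0, omega):
        raise ValueError(f"omega = {m}*pi is a pole of c1, c2")
    r = _w_over_sin(omega)
    return (r * (math.cos(omega) - alpha3), r * (alpha3 * math.cos(omega) - 1.0))


@dataclass(frozen=True)
class BoundaryCurve:
    """A discretized critical-root locus in the (a1, a2) plane."""

    branch: Branch
    k: int
    alpha3: float
    omega: np.ndarray  # empty for L
    points: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        if self.branch in ("L", "C0") and self.k != 0:
            raise ValueError("k must be 0 for L and C0")
        if self.branch in ("Ck_plus", "Ck_minus") and self.k < 1:
            raise ValueError("k must be >= 1 for Ck branches")


@dataclass(frozen=True)
class RegionVerdict:
    """Membership verdict for a point of the (a1, a2) plane."""

    stable: bool
    corner: tuple[float, float]
    note: Literal["interior", "near_L", "near_C0", "right_of_corner"]


def _omega_interval(branch: Branch, k: int) -> tuple[float, float]:
    if branch == "C0":
        return (0.0, math.pi)
    if branch == "Ck_minus":
        return ((2 * k - 1) * math.pi, 2 * k * math.pi)
    if branch == "Ck_plus":
        return (2 * k * math.pi, (2 * k + 1) * math.pi)
    raise ValueError(f"no omega interval for branch {branch}")


def build_curve(
    branch: Branch,
    k: int,
    alpha3: float,
    n: int,
    max_alpha1_step: float = 0.25,
    alpha1_window: float = 50.0,
    omega_clip: float = _OMEGA_EPS,
) -> BoundaryCurve:
    """Sample a boundary locus.

    For C0/Ck the omega grid starts uniform on the (pole-clipped) interval
    and is refined until consecutive a1 steps are below ``max_alpha1_step``
    wherever the curve stays inside |a1| <= ``alpha1_window`` (the poles at
    m*pi send a1 to +-infinity, so refinement is confined to the window).
    ``omega_clip`` sets the pole clearance; shrink it to chase the far tail
    of a curve (the quarter-plane inequalities get numerically marginal
    within ~clip of a pole).  For L the half-line is sampled uniformly in
    a1 from the corner down to -alpha1_window.
    """
    if not abs(alpha3) < 1:
        raise ValueError("build_curve requires |alpha3| < 1")
    if n < 2:
        raise ValueError("n must be >= 2")
    if branch == "L":
        a1 = np.linspace(1.0 - alpha3, -alpha1_window, n)
        pts = np.column_stack([a1, -a1])
        return BoundaryCurve("L", 0, alpha3, np.empty(0), pts)

    lo, hi = _omega_interval(branch, k)
    if branch == "C0":
        grid = np.linspace(0.0, hi - omega_clip, n)
    else:
        grid = np.linspace(lo + omega_clip, hi - omega_clip, n)

    def eval_pts(om: np.ndarray) -> np.ndarray:
        r = np.ones_like(om)
        nz = om != 0.0
        r[nz] = om[nz] / np.sin(om[nz])
        return np.column_stack(
            [r * (np.cos(om) - alpha3), r * (alpha3 * np.cos(om) - 1.0)]
        )

    pts = eval_pts(grid)
    for _ in range(40):
        a1 = pts[:, 0]
        # refine any interval touching the window (a segment can bridge from
        # inside to far beyond the pole in one step)
        inside = (np.abs(a1[:-1]) <= alpha1_window) | (np.abs(a1[1:]) <= alpha1_window)
        big = inside & (np.abs(np.diff(a1)) > max_alpha1_step)
        if not big.any():
            break
        mids = (grid[:-1][big] + grid[1:][big]) / 2
        grid = np.sort(np.concatenate([grid, mids]))
        pts = eval_pts(grid)
    return BoundaryCurve(branch, k, alpha3, grid, pts)


def c0_height(alpha1: float, alpha3: float) -> float:
    """phi(a1): the a2-coordinate of C0(a3) above/below a1.

    c1(., a3) decreases strictly from 1 - a3 (at w = 0) to -inf (at w = pi),
    so for a1 <= 1 - a3 there is a unique w* in [0, pi) with c1(w*) = a1;
    phi(a1) = c2(w*).  Solved by bracketing bisection to 1e-12 in omega.
    """
    if not abs(alpha3) < 1:
        raise ValueError("c0_height requires |alpha3| < 1")
    if alpha1 > 1.0 - alpha3:
        raise ValueError("no C0 point with alpha1 > 1 - alpha3")
    if alpha1 == 1.0 - alpha3:
        return alpha3 - 1.0

    def f(om: float) -> float:
        return c_point(om, alpha3)[0] - alpha1

    hi = math.pi - 1e-13
    while f(hi) > 0:  # pathological rounding guard near the pole
        hi = (hi + math.pi) / 2
    w = brentq(f, 0.0, hi, xtol=_BISECT_XTOL)
    return c_point(w, alpha3)[1]


def classify_point(
    alpha1: float,
    alpha2: float,
    alpha3: float,
    boundary_tol: float = _NEAR_TOL,
) -> RegionVerdict:
    """Geometric membership test for the stability region S(a3).

    Stable iff a1 < 1 - a3 and phi(a1) < a2 < -a1 (strict tests).  Points
    within ``boundary_tol`` of L or C0 are tagged, and the strict test
    decides ``stable``.
    """
    if not abs(alpha3) < 1:
        raise ValueError("classify_point requires |alpha3| < 1")
    cn = corner(alpha3)
    if alpha1 >= 1.0 - alpha3:
        return RegionVerdict(stable=False, corner=cn, note="right_of_corner")
    phi = c0_height(alpha1, alpha3)
    stable = (phi < alpha2) and (alpha2 < -alpha1)
    note = "interior"
    if abs(alpha2 + alpha1) <= boundary_tol:
        note = "near_L"
    elif abs(alpha2 - phi) <= boundary_tol:
        note = "near_C0"
    return RegionVerdict(stable=stable, corner=cn, note=note)


def h_function(omega: float, alpha3: float) -> float:
    """h(w, a3) = a3 (sin w cos w - w) + w cos w - sin w; the sign of
    dc2/dw on (0, pi) equals the sign of h."""
    return (
        alpha3 * (math.sin(omega) * math.cos(omega) - omega)
        + omega * math.cos(omega)
        - math.sin(omega)
    )


def dc2_sign_change(alpha3: float, grid_n: int = 4096) -> float | None:
    """The unique frequency theta(a3) in (0, pi) where dc2/dw changes sign,
    or None when no sign change exists on (0, pi).

    Detection is numerical: h is sampled on a fine grid; if it is nowhere
    positive, c2 is monotone decreasing and None is returned.  Otherwise the
    single +to- crossing is refined by bisection.  (h > 0 near 0 happens
    exactly when a3 < -1/2, and theta(a3) -> pi as a3 -> -1.)
    """
    if not abs(alpha3) < 1:
        raise ValueError("dc2_sign_change requires |alpha3| < 1")
    om = np.linspace(0.0, math.pi, grid_n)
    h = (
        alpha3 * (np.sin(om) * np.cos(om) - om)
        + om * np.cos(om)
        - np.sin(om)
    )
    pos = np.nonzero(h > 0)[0]
    if pos.size == 0:
        return None
    lo = om[pos[-1]]
    # h(pi) = -(1 + a3) pi < 0, so a sign change lies in (lo, pi]
    return float(brentq(h_function, lo, math.pi, args=(alpha3,), xtol=_BISECT_XTOL))


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------


def curves_to_frame(curves: list[BoundaryCurve]) -> pd.DataFrame:
    """Stack curves into a table with columns
    branch,k,alpha3,omega,alpha1,alpha2 (omega is NaN on L)."""
    rows = []
    for cv in curves:
        omega = cv.omega if cv.omega.size else np.full(len(cv.points), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "branch": cv.branch,
                    "k": cv.k,
                    "alpha3": cv.alpha3,
                    "omega": omega,
                    "alpha1": cv.points[:, 0],
                    "alpha2": cv.points[:, 1],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def classify_grid(
    alpha1s: np.ndarray,
    alpha2s: np.ndarray,
    alpha3: float,
    margin: float = 1e-8,
    with_counts: bool = True,
) -> pd.DataFrame:
    """Classify every vertex of the tensor grid; columns
    alpha1,alpha2,alpha3,stable,n_unstable.  Root counts come from the
    argument-principle oracle (n_unstable = -1 when skipped)."""
    recs = []
    for a1 in np.asarray(alpha1s, dtype=float):
        for a2 in np.asarray(alpha2s, dtype=float):
            v = classify_point(a1, a2, alpha3)
            if with_counts:
                n = count_unstable_roots(
                    Coefficients(a1, a2, alpha3), margin=margin
                ).n_unstable
            else:
                n = -1
            recs.append((a1, a2, alpha3, v.stable, n))
    return pd.DataFrame(
        recs, columns=["alpha1", "alpha2", "alpha3", "stable", "n_unstable"]
    )
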