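"""Closed-form results for rigid cells without self-propulsion (nu = 0).

With ``nu = 0`` and the aspect ratio frozen at ``r > 1`` the dynamics reduce
to a 2-D system in ``(alpha, y)`` whose region-B flow admits a first
integral: trajectories follow the explicit curve

    y(alpha) = -sqrt( y0^2 + (1/(2r)) (r^2+1)/(r^2-1)
                      log( (cos a)^{r^2} sin a0 / (sin a (cos a0)^{r^2}) ) ).

Every overlapping trajectory stops on the A-B boundary ``y = -gamma1(alpha)``
in finite time; the terminal orientation is the unique root of a strictly
monotone scalar equation, and the arrival time is an explicit integral with
an integrable inverse-square-root endpoint singularity.

Note on the terminal-angle equation: the root condition used here,

    h(s) = s (1-s^2)^{-r^2/2} exp( 2 (r^2-1)^2 s^2 / (r^2+1) )
         = (sin a0 / (cos a0)^{r^2}) exp( 2 (r^2-1) (r y0^2 - 1) / (r^2+1) ),

carries a factor ``r`` on ``y0^2`` which is required for consistency with the
trajectory curve above (intersecting it with ``y^2 = gamma1^2`` and clearing
the ``1/(2r)`` prefactor multiplies ``y0^2`` by ``r``).  The same
re-derivation fixes the arrival-time prefactor:
``T = I(alpha_T) (r^2+1) / (8 (r^2-1))`` where ``I`` is the arrival-time
integral.  Both forms are validated against the event-detecting ODE
integrator in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .geometry import CellState, Region, classify_region, gamma_factors

__all__ = [
    "Nu0Outcome",
    "trajectory_curve",
    "curve_slope",
    "curve_invariant",
    "final_angle_nu0",
    "bc_no_reentry_root",
    "interaction_time_nu0",
    "solve_nu0",
]

_S_MAX = 1.0 - 1e-12


def _check_long(r: float) -> None:
    if not r > 1.0:
        raise ValueError(f"nu=0 closed forms assume long cells (r > 1), got r={r}")


def _K(r: float) -> float:
    """Prefactor of the log term in the trajectory curve."""
    return (r * r + 1.0) / (2.0 * r * (r * r - 1.0))


def trajectory_curve(alpha: float, alpha0: float, y0: float, r: float) -> float:
    """The region-B solution curve ``y(alpha)`` through ``(alpha0, y0)``.

    Returns the negative branch.  Raises ``ValueError`` for a negative
    radicand (the query angle lies outside the curve) or for angles at the
    log singularities 0 and pi/2.
    """
    _check_long(r)
    if y0 >= 0.0:
        raise ValueError("the closed-form curve is derived for y0 < 0")
    for a, name in ((alpha, "alpha"), (alpha0, "alpha0")):
        if not 0.0 < a < math.pi / 2:
            raise ValueError(f"{name}={a} outside (0, pi/2): log term singular")
    log_term = (
        r * r * (math.log(math.cos(alpha)) - math.log(math.cos(alpha0)))
        + math.log(math.sin(alpha0))
        - math.log(math.sin(alpha))
    )
    radicand = y0 * y0 + _K(r) * log_term
    if radicand < -1e-14:
        raise ValueError(
            f"alpha={alpha} lies outside the trajectory curve through "
            f"(alpha0={alpha0}, y0={y0}): radicand={radicand:.3e}"
        )
    return -math.sqrt(max(radicand, 0.0))


def curve_slope(alpha: float, y: float, r: float) -> float:
    """``dy/dalpha`` of the region-B flow, from the quotient of the two RHS.

    Equal to ``-gamma1^2 (r^2+1) / (4 (r^2-1) sin(a) cos(a) y)``; this is the
    exact derivative of :func:`trajectory_curve`.
    """
    _check_long(r)
    g1sq, _ = gamma_factors(alpha, r)
    sc = math.sin(alpha) * math.cos(alpha)
    return -g1sq * (r * r + 1.0) / (4.0 * (r * r - 1.0) * sc * y)


def curve_invariant(alpha: float, y: float, r: float) -> float:
    """First integral of the region-B flow, constant along trajectories.

    ``Q(alpha, y) = y^2 - K(r) log( (cos a)^{r^2} / sin a )`` with
    ``K = (r^2+1)/(2r(r^2-1))``.
    """
    _check_long(r)
    return y * y - _K(r) * (
        r * r * math.log(math.cos(alpha)) - math.log(math.sin(alpha))
    )


def _log_h(s: float, r: float) -> float:
    """log of the strictly increasing terminal-angle function h(s)."""
    return (
        math.log(s)
        - 0.5 * r * r * math.log1p(-s * s)
        + 2.0 * (r * r - 1.0) ** 2 / (r * r + 1.0) * s * s
    )


def _log_f(s: float, r: float) -> float:
    """log of the strictly increasing B-C re-entry function f(s)."""
    one_m = 1.0 - s * s
    return (
        math.log(s)
        - 0.5 * r * r * math.log1p(-s * s)
        + 2.0
        * (r * r - 1.0) ** 3
        * s
        * s
        * one_m
        / ((r * r + 1.0) * (s * s + r * r * one_m))
    )


def _assert_monotone(func, r: float, name: str, n: int = 201) -> None:
    s = np.linspace(1e-6, _S_MAX, n)
    vals = np.array([func(float(si), r) for si in s])
    if np.any(np.diff(vals) <= 0.0):
        raise RuntimeError(f"{name}(s) is not strictly increasing for r={r}: bug")


def _solve_increasing(func, target: float, r: float, name: str) -> float:
    _assert_monotone(func, r, name)
    lo, hi = 1e-300, _S_MAX
    if func(hi, r) < target:
        raise RuntimeError(
            f"failed to bracket the {name} root (target {target:.3e}): "
            "contradicts monotone range [0, inf)"
        )
    # brentq needs a finite lower value; log(func) -> -inf as s -> 0
    return brentq(lambda s: func(s, r) - target, 1e-15, hi, xtol=1e-15, rtol=1e-15)


def final_angle_nu0(alpha0: float, y0: float, r: float) -> float:
    """Terminal orientation ``alpha_T`` of a region-B start, by root finding.

    The trajectory through ``(alpha0, y0)`` stops where its curve meets the
    A-B boundary ``y^2 = gamma1^2``; ``sin(alpha_T)`` is the unique root of
    the strictly monotone equation ``h(s) = rhs(alpha0, y0)`` (see module
    docstring for the exact form).
    """
    _check_long(r)
    if y0 >= 0.0 or not 0.0 < alpha0 < math.pi / 2:
        raise ValueError("need y0 < 0 and alpha0 in (0, pi/2)")
    region = classify_region(CellState(0.0, y0, alpha0, r)).label
    if region is not Region.B:
        raise ValueError(
            f"({alpha0}, {y0}) lies in region {region.value}; the closed-form "
            "terminal angle applies to region-B starts (the A-B boundary "
            "counts as B)"
        )
    log_rhs = (
        math.log(math.sin(alpha0))
        - r * r * math.log(math.cos(alpha0))
        + 2.0 * (r * r - 1.0) / (r * r + 1.0) * (r * y0 * y0 - 1.0)
    )
    s_t = _solve_increasing(_log_h, log_rhs, r, "h")
    return math.asin(s_t)


def bc_no_reentry_root(alpha0: float, r: float) -> float:
    """Unique root of the B-C boundary re-entry equation, as ``s = sin(alpha)``.

    Launching from the B-C boundary at ``alpha0``, the trajectory curve meets
    ``y^2 = Gamma_BC^2`` only where ``f(s) = f(sin(alpha0))`` — and since
    ``f`` is strictly increasing the unique solution is the start itself.
    The returned root therefore equals ``sin(alpha0)`` to solver tolerance,
    which is the numerical embodiment of region-B invariance.
    """
    _check_long(r)
    if not 0.0 < alpha0 < math.pi / 2:
        raise ValueError("alpha0 must lie in (0, pi/2)")
    target = _log_f(math.sin(alpha0), r)
    return _solve_increasing(_log_f, target, r, "f")


def _gap_and_slope(alpha: float, alpha0: float, y0: float, r: float):
    """``g = gamma1^2 - y^2`` along the curve, and its alpha-derivative."""
    g1sq, _ = gamma_factors(alpha, r)
    y = trajectory_curve(alpha, alpha0, y0, r)
    g = g1sq - y * y
    sc = math.sin(alpha) * math.cos(alpha)
    s2 = math.sin(alpha) ** 2
    c2 = math.cos(alpha) ** 2
    dg = 2.0 * sc * (r - 1.0 / r) + _K(r) * (r * r * s2 + c2) / sc
    return g, dg, y


def interaction_time_nu0(
    alpha0: float, y0: float, r: float, quad_tol: float = 1e-10
) -> float:
    """Finite arrival time ``T`` at the A-B boundary for a region-B start.

    Evaluates the separable-form time integral along the closed-form curve.
    The integrand has an inverse-square-root singularity at the terminal
    angle; the substitution ``u = sqrt(alpha - alpha_T)`` removes it before
    adaptive quadrature.
    """
    _check_long(r)
    alpha_t = final_angle_nu0(alpha0, y0, r)
    u_max = math.sqrt(max(alpha0 - alpha_t, 0.0))
    if u_max == 0.0:
        return 0.0

    _, dg_t, _ = _gap_and_slope(alpha_t, alpha0, y0, r)

    def integrand(u: float) -> float:
        alpha = alpha_t + u * u
        g1sq, _ = gamma_factors(alpha, r)
        g, _, y = _gap_and_slope(alpha, alpha0, y0, r)
        sc = math.sin(alpha) * math.cos(alpha)
        if u < 1e-7:
            q = dg_t  # g / u^2 -> dg/dalpha at alpha_T
        else:
            q = max(g, 0.0) / (u * u)
            if q <= 0.0:
                q = dg_t
        # sqrt(g) = u sqrt(q); the factor u cancels the 2u du of the
        # substitution, leaving a bounded integrand
        return 2.0 * g1sq * g1sq / (y * sc * math.sqrt(q))

    val, err = quad(integrand, 0.0, u_max, epsabs=quad_tol, epsrel=quad_tol, limit=200)
    if not math.isfinite(val) or (abs(err) > 1e-6 * max(abs(val), 1.0)):
        raise RuntimeError(
            f"arrival-time quadrature did not converge: value={val}, "
            f"error estimate={err}, endpoints alpha_T={alpha_t}, alpha0={alpha0}"
        )
    # dt = dalpha * gamma1^4 (r^2+1) / (8 (r^2-1) sc sqrt(g) y); integrating
    # from alpha0 down to alpha_T gives a positive time (y < 0)
    return -val * (r * r + 1.0) / (8.0 * (r * r - 1.0))


@dataclass(frozen=True)
class Nu0Outcome:
    """Terminal point and arrival time of a nu=0 region-B trajectory."""

    alpha_T: float
    y_T: float
    T: float


def solve_nu0(alpha0: float, y0: float, r: float) -> Nu0Outcome:
    """Terminal orientation, position and arrival time for a region-B start."""
    alpha_t = final_angle_nu0(alpha0, y0, r)
    g1sq, _ = gamma_factors(alpha_t, r)
    return Nu0Outcome(
        alpha_T=alpha_t,
        y_T=-math.sqrt(g1sq),
        T=interaction_time_nu0(alpha0, y0, r),
    )
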