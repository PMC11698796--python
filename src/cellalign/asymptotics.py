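"""Matched asymptotics near perfect alignment, and the small-nu slow manifold.

The perfectly aligned side-by-side state ``(alpha, y, r) = (0, -1/sqrt(rb),
rb)`` is degenerate: linear stability analysis says nothing.  In the
distinguished limit ``gamma = eps * Gamma`` a perturbation

    alpha = eps A,   y = -1/sqrt(rb) + eps^2 B,   r = rb + eps^2 C

evolves over two timescales.  Over the early time ``tau = t/eps`` the
orientation is frozen (``A = a``) while overlap avoidance and shape
restoration drive ``(B, C)`` to constant far-field values; over the late time
``T = eps t`` the orientation decays algebraically,
``A ~ a / (4 a nu sqrt(rb) (rb^2-1)/(rb^2+1) T + 1)``, which is the
signature of the half-stable point (decay for ``a > 0``, escape for
``a < 0``, finite-time blow-up for wide cells ``rb < 1``).  An additive
composite of the two layers minus their common part is uniformly valid
in time.

Separately, for rigid slow cells (``0 < nu << 1``) the dynamics collapse
after a fast transient onto the A-B boundary ``gamma1^2(alpha) = y^2``
(the slow manifold), along which alignment proceeds over the slow time
``tau = nu (t - T)``; the reduced flow is a single ODE in ``s0 =
sin(alpha)`` whose time-to-align integral diverges like ``(r^2+1)/s0`` —
perfect alignment is reached only in infinite time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad, solve_ivp

from .geometry import ModelParams

__all__ = [
    "PerturbationSpec",
    "SlowManifoldState",
    "UnstablePerturbationError",
    "LateTimePoleError",
    "early_time_rhs",
    "solve_early_time",
    "far_field_limits",
    "late_time_solution",
    "late_time_pole",
    "composite_solution",
    "rigid_sublimit_solutions",
    "RigidSublimit",
    "algebraic_decay_constant",
    "slow_manifold_rhs",
    "slow_manifold_single_ode",
    "slow_manifold_time",
    "solve_slow_manifold",
]


class UnstablePerturbationError(ValueError):
    """A negative-a perturbation: the early-time dynamics end in escape."""


class LateTimePoleError(ValueError):
    """Late-time solution evaluated at/beyond its finite blow-up time."""


@dataclass(frozen=True)
class PerturbationSpec:
    """Perturbation experiment near the aligned steady state.

    ``eps`` is the small parameter; ``a, b, c`` are the order-one initial
    amplitudes of the ``alpha``, ``y`` and ``r`` perturbations; ``Gamma =
    gamma / eps`` is the rescaled shape parameter of the distinguished limit.
    """

    eps: float
    a: float
    b: float = 0.0
    c: float = 0.0
    Gamma: float = 0.0

    def __post_init__(self) -> None:
        if not self.eps > 0:
            raise ValueError("eps must be positive")
        if self.Gamma < 0:
            raise ValueError("Gamma must be >= 0")

    @property
    def gamma(self) -> float:
        return self.eps * self.Gamma

    def initial_state(self, params: ModelParams) -> tuple[float, float, float]:
        """The perturbed ``(alpha, y, r)`` initial condition this spec encodes."""
        rb = params.r_bar
        return (
            self.eps * self.a,
            -1.0 / math.sqrt(rb) + self.eps**2 * self.b,
            rb + self.eps**2 * self.c,
        )


def _overlap_indicator(A: float, B: float, C: float, r_bar: float) -> float:
    """D = (rb^2-1) A^2 + 2 sqrt(rb) B - C/rb; D > 0 means the cells overlap."""
    return (r_bar**2 - 1.0) * A * A + 2.0 * math.sqrt(r_bar) * B - C / r_bar


def early_time_rhs(
    Ahat: float,
    Bhat: float,
    Chat: float,
    spec: PerturbationSpec,
    params: ModelParams,
) -> tuple[float, float, float]:
    """Leading-order early-time derivatives ``d(A,B,C)/dtau``.

    The orientation is frozen over this timescale (``dA/dtau = 0``);
    the overlap term switches on the sign of the indicator ``D``.  With
    ``Gamma = 0`` (rigid sublimit) the restoration is instantaneous and the
    ``C`` equation degenerates to ``C = 0``: the returned ``dC`` is zero and
    callers should hold ``Chat = 0``.
    """
    rb = params.r_bar
    nu = params.nu
    D = _overlap_indicator(Ahat, Bhat, Chat, rb)
    rootD = math.sqrt(D) if D > 0.0 else 0.0
    dB = nu * Ahat - 2.0 * math.sqrt(rb) * rootD
    if spec.Gamma == 0.0:
        dC = 0.0
    else:
        dC = (
            -16.0 * (1.0 + rb**4) / (spec.Gamma * rb * (1.0 + rb * rb)) * Chat
            + 16.0 * rb * rb / (1.0 + rb * rb) * rootD
        )
    return 0.0, dB, dC


def solve_early_time(
    spec: PerturbationSpec,
    params: ModelParams,
    tau_max: float = 1e3,
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    """Numerically integrate the early-time ``(B, C)`` system to ``tau_max``.

    Returns the scipy solution object (with dense output); ``A`` is constant
    at ``spec.a``.  ``B`` and ``C`` have no closed form over this layer.
    """

    def rhs(tau, z):
        _, dB, dC = early_time_rhs(spec.a, z[0], z[1], spec, params)
        return [dB, dC]

    c0 = 0.0 if spec.Gamma == 0.0 else spec.c
    sol = solve_ivp(
        rhs,
        (0.0, tau_max),
        [spec.b, c0],
        method="LSODA",
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"early-time integration failed: {sol.message}")
    return sol


def far_field_limits(
    a: float, nu: float, Gamma: float, r_bar: float
) -> tuple[float, float, float]:
    """Large-tau limits ``(A_inf, B_inf, C_inf)`` of the early-time layer.

    Only meaningful for ``a > 0``; for ``a < 0`` the early-time dynamics end
    in escape (cells stop interacting) and :class:`UnstablePerturbationError`
    is raised as the documented "unstable" marker.
    """
    if a < 0.0:
        raise UnstablePerturbationError(
            "a < 0 perturbations escape: the early-time system has no "
            "far-field equilibrium (the steady state is half-stable)"
        )
    rb = r_bar
    B_inf = (
        nu * nu * a * a / (8.0 * rb**1.5)
        - (rb * rb - 1.0) * a * a / (2.0 * math.sqrt(rb))
        + Gamma * nu * a * rb / (4.0 * (1.0 + rb**4))
    )
    C_inf = Gamma * nu * a * rb**2.5 / (2.0 * (1.0 + rb**4))
    return a, B_inf, C_inf


def late_time_pole(a: float, nu: float, r_bar: float) -> float:
    """Blow-up time of the late-time solution (positive iff ``r_bar < 1``)."""
    return -(r_bar**2 + 1.0) / (4.0 * a * nu * math.sqrt(r_bar) * (r_bar**2 - 1.0))


def late_time_solution(T_slow, a: float, nu: float, Gamma: float, r_bar: float):
    """Late-time algebraic decay ``(A~, B~, C~)`` at slow time ``T_slow``.

    ``A~(T) = a / (4 a nu sqrt(rb) (rb^2-1)/(rb^2+1) T + 1)`` and ``B~, C~``
    follow it through the algebraic constraints.  For wide cells
    (``r_bar < 1``) the denominator has a positive zero; evaluation at or
    beyond it raises :class:`LateTimePoleError` carrying the pole location.
    """
    if a <= 0.0:
        raise UnstablePerturbationError(
            "late-time solutions exist for a > 0 only (a < 0 escapes)"
        )
    rb = r_bar
    T = np.asarray(T_slow, dtype=float)
    rate = 4.0 * a * nu * math.sqrt(rb) * (rb * rb - 1.0) / (rb * rb + 1.0)
    denom = rate * T + 1.0
    if rb < 1.0 and np.any(denom <= 0.0):
        raise LateTimePoleError(
            f"late-time solution blows up at T = {late_time_pole(a, nu, rb):.6g} "
            "(wide cells, r_bar < 1); evaluation at/beyond the pole"
        )
    A = a / denom
    B = (nu * nu + 4.0 * rb * (1.0 - rb * rb)) / (8.0 * rb**1.5) * A * A + (
        Gamma * nu * rb / (4.0 * (rb**4 + 1.0))
    ) * A
    C = Gamma * nu * rb**2.5 / (2.0 * (rb**4 + 1.0)) * A
    if np.isscalar(T_slow):
        return float(A), float(B), float(C)
    return A, B, C


def composite_solution(
    t,
    spec: PerturbationSpec,
    params: ModelParams,
    tau_max: float = 1e3,
):
    """Uniformly valid additive composite ``(alpha, y, r)`` at times ``t``.

    Early layer (numerical) plus late layer (closed form) minus their common
    part, the early-time far field.  The early layer is evaluated at ``t /
    eps``; beyond ``tau_max`` it has converged to the far field and the
    constants are used directly.  The composite ``alpha`` involves only the
    late layer and is therefore independent of ``Gamma``.
    """
    if spec.a <= 0.0:
        raise UnstablePerturbationError("composite solution requires a > 0")
    rb = params.r_bar
    eps = spec.eps
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)

    _, B_inf, C_inf = far_field_limits(spec.a, params.nu, spec.Gamma, rb)
    early = solve_early_time(spec, params, tau_max=tau_max)

    tau = t / eps
    Bhat = np.where(tau <= tau_max, early.sol(np.minimum(tau, tau_max))[0], B_inf)
    Chat = np.where(tau <= tau_max, early.sol(np.minimum(tau, tau_max))[1], C_inf)

    A_t, B_t, C_t = late_time_solution(eps * t, spec.a, params.nu, spec.Gamma, rb)
    A_t = np.atleast_1d(A_t)
    B_t = np.atleast_1d(B_t)
    C_t = np.atleast_1d(C_t)

    alpha = eps * A_t
    y = -1.0 / math.sqrt(rb) + eps**2 * (Bhat + B_t - B_inf)
    r = rb + eps**2 * (Chat + C_t - C_inf)
    if scalar:
        return float(alpha[0]), float(y[0]), float(r[0])
    return alpha, y, r


@dataclass(frozen=True)
class RigidSublimit:
    """Gamma -> 0 sublimit of the stability layers, mostly in closed form.

    ``A_early`` is constant; ``dBhat_dtau`` is the early-time ODE for the
    position perturbation; ``A_late``/``B_late`` are the closed-form late
    layers.
    """

    a: float
    nu: float
    r_bar: float

    @property
    def A_early(self) -> float:
        return self.a

    def dBhat_dtau(self, Bhat: float) -> float:
        rb = self.r_bar
        D = (rb * rb - 1.0) * self.a**2 + 2.0 * math.sqrt(rb) * Bhat
        rootD = math.sqrt(D) if D > 0.0 else 0.0
        return self.nu * self.a - 2.0 * math.sqrt(rb) * rootD

    def A_late(self, T):
        rb = self.r_bar
        T = np.asarray(T, dtype=float)
        return (
            self.a
            * (rb * rb + 1.0)
            / (4.0 * self.a * self.nu * math.sqrt(rb) * (rb * rb - 1.0) * T
               + rb * rb + 1.0)
        )

    def B_late(self, T):
        rb = self.r_bar
        A = self.A_late(T)
        return (self.nu**2 + 4.0 * rb - 4.0 * rb**3) / (8.0 * rb**1.5) * A * A


def rigid_sublimit_solutions(a: float, nu: float, r_bar: float) -> RigidSublimit:
    """Early/late stability layers for rigid cells (``Gamma -> 0``)."""
    if not r_bar > 1.0:
        raise ValueError("the rigid sublimit layers assume long cells (r_bar > 1)")
    return RigidSublimit(a=a, nu=nu, r_bar=r_bar)


def algebraic_decay_constant(nu: float, r_bar: float) -> float:
    """Limit of ``t * alpha(t)`` along the algebraic decay to alignment.

    From the late-time layer, ``alpha ~ eps A~(eps t)`` gives
    ``t alpha -> (rb^2+1) / (4 nu sqrt(rb) (rb^2-1))`` independently of the
    perturbation amplitude and of eps.
    """
    rb = r_bar
    return (rb * rb + 1.0) / (4.0 * nu * math.sqrt(rb) * (rb * rb - 1.0))


# ----------------------------------------------------------------------------
# small-nu slow manifold (rigid cells)
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class SlowManifoldState:
    """Leading-order state on the A-B boundary over the slow time tau = nu t.

    ``s0 = sin(A0)`` with ``A0`` the leading orientation; ``Y0 < 0``; the
    constraint ``gamma1^2(A0) = Y0^2`` holds on the manifold.
    """

    s0: float
    Y0: float
    tau: float = 0.0


def _check_s0(s0: float) -> None:
    if not 0.0 <= s0 <= 1.0:
        raise ValueError(f"s0 = sin(alpha) must lie in [0, 1], got {s0}")


def slow_manifold_rhs(state: SlowManifoldState, r: float) -> tuple[float, float]:
    """``(ds0/dtau, dY0/dtau)`` of the constrained slow flow."""
    _check_s0(state.s0)
    s0, Y0 = state.s0, state.Y0
    r2m1 = r * r - 1.0
    one_m = 1.0 - s0 * s0
    denom = 4.0 * r2m1**2 * s0 * s0 * one_m + r * (r * r + 1.0) * Y0 * Y0
    ds0 = 4.0 * r * r2m1 * Y0 * s0 * s0 * one_m / denom
    dY0 = 4.0 * r2m1**2 * s0**3 * one_m / denom
    return ds0, dY0


def manifold_Y0(s0: float, r: float) -> float:
    """The (negative) ``Y0`` satisfying the constraint at orientation ``s0``."""
    return -math.sqrt((r * r - 1.0) * s0 * s0 + 1.0) / math.sqrt(r)


def slow_manifold_single_ode(s0: float, r: float) -> float:
    """``ds0/dtau`` with the constraint substituted: a single ODE on (0, 1).

    Strictly negative in the interior — the slow flow always aligns.
    """
    _check_s0(s0)
    r2m1 = r * r - 1.0
    one_m = 1.0 - s0 * s0
    num = (
        -4.0
        * math.sqrt(r)
        * r2m1
        * math.sqrt(r2m1 * s0 * s0 + 1.0)
        * s0
        * s0
        * one_m
    )
    den = 4.0 * r2m1**2 * s0 * s0 * one_m + (r * r + 1.0) * r2m1 * s0 * s0 + r * r + 1.0
    return num / den


def slow_manifold_time(
    s_from: float, s_to: float, r: float, quad_tol: float = 1e-12
) -> float:
    """Slow time to travel from ``s_from`` down to ``s_to`` on the manifold.

    Separating variables gives ``tau = I / (4 sqrt(r) (r^2-1))`` with an
    explicit integral ``I``.  The integrand grows like ``(r^2+1)/s0^2`` as
    ``s0 -> 0``: alignment (``s_to = 0``) is reached only in infinite time,
    and ``s_to = 0`` raises accordingly.
    """
    if not 0.0 < s_to <= s_from < 1.0:
        if s_to == 0.0:
            raise ValueError(
                "s_to = 0 (perfect alignment) is only reached in infinite "
                "time: the time integral diverges like (r^2+1)/s_to"
            )
        raise ValueError("need 0 < s_to <= s_from < 1")
    if s_to == s_from:
        return 0.0
    r2m1 = r * r - 1.0

    def integrand(s: float) -> float:
        one_m = 1.0 - s * s
        num = 4.0 * r2m1**2 * s * s * one_m + (r * r + 1.0) * r2m1 * s * s + r * r + 1.0
        return num / (s * s * one_m * math.sqrt(r2m1 * s * s + 1.0))

    val, _ = quad(integrand, s_to, s_from, epsabs=quad_tol, epsrel=1e-12, limit=200)
    return val / (4.0 * math.sqrt(r) * r2m1)


def solve_slow_manifold(
    s_start: float,
    r: float,
    tau_grid: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Integrate the reduced single ODE; returns ``s0`` on ``tau_grid``."""
    _check_s0(s_start)
    sol = solve_ivp(
        lambda tau, z: [slow_manifold_single_ode(min(max(z[0], 0.0), 1.0), r)],
        (float(tau_grid[0]), float(tau_grid[-1])),
        [s_start],
        t_eval=np.asarray(tau_grid, dtype=float),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"slow-manifold integration failed: {sol.message}")
    return sol.y[0]
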