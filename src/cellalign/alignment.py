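"""Steady states, stability probing, separatrix and the alignment statistic.

For rigid long cells the ``(alpha, y)`` phase plane splits into two basins:
initial conditions below a separatrix are funnelled into the half-stable
perfect-alignment point ``(0, -1/sqrt(r))``, while those above it cross the
deep-overlap region, crawl over the partner and separate with ``y > 0``.
The alignment strength

    S_align = (1 / ((pi/2) sqrt(r))) int int (pi/2 - alpha_final) / (pi/2)
              d(alpha_0) d(y_0),

a normalised average of the post-interaction angle over the initial-condition
rectangle ``(0, pi/2) x (-sqrt(r), 0)``, summarises how favourable a
parameter set is for velocity alignment (1 = every tested pair aligns
perfectly).  It is non-monotone in both the self-propulsion strength ``nu``
(some propulsion is needed, too much lets cells escape) and the aspect ratio
``r`` (round cells barely torque each other, very elongated ones slip past).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import DEFAULT_TOL_ALIGN, Trajectory, integrate_trajectory
from .geometry import CellState, ModelParams, gamma_factors

__all__ = [
    "steady_states",
    "StabilityProbeResult",
    "stability_probe",
    "FinalAngleResult",
    "final_angle",
    "AlignmentMap",
    "alignment_map",
    "alignment_strength",
    "Separatrix",
    "separatrix",
    "fit_decay_laws",
]

#: default tolerances for the many-trajectory map/separatrix sweeps; looser
#: than the single-trajectory defaults because only the terminal angle (an
#: O(1) quantity reached through a funnel) is needed.
MAP_RTOL = 1e-7
MAP_ATOL = 1e-9


def steady_states(params: ModelParams) -> list[tuple[float, float, float]]:
    """The two aligned steady states ``(alpha, y, r) = (0, +-1/sqrt(rb), rb)``.

    These are the perfectly aligned side-by-side configurations with
    boundaries just touching; they are half-stable for long cells.
    """
    yss = 1.0 / math.sqrt(params.r_bar)
    return [(0.0, -yss, params.r_bar), (0.0, yss, params.r_bar)]


def fit_decay_laws(t: np.ndarray, alpha: np.ndarray) -> dict:
    """Fit algebraic (``1/(p t + q)``) and exponential decay to ``alpha(t)``.

    Both fits are linear least squares in transformed coordinates (``1/alpha``
    against ``t``, and ``log alpha`` against ``t``); residuals are compared
    as RMS relative error in ``alpha`` itself.  Algebraic decay with a much
    smaller residual is the signature of the half-stable point, where a naive
    linear analysis would predict exponential decay.
    """
    t = np.asarray(t, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    mask = alpha > 0
    t, alpha = t[mask], alpha[mask]
    # algebraic: 1/alpha = p t + q
    p, q = np.polyfit(t, 1.0 / alpha, 1)
    alg_pred = 1.0 / (p * t + q)
    alg_resid = float(np.sqrt(np.mean((alg_pred / alpha - 1.0) ** 2)))
    # exponential: log alpha = m t + b
    m, b = np.polyfit(t, np.log(alpha), 1)
    exp_pred = np.exp(m * t + b)
    exp_resid = float(np.sqrt(np.mean((exp_pred / alpha - 1.0) ** 2)))
    return {
        "algebraic_rate": float(p),
        "algebraic_residual": alg_resid,
        "exponential_rate": float(m),
        "exponential_residual": exp_resid,
        "t_alpha_tail": float(t[-1] * alpha[-1]),
    }


@dataclass
class StabilityProbeResult:
    """Outcome of perturbing the aligned steady state.

    ``classification`` is one of ``decays`` (algebraic return to alignment),
    ``escapes`` (cells stop interacting and separate), ``turns`` (orientation
    grows towards the head-to-head state, the wide-cell route) or
    ``undetermined``.
    """

    classification: str
    trajectory: Trajectory
    fits: dict = field(default_factory=dict)


def stability_probe(
    params: ModelParams,
    a: float,
    eps: float = 0.05,
    t_end: float = 2e3,
    tol_align: float = DEFAULT_TOL_ALIGN,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> StabilityProbeResult:
    """Perturb ``(0, -1/sqrt(rb), rb)`` by ``alpha -> eps a`` and classify.

    Uses the full deformable system when ``params.gamma > 0``, the rigid
    system otherwise.  The position and shape perturbation amplitudes are
    zero (``b = c = 0``): only the orientation is kicked, the sign of ``a``
    selecting the stable or unstable side of the half-stable point.
    """
    rb = params.r_bar
    state0 = CellState(x=0.0, y=-1.0 / math.sqrt(rb), alpha=eps * a, r=rb)
    mode = "full" if params.gamma > 0.0 else "rigid"
    traj = integrate_trajectory(
        state0,
        params,
        t_end=t_end,
        mode=mode,
        tol_align=tol_align,
        rtol=rtol,
        atol=atol,
    )
    if traj.outcome == "separated":
        return StabilityProbeResult("escapes", traj)

    # sample the orientation history for the decay / growth diagnosis
    t_lo = min(10.0, 0.05 * traj.t_final) if traj.t_final > 0 else 0.0
    ts = np.linspace(max(t_lo, 1e-3), max(traj.t_final, 1e-2), 400)
    alphas = traj.sample(ts)[:, 2]

    if traj.outcome == "aligned" or alphas[-1] < abs(eps * a):
        fits = fit_decay_laws(ts[ts > 0.1 * ts[-1]], alphas[ts > 0.1 * ts[-1]])
        return StabilityProbeResult("decays", traj, fits)
    if alphas[-1] > min(1.0, 4.0 * abs(eps * a)) and alphas[-1] > alphas[0]:
        return StabilityProbeResult("turns", traj)
    return StabilityProbeResult(
        "undetermined",
        traj,
        {"alpha_start": float(alphas[0]), "alpha_end": float(alphas[-1]),
         "t_end": t_end, "outcome": traj.outcome},
    )


@dataclass(frozen=True)
class FinalAngleResult:
    alpha_final: float
    outcome: str  # aligned / separated / stationary / capped
    t_final: float


def final_angle(
    alpha0: float,
    y0: float,
    params: ModelParams,
    t_end: float = 1e4,
    tol_align: float = DEFAULT_TOL_ALIGN,
    rtol: float = MAP_RTOL,
    atol: float = MAP_ATOL,
) -> FinalAngleResult:
    """Post-interaction orientation from ``(alpha0, y0)`` (rigid cells).

    Finite-time endings (separation; the nu=0 stationary arrival) return the
    terminal angle; infinite-time alignment is detected once ``alpha`` drops
    below ``tol_align`` and reported as exactly 0.  If the time cap is hit
    first the outcome is flagged ``capped`` and the current angle returned.
    """
    mode = "nu0" if params.nu == 0.0 else "rigid"
    traj = integrate_trajectory(
        CellState(0.0, y0, alpha0, params.r_bar),
        params,
        t_end=t_end,
        mode=mode,
        tol_align=tol_align,
        rtol=rtol,
        atol=atol,
    )
    alpha_f = float(traj.final_state.alpha)
    if traj.outcome == "aligned":
        alpha_f = 0.0
    # fold the reported angle back into [0, pi/2] (reflective symmetry)
    alpha_f = abs(alpha_f)
    if alpha_f > math.pi / 2:
        alpha_f = math.pi - alpha_f if alpha_f <= math.pi else alpha_f % math.pi
        alpha_f = min(max(alpha_f, 0.0), math.pi / 2)
    return FinalAngleResult(alpha_f, traj.outcome, traj.t_final)


@dataclass
class AlignmentMap:
    """Final-angle map over a midpoint grid of initial conditions."""

    alpha0: np.ndarray  # (n,)
    y0: np.ndarray  # (n,)
    alpha_final: np.ndarray  # (n_y, n_alpha)
    outcome: np.ndarray  # (n_y, n_alpha) of strings
    params: ModelParams

    @property
    def S_align(self) -> float:
        """Midpoint-rule discretisation of the alignment-strength integral."""
        return float(np.mean((math.pi / 2 - self.alpha_final) / (math.pi / 2)))

    @property
    def coverage(self) -> float:
        """Fraction of grid nodes whose outcome was resolved (not capped)."""
        return float(np.mean(self.outcome != "capped"))


def alignment_map(
    params: ModelParams,
    grid_n: int = 20,
    t_end: float = 1e4,
    tol_align: float = DEFAULT_TOL_ALIGN,
    rtol: float = MAP_RTOL,
    atol: float = MAP_ATOL,
) -> AlignmentMap:
    """Evaluate ``alpha_final`` on a ``grid_n x grid_n`` midpoint grid.

    The grid covers ``alpha0 in (0, pi/2)``, ``y0 in (-sqrt(r), 0)`` — cell 1
    below its partner, moving towards it.  Initial conditions in region A are
    included: with ``nu > 0`` they drift into overlap; with ``nu = 0`` they
    are stationary and keep their initial angle.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be at least 2")
    r = params.r_bar
    alpha0 = (np.arange(grid_n) + 0.5) * (math.pi / 2) / grid_n
    y0 = -math.sqrt(r) * (np.arange(grid_n) + 0.5) / grid_n
    alpha_final = np.empty((grid_n, grid_n))
    outcome = np.empty((grid_n, grid_n), dtype=object)
    for j, yv in enumerate(y0):
        for i, av in enumerate(alpha0):
            res = final_angle(
                av, yv, params, t_end=t_end, tol_align=tol_align, rtol=rtol, atol=atol
            )
            alpha_final[j, i] = res.alpha_final
            outcome[j, i] = res.outcome
    return AlignmentMap(
        alpha0=alpha0, y0=y0, alpha_final=alpha_final, outcome=outcome, params=params
    )


def alignment_strength(params: ModelParams, grid_n: int = 20, **kwargs) -> float:
    """``S_align`` on a midpoint grid (see :func:`alignment_map`).

    A coverage warning is attached to the map; use :func:`alignment_map`
    directly to inspect per-node outcomes.
    """
    amap = alignment_map(params, grid_n=grid_n, **kwargs)
    if amap.coverage < 1.0:
        import warnings

        warnings.warn(
            f"{(1 - amap.coverage) * 100:.1f}% of grid nodes hit the time cap; "
            "S_align computed over all nodes regardless",
            stacklevel=2,
        )
    return amap.S_align


@dataclass
class Separatrix:
    """Ordered polyline separating the aligned basin (below) from escape."""

    points: np.ndarray  # (n, 2) columns alpha, y
    params: ModelParams


def _outcome(alpha0, y0, params, t_end, rtol, atol) -> str:
    res = final_angle(alpha0, y0, params, t_end=t_end, rtol=rtol, atol=atol)
    return res.outcome


def _backward_trace(
    params: ModelParams, delta: float, t_end: float, rtol: float, atol: float
):
    """Backward-time trajectory seeded just off the half-stable point.

    The separatrix flows into the half-stable point region in forward time
    near ``alpha = 0``; integrating backwards from a seed at ``(delta, y)``
    slightly on the escaping side sweeps out an approximation of it.
    """
    g1sq, _ = gamma_factors(delta, params.r_bar)
    seed = CellState(0.0, -math.sqrt(g1sq) + delta * delta, delta, params.r_bar)
    return integrate_trajectory(
        seed,
        params,
        t_end=t_end,
        mode="rigid",
        direction="backward",
        rtol=rtol,
        atol=atol,
    )


def separatrix(
    params: ModelParams,
    n_slices: int = 10,
    alpha_range: tuple[float, float] = (0.08, 1.25),
    y_tol: float = 1e-4,
    t_end: float = 2e3,
    rtol: float = MAP_RTOL,
    atol: float = MAP_ATOL,
) -> Separatrix:
    """Locate the separatrix of the rigid system (``r_bar > 1``, ``nu > 0``).

    A backward-time trace from a seed near the half-stable point provides a
    first approximation; each of ``n_slices`` alpha-slices is then refined by
    bisection on the forward-integration outcome (aligned below the curve,
    separated above), to ``y_tol`` in ``y``.
    """
    if params.nu <= 0.0 or params.r_bar <= 1.0:
        raise ValueError("separatrix computation assumes nu > 0 and r_bar > 1")
    r = params.r_bar

    guess = {}
    try:
        bt = _backward_trace(params, 1e-3, 10.0, rtol, atol)
        for s in bt.states:
            if 0.0 < s[2] < math.pi / 2 and -math.sqrt(r) < s[1] < 0.0:
                guess[round(s[2], 2)] = s[1]
    except Exception:
        pass  # the bisection below does not depend on the trace

    # escape is detected in finite time, so 'capped' counts as non-separated
    def is_sep(out: str) -> bool:
        return out == "separated"

    alphas = np.linspace(alpha_range[0], alpha_range[1], n_slices)
    pts = []
    for a in alphas:
        g1 = math.sqrt(gamma_factors(a, r)[0])
        y_lo = -min(g1 * 0.999, math.sqrt(r) * 0.999)  # aligned side
        y_hi = -1e-4  # deep overlap: crawls over and separates
        y_guess = guess.get(round(a, 2))
        if y_guess is not None and y_lo < y_guess < y_hi:
            # tighten the bracket around the backward-trace approximation
            cand_lo, cand_hi = max(y_lo, y_guess - 0.1), min(y_hi, y_guess + 0.1)
            if not is_sep(
                _outcome(a, cand_lo, params, t_end, rtol, atol)
            ) and is_sep(_outcome(a, cand_hi, params, t_end, rtol, atol)):
                y_lo, y_hi = cand_lo, cand_hi
        lo_out = _outcome(a, y_lo, params, t_end, rtol, atol)
        hi_out = _outcome(a, y_hi, params, t_end, rtol, atol)
        if lo_out == hi_out:
            continue  # no basin boundary on this slice
        if is_sep(lo_out) or not is_sep(hi_out):
            continue
        while y_hi - y_lo > y_tol:
            mid = 0.5 * (y_lo + y_hi)
            if is_sep(_outcome(a, mid, params, t_end, rtol, atol)):
                y_hi = mid
            else:
                y_lo = mid
        pts.append((a, 0.5 * (y_lo + y_hi)))
    if not pts:
        raise RuntimeError(
            "no separatrix points found: bisection never bracketed distinct "
            f"outcomes in alpha range {alpha_range}"
        )
    return Separatrix(points=np.array(pts), params=params)
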