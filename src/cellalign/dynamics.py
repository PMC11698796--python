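"""Piecewise governing equations and event-aware trajectory integration.

The symmetric two-cell system evolves ``(x, y, alpha, r)`` of cell 1 (cell 2
is the mirror image).  The right-hand side is piecewise smooth: the overlap
terms switch with the region (A: no overlap, B: two intersection points,
C: four).  The RHS is continuous across both region boundaries — the region-B
terms vanish on the A-B boundary, and the B and C branches agree on the B-C
boundary — but the derivative jumps, so trajectories are integrated segment
by segment with root-resolved boundary-crossing events and a branch switch at
each resolved root.

Three modes are supported:

``full``
    Deformable cells, ``gamma > 0``; the aspect ratio relaxes to ``r_bar``.
``rigid``
    The ``gamma -> 0`` limit: ``r`` is frozen at ``r_bar`` and only
    ``(y, alpha)`` evolve.  This is the 2-D system used for phase portraits,
    the separatrix and the alignment statistic.
``nu0``
    Rigid cells without self-propulsion.  Region A is a continuum of
    stationary states, and every overlapping trajectory stops on the A-B
    boundary in finite time.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .geometry import (
    CellState,
    DegenerateAspectRatioError,
    ModelParams,
    Region,
    classify_region,
    gamma_factors,
)

__all__ = [
    "DerivativeVector",
    "TrajectoryEvent",
    "Trajectory",
    "IntegrationError",
    "rhs_full",
    "rhs_rigid",
    "rhs_nu0",
    "integrate_trajectory",
    "write_trajectory",
    "read_trajectory",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
    "DEFAULT_TOL_ALIGN",
]

DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-11
#: |alpha| below which a trajectory heading for the half-stable point is
#: declared aligned (the point itself is only reached in infinite time).
DEFAULT_TOL_ALIGN = 1e-4
#: distance (in the event function y^2 - Gamma_AB^2) from the A-B boundary at
#: which a nu=0 trajectory is declared stationary; the approach is quadratic
#: in time so the boundary itself is a double root the event solver cannot
#: bracket.
_NU0_STOP_BAND = 1e-12
#: explicit Euler nudge applied after a branch switch so the next segment
#: starts strictly inside its region (the RHS is continuous, so the error is
#: O(nudge^2) ~ 1e-18).
_NUDGE = 1e-9


class IntegrationError(RuntimeError):
    """Integrator failure, annotated with the offending boundary and state."""


@dataclass(frozen=True)
class DerivativeVector:
    """Time derivatives of the cell-1 state fields (non-dimensional time)."""

    dx: float
    dy: float
    dalpha: float
    dr: float


def _sign(y: float) -> float:
    # sign(0) taken as +1: y = 0 is only reachable while crossing between
    # half-planes inside region C.
    return 1.0 if y >= 0.0 else -1.0


def _check_not_circular(r: float) -> None:
    if r == 1.0:
        raise DegenerateAspectRatioError(
            "r = 1 (circular cells) is degenerate in regions B/C: the overlap "
            "torque formulas contain (r^2 - 1) denominators and circular "
            "cells exert no torque in this framework"
        )


#: radicands below this are treated as exactly zero so that states on the A-B
#: boundary (where y^2 = gamma1^2 only up to rounding) have an exactly
#: vanishing overlap term; the band is far below integration tolerances.
_RAD_CLAMP = 1e-13


def _terms_B(alpha: float, y: float, r: float) -> tuple[float, float, float]:
    """Overlap contributions (dy, dalpha, dr) of the region-B branch."""
    g1sq, _ = gamma_factors(alpha, r)
    sc = math.sin(alpha) * math.cos(alpha)
    rad = g1sq - y * y
    root = math.sqrt(rad) if rad > _RAD_CLAMP else 0.0
    dy = 2.0 * root / g1sq * _sign(y)
    dalpha = -8.0 * (r * r - 1.0) / (r * r + 1.0) * sc * root / g1sq**2 * abs(y)
    c2 = math.cos(alpha) ** 2
    s2 = math.sin(alpha) ** 2
    dr = 16.0 * r / (r * r + 1.0) * (c2 - r * r * s2) * root / g1sq**2 * abs(y)
    return dy, dalpha, dr


def _terms_C(alpha: float, y: float, r: float) -> tuple[float, float, float]:
    """Overlap contributions (dy, dalpha, dr) of the region-C branch.

    The shape-change term is assembled from the already-computed ``dalpha``
    and the overlap part of ``dy`` exactly as in the governing equations.
    """
    _check_not_circular(r)
    g1sq, g2sq = gamma_factors(alpha, r)
    sc = math.sin(alpha) * math.cos(alpha)
    r2m1 = r * r - 1.0
    dy = 2.0 * r * y / (g1sq * abs(r2m1 * sc))
    bracket = y * y * (
        (r2m1 / r) ** 2 * sc * sc / g1sq**2
        - (r / r2m1) ** 2 * (g2sq * g2sq - 1.0) / (sc * sc)
        - 1.0 / g1sq**2
    ) + (g2sq - g1sq) / (g1sq * g2sq)
    dalpha = 4.0 * r * math.copysign(1.0, (r - 1.0) * sc) / (r * r + 1.0) * bracket
    s2 = math.sin(alpha) ** 2
    c2 = math.cos(alpha) ** 2
    dr = 4.0 * r * sc * dalpha + 8.0 * r * r * y * dy / (1.0 + r * r) * (s2 - c2)
    return dy, dalpha, dr


def _restoration(r: float, params: ModelParams) -> float:
    return (
        -16.0
        / params.gamma
        * (1.0 + params.r_bar * r**3)
        / (params.r_bar * (r * r + 1.0))
        * (r - params.r_bar)
    )


def _branch_derivs(
    alpha: float, y: float, r: float, region: Region, nu: float
) -> tuple[float, float, float]:
    """(dy, dalpha, dr_overlap) of the given branch, excluding restoration."""
    if region is Region.A:
        return nu * math.sin(alpha), 0.0, 0.0
    _check_not_circular(r)
    if region is Region.B:
        dy_ov, dalpha, dr_ov = _terms_B(alpha, y, r)
    else:
        dy_ov, dalpha, dr_ov = _terms_C(alpha, y, r)
    return nu * math.sin(alpha) + dy_ov, dalpha, dr_ov


def rhs_full(state: CellState, params: ModelParams) -> DerivativeVector:
    """Right-hand side of the full deformable system at ``state``.

    Classifies the region itself; requires ``gamma > 0`` (for rigid cells use
    :func:`rhs_rigid`, which freezes ``r``).
    """
    if params.gamma == 0.0:
        raise ValueError(
            "gamma = 0 has no shape-restoration term: the aspect ratio is "
            "constrained to r_bar; use rhs_rigid instead"
        )
    region = classify_region(state).label
    dy, dalpha, dr_ov = _branch_derivs(state.alpha, state.y, state.r, region, params.nu)
    dr = dr_ov + _restoration(state.r, params)
    return DerivativeVector(
        dx=params.nu * math.cos(state.alpha), dy=dy, dalpha=dalpha, dr=dr
    )


def rhs_rigid(alpha: float, y: float, params: ModelParams) -> tuple[float, float]:
    """``(dy, dalpha)`` of the rigid (``r`` frozen at ``r_bar``) system."""
    _check_not_circular(params.r_bar)
    if params.r_bar < 1.0:
        warnings.warn(
            "rigid-cell analysis assumes long cells (r_bar > 1); formulas "
            "remain valid but the alignment results do not apply",
            stacklevel=2,
        )
    region = classify_region(CellState(0.0, y, alpha, params.r_bar)).label
    dy, dalpha, _ = _branch_derivs(alpha, y, params.r_bar, region, params.nu)
    return dy, dalpha


def rhs_nu0(alpha: float, y: float, r: float) -> tuple[float, float]:
    """``(dy, dalpha)`` of the rigid system with zero self-propulsion."""
    if not r > 1.0:
        raise ValueError(f"the nu=0 analysis assumes long cells (r > 1), got r={r}")
    region = classify_region(CellState(0.0, y, alpha, r)).label
    dy, dalpha, _ = _branch_derivs(alpha, y, r, region, 0.0)
    return dy, dalpha


# ----------------------------------------------------------------------------
# trajectory integration
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectoryEvent:
    time: float
    kind: str


@dataclass
class Trajectory:
    """Time-ordered states with region labels and boundary-event annotations.

    ``outcome`` summarises the termination: ``aligned`` (converged to the
    half-stable point within ``tol_align``), ``separated`` (in region A on
    the far side of the partner, heading away), ``stationary`` (nu=0 arrival
    on the A-B boundary), or ``capped`` (hit ``t_end``).
    """

    times: np.ndarray
    states: np.ndarray  # columns x, y, alpha, r
    regions: list[Region]
    events: list[TrajectoryEvent]
    mode: str
    params: ModelParams
    outcome: str
    tol_align: float = DEFAULT_TOL_ALIGN
    _segments: list = field(default_factory=list, repr=False)

    @property
    def final_state(self) -> CellState:
        x, y, alpha, r = self.states[-1]
        return CellState(x=x, y=y, alpha=alpha, r=r)

    @property
    def t_final(self) -> float:
        return float(self.times[-1])

    def sample(self, t) -> np.ndarray:
        """Interpolate states at times ``t`` using the dense solver output.

        Returns an ``(len(t), 4)`` array with columns ``x, y, alpha, r``.
        Times beyond the trajectory's end return the (constant) final state:
        a terminated interaction leaves the reduced variables frozen.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((t.size, 4))
        for i, ti in enumerate(t):
            out[i] = self._sample_one(ti)
        return out

    def _sample_one(self, ti: float) -> np.ndarray:
        forward = self.times[-1] >= self.times[0]
        past_end = ti >= self.t_final if forward else ti <= self.t_final
        if past_end or not self._segments:
            return self.states[-1]
        for t0, t1, sol, unpack, offset in self._segments:
            lo, hi = (t0, t1) if t0 <= t1 else (t1, t0)
            if lo - 1e-12 <= ti <= hi + 1e-12:
                return unpack(sol(ti - offset))
        # between segments (exactly at a switch point): nearest stored sample
        idx = int(np.argmin(np.abs(self.times - ti)))
        return self.states[idx]


#: hysteresis band for the region-leaving events: each fires this far (in the
#: squared-distance event function) *inside* the neighbouring region.  The
#: RHS is continuous across the boundaries, so offsetting the switch point is
#: dynamically free, while grazing trajectories (the funnel into the
#: half-stable point slides along the A-B boundary) can no longer trigger
#: spurious crossings through solver noise.
_EVENT_BAND = 1e-6


def _region_events(
    region: Region, mode: str, nu: float, tol_align: float, band: float
):
    """Event functions and metadata for one region branch.

    Each entry is ``(func(state4), direction, terminal, kind)`` where
    ``state4 = (x, y, alpha, r)``.
    """

    def g_ab(s):
        g1sq, _ = gamma_factors(s[2], s[3])
        return s[1] * s[1] - g1sq

    def g_bc(s):
        g1sq, g2sq = gamma_factors(s[2], s[3])
        sc = math.sin(s[2]) * math.cos(s[2])
        bc2 = (s[3] * s[3] - 1.0) ** 2 * sc * sc / (s[3] * s[3] * g2sq)
        return s[1] * s[1] - bc2

    events = []
    if region is Region.A:
        events.append((lambda s: g_ab(s) + band, -1, True, "AB-crossing"))
    elif region is Region.B:
        events.append((lambda s: g_ab(s) - band, +1, True, "AB-crossing"))
        events.append((lambda s: g_bc(s) + band, -1, True, "BC-crossing"))
        if mode == "nu0":
            events.append(
                (lambda s: g_ab(s) + _NU0_STOP_BAND, +1, True, "terminated-stationary")
            )
        elif nu > 0.0:
            events.append(
                (lambda s: s[2] - tol_align, -1, True, "terminated-stationary")
            )
    else:  # region C
        events.append((lambda s: g_bc(s) - band, +1, True, "BC-crossing"))
        events.append((lambda s: s[1], 0, False, "y0-crossing"))
    return events


def integrate_trajectory(
    state0: CellState,
    params: ModelParams,
    t_end: float,
    mode: str = "full",
    direction: str = "forward",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    tol_align: float = DEFAULT_TOL_ALIGN,
    method: str = "BDF",
    max_segments: int = 500,
    event_band: float = _EVENT_BAND,
) -> Trajectory:
    """Integrate the piecewise system with root-resolved boundary crossings.

    The integration restarts at each detected region-boundary crossing with
    the new branch; the branch switch occurs at the resolved root, never
    mid-step.  Termination policy: ``nu0`` trajectories stop when stationary
    on the A-B boundary; ``full``/``rigid`` trajectories stop when separating
    in region A (``sign(y) sin(alpha) > 0``: cell 1 past its partner and
    heading away, after which region-A motion is a straight line that never
    re-enters overlap) or when ``alpha`` has decayed below ``tol_align``
    (infinite-time alignment).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if mode not in ("full", "rigid", "nu0"):
        raise ValueError(f"unknown mode {mode!r}")
    if direction not in ("forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    if mode == "full" and params.gamma == 0.0:
        raise ValueError("mode='full' requires gamma > 0; use mode='rigid'")
    if mode in ("rigid", "nu0"):
        state0 = CellState(state0.x, state0.y, state0.alpha, params.r_bar)
    nu = 0.0 if mode == "nu0" else params.nu
    tdir = 1.0 if direction == "forward" else -1.0

    def pack(s: np.ndarray) -> np.ndarray:
        if mode == "full":
            return s.copy()
        return s[:3].copy()  # x, y, alpha; r frozen

    def unpack(z: np.ndarray) -> np.ndarray:
        if mode == "full":
            return np.asarray(z, dtype=float)
        return np.array([z[0], z[1], z[2], params.r_bar])

    def make_rhs(region: Region):
        def f(t, z):
            s = unpack(z)
            dy, dalpha, dr_ov = _branch_derivs(s[2], s[1], s[3], region, nu)
            dx = nu * math.cos(s[2])
            if mode == "full":
                dr = dr_ov + _restoration(s[3], params)
                return tdir * np.array([dx, dy, dalpha, dr])
            return tdir * np.array([dx, dy, dalpha])

        return f

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    regions: list[Region] = []
    events: list[TrajectoryEvent] = []
    segments: list = []
    outcome = "capped"

    # the integration variable is elapsed time along the chosen direction
    # (always increasing); backward runs flow under the negated RHS.
    s = np.array([state0.x, state0.y, state0.alpha, state0.r])
    region = classify_region(CellState(*s)).label
    t = 0.0
    done = False

    # immediate-termination checks at the initial state
    if region is Region.A:
        if mode == "nu0":
            # region A is a continuum of stationary states: constant solution
            tt = np.array([0.0, t_end])
            ss = np.vstack([s, s])
            return Trajectory(
                times=tt,
                states=ss,
                regions=[region, region],
                events=[TrajectoryEvent(t_end, "t_end")],
                mode=mode,
                params=params,
                outcome="stationary",
                tol_align=tol_align,
            )
        if direction == "forward" and _sign(s[1]) * math.sin(s[2]) > 0.0:
            return Trajectory(
                times=np.array([0.0]),
                states=s[None, :],
                regions=[region],
                events=[TrajectoryEvent(0.0, "terminated-separating")],
                mode=mode,
                params=params,
                outcome="separated",
                tol_align=tol_align,
            )
    elif (
        mode != "nu0"
        and nu > 0.0
        and direction == "forward"
        and 0.0 <= s[2] <= tol_align
    ):
        # already within the alignment tolerance of the half-stable point
        return Trajectory(
            times=np.array([0.0]),
            states=s[None, :],
            regions=[region],
            events=[TrajectoryEvent(0.0, "terminated-stationary")],
            mode=mode,
            params=params,
            outcome="aligned",
            tol_align=tol_align,
        )

    for _ in range(max_segments):
        rhs = make_rhs(region)
        evs = _region_events(region, mode, nu, tol_align, event_band)

        def wrap(func, direc, terminal):
            w = lambda tt, z: func(unpack(z))  # noqa: E731
            w.direction = direc
            w.terminal = terminal
            return w

        ev_funcs = [wrap(func, direc, term) for func, direc, term, _ in evs]

        # the system is autonomous: integrate each segment in local time
        # starting from 0 (LSODA's step-size heuristics degrade badly when a
        # segment starts at a large absolute time) and offset stored times
        t_offset = t
        with warnings.catch_warnings():
            # the finite-difference Jacobian of the sqrt overlap term emits
            # harmless overflow warnings while probing increments near the
            # A-B boundary
            warnings.simplefilter("ignore", RuntimeWarning)
            sol = solve_ivp(
                rhs,
                (0.0, t_end - t),
                pack(s),
                method=method,
                rtol=rtol,
                atol=atol,
                events=ev_funcs,
                dense_output=True,
            )
        if not sol.success:
            raise IntegrationError(
                f"integrator failed in region {region.value} at "
                f"t={t_offset + sol.t[-1]:.6g}, "
                f"state={unpack(sol.y[:, -1])}: {sol.message}"
            )

        times.append(sol.t + t_offset)
        seg_states = np.array([unpack(sol.y[:, i]) for i in range(sol.t.size)])
        states.append(seg_states)
        regions.extend([region] * sol.t.size)
        segments.append(
            (t_offset + sol.t[0], t_offset + sol.t[-1], sol.sol, unpack, t_offset)
        )

        # log any non-terminal events that fired during this segment
        for i, (func, direc, terminal, kind) in enumerate(evs):
            if not terminal:
                for te in np.atleast_1d(sol.t_events[i]):
                    events.append(TrajectoryEvent(float(te) + t_offset, kind))

        if sol.status == 0:  # reached t_end
            events.append(TrajectoryEvent(t_offset + sol.t[-1], "t_end"))
            outcome = "capped"
            done = True
        elif sol.status == 1:  # stopped by a terminal event
            t_stop = sol.t[-1]
            idx = None
            for i, (func, direc, terminal, kind) in enumerate(evs):
                if terminal and sol.t_events[i].size > 0:
                    if abs(float(sol.t_events[i][-1]) - t_stop) <= 1e-12 * max(
                        1.0, abs(t_stop)
                    ):
                        idx = i
                        break
            if idx is None:  # fall back: latest terminal event
                idx = max(
                    (i for i in range(len(evs)) if evs[i][2] and sol.t_events[i].size),
                    key=lambda i: sol.t_events[i][-1],
                )
            t_ev = float(sol.t_events[idx][-1]) + t_offset
            s = unpack(sol.y_events[idx][-1])
            kind = evs[idx][3]
            t = t_ev
            if kind == "terminated-stationary":
                events.append(TrajectoryEvent(t_ev, kind))
                outcome = "stationary" if mode == "nu0" else "aligned"
                done = True
            else:
                events.append(TrajectoryEvent(t_ev, kind))
                # Nudge along the (continuous) RHS, then decide which side of
                # the boundary the flow actually enters from the sign of the
                # boundary function.  A blind toggle would fail on grazing
                # events: trajectories funnelling into the half-stable point
                # slide along the A-B boundary and can touch it without
                # crossing.
                f_here = make_rhs(region)
                z = pack(s) + _NUDGE * np.asarray(f_here(t, pack(s)))
                s = unpack(z)
                t = t + _NUDGE
                g1sq, g2sq = gamma_factors(s[2], s[3])
                if kind == "AB-crossing":
                    gval = s[1] * s[1] - g1sq
                    # on a tangency (|gval| ~ 0) stay on the overlapping side
                    new_region = Region.A if gval > 1e-15 else Region.B
                    if new_region is Region.A and direction == "forward":
                        if _sign(s[1]) * math.sin(s[2]) > 0.0:
                            events.append(
                                TrajectoryEvent(t_ev, "terminated-separating")
                            )
                            outcome = "separated"
                            done = True
                    region = new_region
                elif kind == "BC-crossing":
                    sc = math.sin(s[2]) * math.cos(s[2])
                    bc2 = (s[3] ** 2 - 1.0) ** 2 * sc * sc / (s[3] ** 2 * g2sq)
                    gval = s[1] * s[1] - bc2
                    new_region = Region.C if gval < -1e-15 else Region.B
                    region = new_region
        if done:
            break
    else:
        raise IntegrationError(
            f"exceeded {max_segments} region switches (possible chattering) "
            f"near state {s} in region {region.value}"
        )

    tt = np.concatenate(times)
    ss = np.vstack(states)
    return Trajectory(
        times=tt,
        states=ss,
        regions=regions,
        events=events,
        mode=mode,
        params=params,
        outcome=outcome,
        tol_align=tol_align,
        _segments=segments,
    )


# ----------------------------------------------------------------------------
# trajectory round-trip I/O (CSV + JSON events sidecar)
# ----------------------------------------------------------------------------


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as CSV (t, x, y, alpha, r, region) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "t": traj.times,
            "x": traj.states[:, 0],
            "y": traj.states[:, 1],
            "alpha": traj.states[:, 2],
            "r": traj.states[:, 3],
            "region": [reg.value for reg in traj.regions],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "mode": traj.mode,
        "outcome": traj.outcome,
        "tol_align": traj.tol_align,
        "params": {"nu": traj.params.nu, "gamma": traj.params.gamma,
                   "r_bar": traj.params.r_bar},
        "events": [{"time": ev.time, "kind": ev.kind} for ev in traj.events],
    }
    path.with_suffix(path.suffix + ".events.json").write_text(
        json.dumps(sidecar, indent=2)
    )


def read_trajectory(path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory` (no dense data)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar = json.loads(path.with_suffix(path.suffix + ".events.json").read_text())
    params = ModelParams(**sidecar["params"])
    return Trajectory(
        times=df["t"].to_numpy(),
        states=df[["x", "y", "alpha", "r"]].to_numpy(),
        regions=[Region(v) for v in df["region"]],
        events=[TrajectoryEvent(ev["time"], ev["kind"]) for ev in sidecar["events"]],
        mode=sidecar["mode"],
        params=params,
        outcome=sidecar["outcome"],
        tol_align=sidecar["tol_align"],
    )
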