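"""Exact overlap geometry of two mirror-symmetric ellipse cells.

Two identical ellipse cells of aspect ratio ``r`` interact in a configuration
that is mirror-symmetric about the x-axis: cell 1 has centre ``(x, y)`` and
orientation ``alpha``, cell 2 sits at ``(x, -y)`` with orientation ``-alpha``.
This symmetry makes the boundary-intersection problem analytically solvable:
the two boundaries cross in 0, 2 or 4 points, and the corresponding regions of
``(alpha, y, r)`` space (labelled A, B and C) are bounded by two closed-form
curves.  Everything downstream (the piecewise governing equations, the
asymptotics, the alignment statistic) is built on the quantities computed
here.

Conventions
-----------
* ``gamma1``/``gamma2`` are the two shape factors
  ``gamma1^2 = r sin^2(a) + cos^2(a)/r`` and
  ``gamma2^2 = sin^2(a)/r + r cos^2(a)``.
* Region A: no intersection (``y^2 > Gamma_AB^2``); region B: two
  intersections ``P_B+-`` on the x-axis of the mirror frame; region C: four
  intersections (``P_B+-`` and the mirror pair ``P_C+-``).
* ``alpha`` is stored unwrapped; all formulas use ``sin``/``cos`` directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "ModelParams",
    "CellState",
    "Region",
    "RegionLabel",
    "IntersectionSet",
    "DegenerateAspectRatioError",
    "GeometryConsistencyError",
    "boundary_point",
    "gamma_factors",
    "boundary_curves",
    "classify_region",
    "intersection_points",
    "implicit_residual",
    "BOUNDARY_TOL",
    "RADICAND_TOL",
]

#: absolute tolerance band used to resolve exact-boundary ties in region
#: classification (ties are assigned to the region with more intersections so
#: that vanishing square roots evaluate to 0 rather than NaN).
BOUNDARY_TOL = 1e-12

#: radicands within this band below zero are clamped to zero; anything more
#: negative while the state is classified as overlapping raises
#: :class:`GeometryConsistencyError`.
RADICAND_TOL = 1e-12


class DegenerateAspectRatioError(ValueError):
    """Raised when an operation requires ``r != 1``.

    Circular cells (``r = 1``) exert no torque in this framework; formulas
    containing ``(r^2 - 1)`` denominators are undefined there.
    """


class GeometryConsistencyError(RuntimeError):
    """Internal mismatch between region classification and intersection math."""


def _check_r(r: float) -> None:
    if not r > 0:
        raise ValueError(f"aspect ratio must be positive, got r={r}")


@dataclass(frozen=True)
class ModelParams:
    """Non-dimensional model parameters.

    Parameters
    ----------
    nu : float
        Self-propulsion strength (speed relative to overlap-avoidance
        strength in the presence of substrate friction).  ``nu >= 0``.
    gamma : float
        Shape-change parameter (overlap avoidance relative to shape
        restoration).  ``gamma = 0`` means rigid cells.  ``gamma >= 0``.
    r_bar : float
        Preferred aspect ratio.  ``r_bar > 1`` are "long" cells that move
        along their long axis; ``r_bar < 1`` are "wide" cells.
    """

    nu: float
    gamma: float
    r_bar: float

    def __post_init__(self) -> None:
        if self.nu < 0:
            raise ValueError(f"nu must be >= 0, got {self.nu}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not self.r_bar > 0:
            raise ValueError(f"r_bar must be > 0, got {self.r_bar}")


@dataclass(frozen=True)
class CellState:
    """State of cell 1; cell 2 is its mirror image at ``(x, -y)``, ``-alpha``.

    The mirror construction means cell 2 is never stored: the pair is fully
    described by ``(x, y, alpha, r)``.
    """

    x: float
    y: float
    alpha: float
    r: float

    def __post_init__(self) -> None:
        _check_r(self.r)


class Region(str, Enum):
    """Overlap class of the symmetric pair: 0, 2 or 4 boundary intersections."""

    A = "A"
    B = "B"
    C = "C"

    @property
    def n_intersections(self) -> int:
        return {"A": 0, "B": 2, "C": 4}[self.value]


@dataclass(frozen=True)
class RegionLabel:
    label: Region
    n_intersections: int

    @classmethod
    def from_region(cls, region: Region) -> "RegionLabel":
        return cls(label=region, n_intersections=region.n_intersections)


@dataclass(frozen=True)
class IntersectionSet:
    """Boundary-boundary intersection points, relative to the shared x-position.

    ``points`` is an ``(n, 2)`` array; ``kinds`` labels each row one of
    ``"B+", "B-", "C+", "C-"``.
    """

    points: np.ndarray
    kinds: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.kinds)


def _rot(alpha: float) -> np.ndarray:
    c, s = math.cos(alpha), math.sin(alpha)
    return np.array([[c, -s], [s, c]])


def boundary_point(state: CellState, cell_index: int, theta: float) -> np.ndarray:
    """Point on the boundary of cell 1 or 2 at ellipse parameter ``theta``.

    The boundary is ``X + R(+-alpha) k(r, theta)`` with shape vector
    ``k = (sqrt(r) cos(theta), sin(theta)/sqrt(r))``; cell 2 mirrors the signs
    of ``y`` and ``alpha``.
    """
    _check_r(state.r)
    if cell_index not in (1, 2):
        raise ValueError(f"cell_index must be 1 or 2, got {cell_index}")
    sgn = 1.0 if cell_index == 1 else -1.0
    centre = np.array([state.x, sgn * state.y])
    k = np.array(
        [math.sqrt(state.r) * math.cos(theta), math.sin(theta) / math.sqrt(state.r)]
    )
    return centre + _rot(sgn * state.alpha) @ k


def gamma_factors(alpha: float, r: float) -> tuple[float, float]:
    """Return ``(gamma1^2, gamma2^2)`` for orientation ``alpha`` and ratio ``r``."""
    _check_r(r)
    s2 = math.sin(alpha) ** 2
    c2 = math.cos(alpha) ** 2
    g1sq = r * s2 + c2 / r
    g2sq = s2 / r + r * c2
    return g1sq, g2sq


def boundary_curves(alpha: float, r: float) -> tuple[float, float]:
    """Region-boundary curves ``(Gamma_AB, Gamma_BC)`` at ``(alpha, r)``.

    ``Gamma_AB = gamma1`` and ``Gamma_BC = (r^2-1) sin(a) cos(a) / (r gamma2)``;
    the sign of ``Gamma_BC`` follows ``sin(a) cos(a)`` and ``(r^2-1)``.
    """
    g1sq, g2sq = gamma_factors(alpha, r)
    gamma_ab = math.sqrt(g1sq)
    gamma_bc = (r * r - 1.0) * math.sin(alpha) * math.cos(alpha) / (r * math.sqrt(g2sq))
    return gamma_ab, gamma_bc


def classify_region(state: CellState) -> RegionLabel:
    """Classify the configuration as region A, B or C.

    Ties within ``BOUNDARY_TOL`` of a boundary are assigned to the region with
    more intersections (B on the A-B boundary, C on the B-C boundary) so that
    the vanishing square roots in the intersection formulas evaluate to zero.
    """
    gamma_ab, gamma_bc = boundary_curves(state.alpha, state.r)
    y2 = state.y * state.y
    if y2 <= gamma_bc * gamma_bc + BOUNDARY_TOL:
        return RegionLabel.from_region(Region.C)
    if y2 <= gamma_ab * gamma_ab + BOUNDARY_TOL:
        return RegionLabel.from_region(Region.B)
    return RegionLabel.from_region(Region.A)


def _clamped_sqrt(radicand: float, where: str) -> float:
    if radicand < -RADICAND_TOL:
        raise GeometryConsistencyError(
            f"negative radicand {radicand:.3e} in {where}: classification and "
            "intersection geometry disagree"
        )
    return math.sqrt(max(radicand, 0.0))


def intersection_points(state: CellState) -> IntersectionSet:
    """Analytic boundary-intersection points of the symmetric pair.

    Returns the empty set in region A, ``P_B+-`` in region B, and additionally
    ``P_C+-`` in region C.  Coordinates are relative to the cells' shared
    x-position.  ``P_B+-`` lie on the mirror axis (second coordinate 0);
    ``P_C+-`` are mirror-symmetric in the second coordinate.
    """
    region = classify_region(state).label
    if region is Region.A:
        return IntersectionSet(points=np.empty((0, 2)), kinds=())

    alpha, y, r = state.alpha, state.y, state.r
    g1sq, g2sq = gamma_factors(alpha, r)
    sc = math.sin(alpha) * math.cos(alpha)

    root_b = _clamped_sqrt(g1sq - y * y, "P_B radicand")
    xb = -y * (r * r - 1.0) * sc / r
    pts = [
        np.array([(xb + root_b) / g1sq, 0.0]),
        np.array([(xb - root_b) / g1sq, 0.0]),
    ]
    kinds = ["B+", "B-"]

    if region is Region.C:
        denom = (r * r - 1.0) * sc
        if denom == 0.0:
            # the B-C boundary collapses onto y = 0 here; region C is only
            # reachable with sc != 0 unless y == 0 exactly
            raise GeometryConsistencyError(
                "region C classification with (r^2-1) sin(a) cos(a) = 0"
            )
        gamma_bc = denom / (r * math.sqrt(g2sq))
        root_c = _clamped_sqrt(gamma_bc * gamma_bc - y * y, "P_C radicand")
        pref = r / denom
        xc = pref * (-y * g2sq)
        pts.append(np.array([xc, pref * root_c]))
        pts.append(np.array([xc, -pref * root_c]))
        kinds.extend(["C+", "C-"])

    return IntersectionSet(points=np.vstack(pts), kinds=tuple(kinds))


def implicit_residual(state: CellState, cell_index: int, point) -> float:
    """Value of the implicit ellipse equation of one cell at ``point``.

    With ``q = R(+-alpha)^T (p - X)`` the residual is
    ``q1^2/r + r q2^2 - 1``: zero on the boundary, negative inside, positive
    outside.  Used as the independent oracle for the analytic intersections.
    """
    _check_r(state.r)
    if cell_index not in (1, 2):
        raise ValueError(f"cell_index must be 1 or 2, got {cell_index}")
    sgn = 1.0 if cell_index == 1 else -1.0
    p = np.asarray(point, dtype=float)
    centre = np.array([state.x, sgn * state.y])
    q = _rot(sgn * state.alpha).T @ (p - centre)
    return float(q[0] ** 2 / state.r + state.r * q[1] ** 2 - 1.0)
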