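"""Accessible-information polytopes of bistable probabilities.

For two events E1, E2 with probabilities P1, P2 and conjunction
probability P12, Boole's conditions of possible experience

    0 <= Pi <= 1,   P12 >= 0,   P12 <= Pi,   P1 + P2 - P12 <= 1

carve a tetrahedron out of the unit cube in (P1, P2, P12) space: the
set of assignments realisable by some classical joint distribution.
Its vertices are (0,0,0), (0,1,0), (1,0,0), (1,1,1) and its volume is
1/6.

Under bistability the conjunction coordinate obeys the relaxed system

    (2k-1) Pi - P12 >= k - 1   (i = 1, 2)
    (2k-1)(P1 + P2) - P12 <= 2k - 1

together with the base constraints 0 <= P1, P2 <= 1 and P12 >= 0.  At
k=1 this is exactly the Boole tetrahedron; at k=0.5 it degenerates to
the box 0 <= P12 <= 1/2 with P1, P2 free in [0,1] (volume 1/2).  The
region grows as k decreases: an irrational decision maker has *more*
accessible probability assignments than a rational one.  The excess is
the pure irrational information volume (PIIV),

    Delta(k) = V(k) - V(1),

zero at k=1 and monotonically increasing as k falls to 0.5.  Volumes
are computed exactly by half-space intersection (vertex enumeration)
followed by convex-hull triangulation — no Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection

from .core import validate_probability

__all__ = [
    "EmptyRegionError",
    "BooleVerdict",
    "ProbPolytope",
    "PIIVResult",
    "boole_check",
    "bistable_polytope",
    "volume",
    "piiv",
    "piiv_curve",
]

#: Tolerance for vertex/half-space consistency checks.
GEOMETRY_TOL = 1e-9


class EmptyRegionError(ValueError):
    """Raised when a half-space system has no (full-dimensional) interior."""


@dataclass(frozen=True)
class BooleVerdict:
    """Result of checking Boole's conditions for two events."""

    violations: tuple[str, ...]

    @property
    def is_possible_experience(self) -> bool:
        """True when (P1, P2, P12) admits a classical joint distribution."""
        return not self.violations


def boole_check(p1: float, p2: float, p12: float, tol: float = 1e-12) -> BooleVerdict:
    """List every violated Boole condition for a (P1, P2, P12) triple.

    An empty violation list means the triple is a potential rational
    choice: some classical joint distribution over the two events
    realises it.
    """
    violations: list[str] = []
    for name, value in (("P1", p1), ("P2", p2)):
        if value < -tol or value > 1.0 + tol:
            violations.append(f"0 <= {name} <= 1")
    if p12 < -tol:
        violations.append("P12 >= 0")
    for name, value in (("P1", p1), ("P2", p2)):
        if p12 > value + tol:
            violations.append(f"{name} >= P12")
    if p1 + p2 - p12 > 1.0 + tol:
        violations.append("P1 + P2 - P12 <= 1")
    return BooleVerdict(violations=tuple(violations))


@dataclass(frozen=True)
class ProbPolytope:
    """A convex region in (P1, P2, P12) coordinates, double-described.

    ``halfspaces`` is an (m, 4) array of rows [a1, a2, a3, b] meaning
    a1*P1 + a2*P2 + a3*P12 <= b; ``vertices`` is an (n, 3) array.  The
    two representations describe the same region.
    """

    halfspaces: np.ndarray
    vertices: np.ndarray
    k: float

    def contains(self, point: np.ndarray, tol: float = GEOMETRY_TOL) -> bool:
        """True if ``point`` satisfies every half-space within ``tol``."""
        point = np.asarray(point, dtype=float)
        A, b = self.halfspaces[:, :3], self.halfspaces[:, 3]
        return bool(np.all(A @ point <= b + tol))


@dataclass(frozen=True)
class PIIVResult:
    """Pure irrational information volume Delta(k) = V(k) - V(1)."""

    k: float
    volume_k: float
    volume_rational: float
    delta: float


def _halfspace_rows(k: float) -> np.ndarray:
    """Half-space system a.x <= b for the bistable region at ``k``."""
    a = 2.0 * k - 1.0
    rows = [
        [-1.0, 0.0, 0.0, 0.0],  # P1 >= 0
        [1.0, 0.0, 0.0, 1.0],  # P1 <= 1
        [0.0, -1.0, 0.0, 0.0],  # P2 >= 0
        [0.0, 1.0, 0.0, 1.0],  # P2 <= 1
        [0.0, 0.0, -1.0, 0.0],  # P12 >= 0
        [-a, 0.0, 1.0, 1.0 - k],  # (2k-1) P1 - P12 >= k-1
        [0.0, -a, 1.0, 1.0 - k],  # (2k-1) P2 - P12 >= k-1
        [a, a, -1.0, a],  # (2k-1)(P1+P2) - P12 <= 2k-1
    ]
    return np.array(rows, dtype=float)


def _chebyshev_center(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Largest inscribed ball (center, radius) via linear programming."""
    norms = np.linalg.norm(A, axis=1)
    res = linprog(
        c=np.array([0.0, 0.0, 0.0, -1.0]),
        A_ub=np.hstack([A, norms[:, None]]),
        b_ub=b,
        bounds=[(None, None)] * 3 + [(0.0, None)],
        method="highs",
    )
    if not res.success:
        raise EmptyRegionError("half-space system is infeasible")
    return res.x[:3], float(res.x[3])


def _enumerate_vertices(halfspaces: np.ndarray) -> np.ndarray:
    """Vertex enumeration via scipy's half-space intersection."""
    A, b = halfspaces[:, :3], halfspaces[:, 3]
    center, radius = _chebyshev_center(A, b)
    if radius <= GEOMETRY_TOL:
        raise EmptyRegionError(
            f"region is empty or degenerate (inscribed radius {radius:g})"
        )
    # scipy wants rows [normal | offset] with normal.x + offset <= 0.
    hs = np.hstack([A, -b[:, None]])
    intersections = HalfspaceIntersection(hs, center).intersections
    rounded = np.round(intersections, 9)
    _, idx = np.unique(rounded, axis=0, return_index=True)
    return intersections[np.sort(idx)]


def bistable_polytope(k: float) -> ProbPolytope:
    """The accessible region of (P1, P2, P12) at bistable parameter k.

    Returns both the half-space list and the exact vertex list.  At
    k=1 the region is the classical Boole tetrahedron with 4 vertices;
    at k=0.5 the box [0,1]^2 x [0, 1/2].
    """
    k = validate_probability(k, "k")
    halfspaces = _halfspace_rows(k)
    vertices = _enumerate_vertices(halfspaces)
    return ProbPolytope(halfspaces=halfspaces, vertices=vertices, k=k)


def volume(poly: ProbPolytope) -> float:
    """Exact 3-D Lebesgue volume via convex-hull triangulation."""
    if len(poly.vertices) < 4:
        raise EmptyRegionError("fewer than 4 vertices: region has zero volume")
    return float(ConvexHull(poly.vertices).volume)


def piiv(k: float) -> PIIVResult:
    """Pure irrational information volume Delta(k) = V(k) - V(1).

    Defined for any k in [0, 1]; nonnegative and monotonically
    decreasing to 0 on [0.5, 1], where V(0.5) = 1/2 and V(1) = 1/6
    give the maximal Delta of 1/3.
    """
    v_k = volume(bistable_polytope(k))
    v_rational = volume(bistable_polytope(1.0))
    return PIIVResult(k=float(k), volume_k=v_k, volume_rational=v_rational, delta=v_k - v_rational)


def piiv_curve(k_grid) -> list[dict]:
    """Tabulate (k, n_vertices, V(k), Delta(k)) over ``k_grid``.

    Grid order is preserved exactly as given.  Rows are plain dicts
    with keys ``k``, ``n_vertices``, ``volume``, ``piiv`` — ready for
    CSV export.
    """
    v_rational = volume(bistable_polytope(1.0))
    rows = []
    for k in k_grid:
        poly = bistable_polytope(k)
        v = volume(poly)
        rows.append(
            {
                "k": float(k),
                "n_vertices": len(poly.vertices),
                "volume": v,
                "piiv": v - v_rational,
            }
        )
    return rows
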