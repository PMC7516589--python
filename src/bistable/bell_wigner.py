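"""Bell-Wigner polytope checks and bistable attenuation sweeps.

For three events with marginal probabilities p1, p2, p3 and pairwise
conjunction probabilities p12, p13, p23, Boole's conditions of
possible experience are the linear inequalities

    0 <= pi <= 1                          (bounds)
    0 <= pij <= min(pi, pj)               (pair bounds)
    pi + pj - pij <= 1                    (pair unions)
    p1 + p2 + p3 - p12 - p13 - p23 <= 1   (triple union)
    p1 - p12 - p13 + p23 >= 0             (Bell-Wigner)
    p2 - p12 - p23 + p13 >= 0
    p3 - p13 - p23 + p12 >= 0

Together they bound the Bell-Wigner polytope: the set of six-number
assignments realisable by a classical joint distribution over the
eight outcome triples.  Assignments outside the polytope cannot come
from any classical joint — they are "quantum-like".

This module attenuates a classically realisable assignment through
the bistable map f_k(x) = 1 - x - k + 2*k*x with a separate parameter
k_i per event, then tests the inequalities.  Two attenuation schemes
for the pairwise joints are provided (see :func:`attenuate`); both
leave every entry in [0, 1], and both produce genuine Bell-Wigner
violations for suitable (k1, k2, k3) — irrationally distorted
frequencies can leave the classical polytope entirely.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import pk_plus, validate_probability

__all__ = [
    "VIOLATION_TOL",
    "BellWignerAssignment",
    "AttenuationSpec",
    "ViolationRecord",
    "assignment_from_joint",
    "independent_assignment",
    "inequality_values",
    "attenuate",
    "sweep",
    "max_violation",
]

#: An inequality is flagged violated when breached by more than this.
VIOLATION_TOL = 1e-12

_PAIRS = ((1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class BellWignerAssignment:
    """Marginals and pairwise joints for three binary events."""

    p1: float
    p2: float
    p3: float
    p12: float
    p13: float
    p23: float

    def marginal(self, i: int) -> float:
        return (self.p1, self.p2, self.p3)[i - 1]

    def joint(self, i: int, j: int) -> float:
        i, j = min(i, j), max(i, j)
        return {(1, 2): self.p12, (1, 3): self.p13, (2, 3): self.p23}[(i, j)]

    def as_dict(self) -> dict[str, float]:
        return {
            "p1": self.p1, "p2": self.p2, "p3": self.p3,
            "p12": self.p12, "p13": self.p13, "p23": self.p23,
        }


@dataclass(frozen=True)
class AttenuationSpec:
    """One bistable parameter per event."""

    k1: float
    k2: float
    k3: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3"):
            validate_probability(getattr(self, name), name)

    def k(self, i: int) -> float:
        return (self.k1, self.k2, self.k3)[i - 1]


@dataclass(frozen=True)
class ViolationRecord:
    """One inequality's evaluated value and violation flag.

    ``value`` is the quantity printed in the inequality's canonical
    form; ``violated`` is True when the inequality's direction is
    breached by more than :data:`VIOLATION_TOL`.
    """

    inequality: str
    value: float
    violated: bool


def assignment_from_joint(joint) -> BellWignerAssignment:
    """Build an assignment from a full joint over (E1, E2, E3) outcomes.

    ``joint`` is 8 nonnegative numbers summing to 1, ordered
    lexicographically by the occurrence indicators (e1, e2, e3) with 0
    before 1 — i.e. index ``4*e1 + 2*e2 + e3``.  Marginals and
    pairwise joints follow by summation, which guarantees every Boole
    condition holds (classical realizability).
    """
    j = np.asarray(joint, dtype=float).reshape(2, 2, 2)
    if np.any(j < -1e-12):
        raise ValueError("joint probabilities must be nonnegative")
    total = float(j.sum())
    if abs(total - 1.0) > 1e-12:
        raise ValueError(f"joint must sum to 1 (got {total!r})")
    return BellWignerAssignment(
        p1=float(j[1].sum()),
        p2=float(j[:, 1].sum()),
        p3=float(j[:, :, 1].sum()),
        p12=float(j[1, 1].sum()),
        p13=float(j[1, :, 1].sum()),
        p23=float(j[:, 1, 1].sum()),
    )


def independent_assignment(p: float = 0.9) -> BellWignerAssignment:
    """Three independent events with common marginal ``p`` (joints p**2).

    The default, p=0.9, is the documented base fixture for attenuation
    sweeps: strongly expected events whose perceived frequencies are
    then distorted by irrationality.
    """
    p = validate_probability(p, "p")
    q = 1.0 - p
    joint = np.array(
        [q * q * q, q * q * p, q * p * q, q * p * p,
         p * q * q, p * q * p, p * p * q, p * p * p]
    )
    return assignment_from_joint(joint)


def inequality_values(
    a: BellWignerAssignment, tol: float = VIOLATION_TOL
) -> list[ViolationRecord]:
    """Evaluate every Boole / Bell-Wigner inequality for ``a``.

    Inequality identifiers: ``bounds(i)`` for 0 <= pi <= 1,
    ``pair-bounds(i,j)`` for 0 <= pij <= min(pi, pj),
    ``pair-union(i,j)`` for pi + pj - pij <= 1, ``triple-union`` for
    the three-event union bound, and ``bell-wigner(i)`` for the three
    inequalities pi - pij - pik + pjk >= 0.
    """
    records: list[ViolationRecord] = []
    for i in (1, 2, 3):
        v = a.marginal(i)
        records.append(
            ViolationRecord(f"bounds({i})", v, v < -tol or v > 1.0 + tol)
        )
    for i, j in _PAIRS:
        v = a.joint(i, j)
        hi = min(a.marginal(i), a.marginal(j))
        records.append(
            ViolationRecord(f"pair-bounds({i},{j})", v, v < -tol or v > hi + tol)
        )
    for i, j in _PAIRS:
        v = a.marginal(i) + a.marginal(j) - a.joint(i, j)
        records.append(ViolationRecord(f"pair-union({i},{j})", v, v > 1.0 + tol))
    v = a.p1 + a.p2 + a.p3 - a.p12 - a.p13 - a.p23
    records.append(ViolationRecord("triple-union", v, v > 1.0 + tol))
    for i in (1, 2, 3):
        j, m = [x for x in (1, 2, 3) if x != i]
        v = a.marginal(i) - a.joint(i, j) - a.joint(i, m) + a.joint(j, m)
        records.append(ViolationRecord(f"bell-wigner({i})", v, v < -tol))
    return records


def attenuate(
    a: BellWignerAssignment,
    spec: AttenuationSpec,
    *,
    marginals_only: bool = False,
) -> BellWignerAssignment:
    """Distort an assignment through per-event bistable maps.

    Marginals are always mapped pi -> f_{ki}(pi).  For the pairwise
    joints two schemes are available:

    * default — sequential composition pij -> f_{ki}(f_{kj}(pij)).
      The composition of two bistable maps is itself affine and
      symmetric in (ki, kj), so the order of application is
      immaterial.  All entries then vary with every k touching them.
    * ``marginals_only=True`` — the joints are left untouched; only
      the three marginals are attenuated.  This literal scheme
      produces the strongest Bell-Wigner violations, because a
      suppressed marginal can fall below joints that still remember
      the undistorted frequencies.

    ki = 1 for all i is the identity under either scheme; ki = 0.5
    collapses the touched entries to 1/2.
    """
    m = {i: pk_plus(spec.k(i), a.marginal(i)) for i in (1, 2, 3)}
    if marginals_only:
        joints = {pair: a.joint(*pair) for pair in _PAIRS}
    else:
        joints = {
            (i, j): pk_plus(spec.k(i), pk_plus(spec.k(j), a.joint(i, j)))
            for i, j in _PAIRS
        }
    return BellWignerAssignment(
        p1=m[1], p2=m[2], p3=m[3],
        p12=joints[(1, 2)], p13=joints[(1, 3)], p23=joints[(2, 3)],
    )


def sweep(
    a: BellWignerAssignment,
    k1_grid,
    k2_grid,
    k3_grid,
    inequality: str | None = None,
    *,
    marginals_only: bool = False,
) -> pd.DataFrame:
    """Full factorial attenuation sweep over (k1, k2, k3) grids.

    Returns a DataFrame with columns ``k1, k2, k3, ineq_id, value,
    violated``, ordered with k3 varying slowest (one block per k3
    panel), then k1, then k2.  ``inequality`` restricts the output to
    a single inequality id (e.g. ``"bell-wigner(1)"``).
    """
    rows = []
    for k3, k1, k2 in itertools.product(k3_grid, k1_grid, k2_grid):
        spec = AttenuationSpec(k1=float(k1), k2=float(k2), k3=float(k3))
        att = attenuate(a, spec, marginals_only=marginals_only)
        for rec in inequality_values(att):
            if inequality is not None and rec.inequality != inequality:
                continue
            rows.append(
                {
                    "k1": spec.k1, "k2": spec.k2, "k3": spec.k3,
                    "ineq_id": rec.inequality,
                    "value": rec.value,
                    "violated": rec.violated,
                }
            )
    return pd.DataFrame(rows, columns=["k1", "k2", "k3", "ineq_id", "value", "violated"])


def max_violation(table: pd.DataFrame, inequality: str = "bell-wigner(1)") -> pd.Series:
    """The sweep row where ``inequality`` is most strongly violated.

    For the >=0 inequalities this is the most negative value; the row
    is returned even if no entry is formally violated (the minimum is
    still the closest approach to violation).
    """
    sub = table[table["ineq_id"] == inequality]
    if sub.empty:
        raise ValueError(f"no rows for inequality {inequality!r}")
    return sub.loc[sub["value"].idxmin()]
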