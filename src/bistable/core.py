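"""Scalar bistable probability maps and their algebra.

A bistable probability models a decision maker caught between two
cognitive systems.  System 1 (fast, intuitive) favours outcome A with
probability ``k``; System 2 (slow, deliberative) lets that intuition
stand with probability ``p`` and overrides it otherwise.  The final
probability of choosing A is the affine map

    P_k(A) = 1 - p - k + 2*k*p

which is ``p`` at k=1 (fully rational), ``1-p`` at k=0 (fully
inverting), and identically 1/2 at k=0.5 (maximal ambivalence: the two
systems disagree with no means of resolution, so the outcome is a coin
flip).  The map is symmetric in ``k`` and ``p``, so the two parameters
are not jointly identifiable from a single outcome frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BOUNDARY_TOL",
    "SingularInversionError",
    "InfeasibleProbabilityError",
    "validate_probability",
    "pk_plus",
    "pk_minus",
    "classify_regime",
    "invert_map",
    "eta_from_k",
    "k_from_eta",
]

#: Tolerance for floating-point excursions past the [0, 1] boundary.
BOUNDARY_TOL = 1e-12


class SingularInversionError(ValueError):
    """Raised when the bistable map cannot be inverted (slope zero)."""


class InfeasibleProbabilityError(ValueError):
    """Raised when an algebraic solution falls outside [0, 1].

    Out-of-range solutions are surfaced, never silently clipped: they
    indicate that the observed frequency is inconsistent with the model
    at the supplied parameter value.
    """


def validate_probability(value: float, name: str = "value") -> float:
    """Validate that ``value`` lies in [0, 1] and return it as a float.

    Excursions beyond the boundary smaller than :data:`BOUNDARY_TOL`
    are clamped; anything larger raises ``ValueError``.
    """
    x = float(value)
    if not math.isfinite(x) or x < -BOUNDARY_TOL or x > 1.0 + BOUNDARY_TOL:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return min(max(x, 0.0), 1.0)


def pk_plus(k: float, p: float) -> float:
    """Final probability of choosing outcome A (the '+' branch).

    Parameters
    ----------
    k
        Bistable parameter in [0, 1]: the probability that System 1
        opts for A (k=1 rational, k=0 inverting, k=0.5 ambivalent).
    p
        Rational probability in [0, 1]: the probability that System 2
        lets System 1's choice stand.

    Returns
    -------
    float
        ``1 - p - k + 2*k*p``, always inside [0, 1] (affine in p with
        slope 2k-1 and endpoint values 1-k and k).
    """
    k = validate_probability(k, "k")
    p = validate_probability(p, "p")
    # Evaluated as (1-k)(1-p) + k p, algebraically identical to
    # 1 - p - k + 2 k p but exactly symmetric under k <-> p, exactly
    # 1/2 at k = 0.5, and confined to [0, 1] in floating point.
    return (1.0 - k) * (1.0 - p) + k * p


def pk_minus(k: float, p: float) -> float:
    """Final probability of the complementary outcome B: ``p + k - 2*k*p``."""
    k = validate_probability(k, "k")
    p = validate_probability(p, "p")
    return k * (1.0 - p) + p * (1.0 - k)


def classify_regime(k: float) -> str:
    """Classify the bistable parameter into its behavioural regime.

    Returns one of ``"rational"`` (k=1), ``"irrational-inverting"``
    (k=0), ``"ambivalent"`` (k=0.5) or ``"partially-irrational"``.
    Boundary comparisons are exact: regimes are definitional, not
    estimated, so no tolerance band is applied around the special
    values.
    """
    k = validate_probability(k, "k")
    if k == 1.0:
        return "rational"
    if k == 0.0:
        return "irrational-inverting"
    if k == 0.5:
        return "ambivalent"
    return "partially-irrational"


def invert_map(observed: float, known: str, value: float) -> float:
    """Solve ``observed = 1 - p - k + 2*k*p`` for the unknown parameter.

    Parameters
    ----------
    observed
        Observed final-choice probability in [0, 1].
    known
        Which parameter is known: ``"k"`` or ``"p"``.
    value
        The known parameter's value.  Must differ from 0.5, where the
        map is constant in the other parameter and inversion is
        singular.

    Raises
    ------
    SingularInversionError
        If ``value == 0.5``.
    InfeasibleProbabilityError
        If the unique algebraic solution falls outside [0, 1].
    """
    observed = validate_probability(observed, "observed")
    value = validate_probability(value, known)
    if known not in ("k", "p"):
        raise ValueError(f"known must be 'k' or 'p', got {known!r}")
    if value == 0.5:
        raise SingularInversionError(
            f"cannot invert: the map is constant in the unknown when {known}=0.5"
        )
    # The map is symmetric in k and p, so the algebra is identical
    # either way round.
    solution = (observed - 1.0 + value) / (2.0 * value - 1.0)
    if solution < -BOUNDARY_TOL or solution > 1.0 + BOUNDARY_TOL:
        raise InfeasibleProbabilityError(
            f"inverted parameter {solution!r} lies outside [0, 1]; "
            f"observed={observed} is inconsistent with {known}={value}"
        )
    return min(max(solution, 0.0), 1.0)


def eta_from_k(k: float) -> float:
    """Map the bistable parameter to the unsharpness parameter eta = 2k - 1.

    eta ranges over the extended noise interval [-1, 1]: eta=1 is a
    sharp (projective) measurement, eta=0 fully depolarised, eta=-1 the
    inverting measurement.
    """
    k = validate_probability(k, "k")
    return 2.0 * k - 1.0


def k_from_eta(eta: float) -> float:
    """Inverse of :func:`eta_from_k`: k = (eta + 1) / 2."""
    eta = float(eta)
    if not math.isfinite(eta) or eta < -1.0 - BOUNDARY_TOL or eta > 1.0 + BOUNDARY_TOL:
        raise ValueError(f"eta must lie in [-1, 1], got {eta!r}")
    return min(max((eta + 1.0) / 2.0, 0.0), 1.0)


@dataclass(frozen=True)
class BistableOutcome:
    """Both branch probabilities and the regime label for one (k, p)."""

    k: float
    p: float
    p_plus: float
    p_minus: float
    regime: str


def evaluate(k: float, p: float) -> BistableOutcome:
    """Convenience: both branches plus the regime in one record."""
    return BistableOutcome(
        k=float(k),
        p=float(p),
        p_plus=pk_plus(k, p),
        p_minus=pk_minus(k, p),
        regime=classify_regime(k),
    )
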