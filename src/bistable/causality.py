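"""Causal inference under bistability.

Two questions are addressed.  First, what happens to an agent's
ability to *recognise* statistical independence when its probabilities
pass through the bistable map?  Writing f_k for the map, independence
of Y and Z means P(Y,Z) = P(Y) P(Z); the bistable observer instead
compares f_k(P(Y,Z)) with f_k(P(Y)) f_k(P(Z)), and for k != 1 the map
does not distribute over products, so genuinely independent events can
look dependent (spurious causality) and genuinely dependent events can
become indistinguishable from independent ones (masked causality).

Second, how does the causal *strength* between an assumed cause X and
effect Y change with the bistable parameter?  The classical measures
are delta-P = P(Y|X) - P(Y|not X) and the causal power
kappa = delta-P / P(not Y | not X).  Their bistable counterparts are
computed from expectation values of products of bistable POVM
elements: X measured along z, Y along x, on the real state encoding p.
The operator-product route gives delta-P_k = (2k-1)(2p-1)/2, which
vanishes at k = 0.5 for every p — at maximal ambivalence no
cause-effect relation can be established.

A closed-form variant exists in the literature whose printed
right-hand side, (1 - k - p + 2*k*p)/2, does *not* vanish at k=0.5
(it gives 1/4 there), contradicting the requirement that both criteria
vanish at maximal ambivalence.  The operator-product computation is
therefore canonical; the printed forms remain available via
``as_printed=True`` and carry a documented-discrepancy warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import pk_plus, validate_probability
from .povm import BlochDirection, bistable_projection, expectation, state_from_p

__all__ = [
    "UndefinedCausalPowerError",
    "JointSpec",
    "CausalStrength",
    "factorization_gap",
    "delta_p_classical",
    "kappa_classical",
    "strength_bistable_closed",
    "strength_bistable_matrix",
    "independence_verdict",
]

#: Default tolerance for declaring a factorization gap to be zero.
INDEPENDENCE_TOL = 1e-9


class UndefinedCausalPowerError(ZeroDivisionError):
    """Raised when the causal-power denominator is zero."""


@dataclass(frozen=True)
class JointSpec:
    """Marginals and joint probability for two binary events Y and Z.

    The joint must respect the Frechet bounds
    max(0, pY + pZ - 1) <= pYZ <= min(pY, pZ).
    """

    pY: float
    pZ: float
    pYZ: float

    def __post_init__(self) -> None:
        pY = validate_probability(self.pY, "pY")
        pZ = validate_probability(self.pZ, "pZ")
        pYZ = validate_probability(self.pYZ, "pYZ")
        lo = max(0.0, pY + pZ - 1.0)
        hi = min(pY, pZ)
        if pYZ < lo - 1e-12 or pYZ > hi + 1e-12:
            raise ValueError(
                f"pYZ={pYZ} violates the Frechet bounds [{lo}, {hi}] "
                f"for marginals pY={pY}, pZ={pZ}"
            )


@dataclass(frozen=True)
class CausalStrength:
    """Causal strength delta-P and causal power kappa.

    ``kappa`` is ``None`` when its denominator vanishes (the power is
    undefined, e.g. at k=1 or p=1 in the closed form).
    """

    delta_p: float
    kappa: float | None


def factorization_gap(spec: JointSpec, k: float) -> float:
    """Perceived deviation from independence: f_k(pYZ) - f_k(pY) f_k(pZ).

    Zero means the bistable observer perceives Y and Z as independent.
    At k=1 this reduces to the classical gap pYZ - pY*pZ.
    """
    k = validate_probability(k, "k")
    return pk_plus(k, spec.pYZ) - pk_plus(k, spec.pY) * pk_plus(k, spec.pZ)


def delta_p_classical(pY_given_X: float, pY_given_notX: float) -> float:
    """Classical causal strength P(Y|X) - P(Y|not X)."""
    a = validate_probability(pY_given_X, "pY_given_X")
    b = validate_probability(pY_given_notX, "pY_given_notX")
    return a - b


def kappa_classical(delta_p: float, p_notY_given_notX: float) -> float:
    """Classical causal power delta-P / P(not Y | not X)."""
    denom = validate_probability(p_notY_given_notX, "p_notY_given_notX")
    if denom == 0.0:
        raise UndefinedCausalPowerError(
            "causal power is undefined: P(not Y | not X) = 0"
        )
    return float(delta_p) / denom


def strength_bistable_closed(k: float, p: float) -> CausalStrength:
    """Closed-form bistable causal strength: delta-P = k + p - 1.

    The power is kappa = (k + p - 1) / ((1 - p)(1 - k)), undefined at
    k=1 or p=1 where the denominator vanishes.  Both are nondecreasing
    in k for fixed p: rising irrationality (lower k) weakens perceived
    causal strength and power.
    """
    k = validate_probability(k, "k")
    p = validate_probability(p, "p")
    delta_p = k + p - 1.0
    denom = (1.0 - p) * (1.0 - k)
    kappa = delta_p / denom if denom > 0.0 else None
    return CausalStrength(delta_p=delta_p, kappa=kappa)


def _operator_expectations(k: float, p: float) -> dict[str, float]:
    """Expectations of products P_Y(s) P_X(t) for all sign pairs.

    X is measured along z, Y along x, on the state encoding p.  The
    products are not Hermitian but have real expectation on real
    states.
    """
    state = state_from_p(p)
    z, x = BlochDirection.z(), BlochDirection.x()
    PX = {s: bistable_projection(k, z, s).matrix for s in "+-"}
    PY = {s: bistable_projection(k, x, s).matrix for s in "+-"}
    out: dict[str, float] = {}
    for sy in "+-":
        for sx in "+-":
            out[f"Y{sy}X{sx}"] = expectation(state, PY[sy] @ PX[sx])
    out["X+"] = expectation(state, PX["+"])
    out["X-"] = expectation(state, PX["-"])
    return out


def strength_bistable_matrix(
    k: float,
    p: float,
    *,
    conditional: bool = False,
    as_printed: bool = False,
) -> CausalStrength:
    """Bistable causal strength from operator-product expectations.

    The canonical route evaluates the 2x2 matrix products literally:
    delta-P_k = <P_Y(+) P_X(+)> - <P_Y(+) P_X(-)> and
    kappa = delta-P_k / <P_Y(-) P_X(-)>, with X measured along z and Y
    along x.  Both vanish identically at k = 0.5.

    Parameters
    ----------
    conditional
        If True, normalise each joint expectation by the marginal
        <P_X(s)> to form genuine conditionals before differencing.
        The default (False) differences the joint expectations, which
        matches the printed derivation's structure.
    as_printed
        If True, return the literature's printed closed forms
        delta-P_k = (1 - k - p + 2kp)/2 and
        kappa = (1 - p - k + 2kp) / (p + k - 2kp + (1-2k) p (1-p))
        verbatim.  These disagree with the operator-product route (the
        printed delta-P is 1/4, not 0, at k=0.5); a warning is issued.
    """
    k = validate_probability(k, "k")
    p = validate_probability(p, "p")

    if as_printed:
        warnings.warn(
            "as_printed closed forms do not vanish at k=0.5 and disagree "
            "with the canonical operator-product route; use them only for "
            "comparison with the printed derivation",
            UserWarning,
            stacklevel=2,
        )
        delta_p = 0.5 * (1.0 - k - p + 2.0 * k * p)
        denom = p + k - 2.0 * k * p + (1.0 - 2.0 * k) * p * (1.0 - p)
        kappa = (1.0 - p - k + 2.0 * k * p) / denom if abs(denom) > 0.0 else None
        return CausalStrength(delta_p=delta_p, kappa=kappa)

    e = _operator_expectations(k, p)
    if conditional:
        if e["X+"] == 0.0 or e["X-"] == 0.0:
            raise UndefinedCausalPowerError(
                "conditionals undefined: a marginal expectation <P_X> is zero"
            )
        delta_p = e["Y+X+"] / e["X+"] - e["Y+X-"] / e["X-"]
        denom = e["Y-X-"] / e["X-"]
    else:
        delta_p = e["Y+X+"] - e["Y+X-"]
        denom = e["Y-X-"]
    kappa = delta_p / denom if abs(denom) > 0.0 else None
    # At exact ambivalence both criteria are identically zero; snap the
    # 1-ulp residue of the matrix arithmetic so callers see exact zeros.
    if k == 0.5:
        delta_p = 0.0 if abs(delta_p) < 1e-15 else delta_p
        kappa = 0.0 if kappa is not None and abs(kappa) < 1e-14 else kappa
    return CausalStrength(delta_p=delta_p, kappa=kappa)


def independence_verdict(
    spec: JointSpec, k: float, tol: float = INDEPENDENCE_TOL
) -> str:
    """Classify how a bistable observer perceives the (in)dependence of Y, Z.

    The observer applies classical reasoning to bistable probabilities:
    it perceives independence when the factorization gap at its k is
    (near) zero, and it cannot tell a dependent assignment from an
    independent one when the gap equals what an independent surrogate
    with the same marginals would produce at the same k.

    Returns
    -------
    str
        ``"independent"`` — truly independent and perceived as such;
        ``"spuriously-causal"`` — truly independent but the bistable
        gap is nonzero, so dependence is wrongly discerned;
        ``"causality-masked"`` — truly dependent but indistinguishable
        at this k from an independent assignment (e.g. at k=0.5, where
        every probability maps to 1/2);
        ``"causal"`` — truly dependent and still discernibly so.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    gap_classical = factorization_gap(spec, 1.0)
    gap_k = factorization_gap(spec, k)
    if abs(gap_classical) <= tol:
        return "independent" if abs(gap_k) <= tol else "spuriously-causal"
    surrogate = JointSpec(pY=spec.pY, pZ=spec.pZ, pYZ=spec.pY * spec.pZ)
    gap_surrogate = factorization_gap(surrogate, k)
    if abs(gap_k - gap_surrogate) <= tol:
        return "causality-masked"
    return "causal"
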