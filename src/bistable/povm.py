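"""Quantum formalism for bistable measurements.

The bistable map has an exact operator representation: a two-outcome
positive-operator-valued measure (POVM) on a qubit.  For a measurement
direction n-hat on the Bloch sphere the sharp projectors are
pi(+/-) = (I +/- sigma.n)/2, and the bistable POVM elements are

    P(+/-) = (1 - k) I + (2k - 1) pi(+/-)

with eigenvalues {k, 1 - k} regardless of direction.  The rational
probability p is encoded in a real two-component unit state whose
squared amplitudes are (p, 1 - p); the decision probability is the
expectation value <psi| P(+/-) |psi>, which for the z direction
reproduces the scalar bistable map exactly.

Amplitude convention
--------------------
The state is built with components (sqrt(p), sqrt(1-p)).  A literal
row-vector (p, 1-p) bilinear form would give k*p**2 + (1-k)*(1-p)**2,
which does not match the bistable map; only the square-root amplitude
convention reproduces 1 - p - k + 2*k*p.  State vectors are therefore
understood as *encoding* the probabilities (p, 1-p) in their squared
magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import k_from_eta, validate_probability

__all__ = [
    "MATRIX_TOL",
    "BlochDirection",
    "Projector",
    "BistableProjection",
    "StateVector",
    "PovmReport",
    "pauli",
    "sharp_projector",
    "unsharp_projection",
    "bistable_projection",
    "state_from_p",
    "expectation",
    "povm_validate",
]

#: Tolerance for matrix-identity checks (max-abs entry difference).
MATRIX_TOL = 1e-10

_I2 = np.eye(2, dtype=complex)

_PAULI = {
    "x": np.array([[0, 1], [1, 0]], dtype=complex),
    "y": np.array([[0, -1j], [1j, 0]], dtype=complex),
    "z": np.array([[1, 0], [0, -1]], dtype=complex),
}


def pauli(axis: str) -> np.ndarray:
    """Return the standard Pauli matrix for ``axis`` in {'x', 'y', 'z'}."""
    try:
        return _PAULI[axis].copy()
    except KeyError:
        raise ValueError(f"unknown Pauli axis {axis!r}; expected 'x', 'y' or 'z'") from None


@dataclass(frozen=True)
class BlochDirection:
    """A measurement direction on the Bloch sphere.

    Parameters
    ----------
    theta
        Polar angle in [0, pi].
    phi
        Azimuth in [0, 2*pi).
    """

    theta: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= math.pi + 1e-12):
            raise ValueError(f"theta must lie in [0, pi], got {self.theta!r}")
        if not math.isfinite(self.phi):
            raise ValueError(f"phi must be finite, got {self.phi!r}")

    @property
    def n_hat(self) -> np.ndarray:
        """Unit 3-vector (sin t cos f, sin t sin f, cos t)."""
        t, f = self.theta, self.phi
        return np.array(
            [math.sin(t) * math.cos(f), math.sin(t) * math.sin(f), math.cos(t)]
        )

    @classmethod
    def z(cls) -> "BlochDirection":
        return cls(theta=0.0, phi=0.0)

    @classmethod
    def x(cls) -> "BlochDirection":
        return cls(theta=math.pi / 2.0, phi=0.0)

    def sigma_dot_n(self) -> np.ndarray:
        """The operator sigma . n-hat."""
        nx, ny, nz = self.n_hat
        return nx * _PAULI["x"] + ny * _PAULI["y"] + nz * _PAULI["z"]


def _sign_factor(sign: str) -> float:
    if sign in ("+", "plus"):
        return 1.0
    if sign in ("-", "minus"):
        return -1.0
    raise ValueError(f"sign must be '+' or '-', got {sign!r}")


@dataclass(frozen=True)
class Projector:
    """A sharp rank-one projector pi(+/-) = (I +/- sigma.n)/2."""

    matrix: np.ndarray
    sign: str
    direction: BlochDirection


@dataclass(frozen=True)
class BistableProjection:
    """One element of the bistable POVM, with its generating parameters."""

    matrix: np.ndarray
    k: float
    direction: BlochDirection
    sign: str

    @property
    def eigenvalues(self) -> np.ndarray:
        """Sorted real eigenvalues; always {min(k,1-k), max(k,1-k)}."""
        return np.linalg.eigvalsh(self.matrix)


@dataclass(frozen=True)
class StateVector:
    """A real two-component unit state encoding a rational probability.

    ``psi`` has components (sqrt(p), sqrt(1-p)); the squared magnitude
    of the first component is the probability of the rational choice.
    """

    psi: np.ndarray
    p: float


def sharp_projector(direction: BlochDirection, sign: str = "+") -> Projector:
    """The projective (sharp) measurement element (I +/- sigma.n)/2.

    For theta=0 this is diag(1, 0) / diag(0, 1); for theta=pi/2, phi=0
    the '+' element is the x-axis projector [[1,1],[1,1]]/2.
    """
    s = _sign_factor(sign)
    matrix = 0.5 * (_I2 + s * direction.sigma_dot_n())
    return Projector(matrix=matrix, sign="+" if s > 0 else "-", direction=direction)


def unsharp_projection(
    direction: BlochDirection, eta: float, sign: str = "+"
) -> np.ndarray:
    """Noisy two-outcome measurement element I/2 +/- (eta/2) sigma.n.

    ``eta`` ranges over the extended interval [-1, 1]; eta=1 recovers
    the sharp projector, eta=0 the fully depolarised I/2, and the
    substitution eta = 2k - 1 gives the bistable POVM element.
    """
    eta = float(eta)
    if not (-1.0 - 1e-12 <= eta <= 1.0 + 1e-12):
        raise ValueError(f"eta must lie in [-1, 1], got {eta!r}")
    s = _sign_factor(sign)
    return 0.5 * _I2 + s * (eta / 2.0) * direction.sigma_dot_n()


def bistable_projection(
    k: float, direction: BlochDirection, sign: str = "+"
) -> BistableProjection:
    """The bistable POVM element (1-k) I + (2k-1) pi(+/-).

    In the z direction this is diag(k, 1-k) / diag(1-k, k); in the x
    direction [[1/2, +/-(k-1/2)], [+/-(k-1/2), 1/2]].  At k=1 it
    reduces to the sharp projector; at k=0.5 it is I/2, so every state
    yields outcome probability 1/2.
    """
    k = validate_probability(k, "k")
    s = _sign_factor(sign)
    proj = sharp_projector(direction, "+" if s > 0 else "-")
    matrix = (1.0 - k) * _I2 + (2.0 * k - 1.0) * proj.matrix
    return BistableProjection(
        matrix=matrix, k=k, direction=direction, sign=proj.sign
    )


def state_from_p(p: float) -> StateVector:
    """Prepare the real state (sqrt(p), sqrt(1-p)) encoding probability p."""
    p = validate_probability(p, "p")
    psi = np.array([math.sqrt(p), math.sqrt(1.0 - p)], dtype=complex)
    return StateVector(psi=psi, p=p)


def expectation(state: StateVector | np.ndarray, operator: np.ndarray) -> float:
    """Real expectation value <psi| O |psi>.

    ``operator`` may be a single POVM element or a product of elements
    (products arise in sequential-measurement causal-strength
    computations and need not be Hermitian; the real part is returned,
    and for the real states used here the imaginary part vanishes).
    """
    psi = state.psi if isinstance(state, StateVector) else np.asarray(state, dtype=complex)
    operator = np.asarray(operator, dtype=complex)
    if not np.all(np.isfinite(operator.real)) or not np.all(np.isfinite(operator.imag)):
        raise ValueError("operator has non-finite entries")
    return float(np.real(psi.conj() @ operator @ psi))


@dataclass(frozen=True)
class PovmReport:
    """Diagnostics for a candidate POVM.

    Attributes
    ----------
    completeness_deviation
        Max-abs entry of (sum of elements) - I; zero for a valid POVM.
    min_eigenvalue
        Smallest eigenvalue over all elements; negative values mean
        some element is not positive semidefinite.
    idempotency_defects
        Per element, max-abs entry of E@E - E; zero only for sharp
        projectors.  Unsharp POVM elements are *not* idempotent.
    """

    completeness_deviation: float
    min_eigenvalue: float
    idempotency_defects: tuple[float, ...] = field(default=())

    @property
    def is_complete(self) -> bool:
        return self.completeness_deviation <= MATRIX_TOL

    @property
    def is_positive(self) -> bool:
        return self.min_eigenvalue >= -MATRIX_TOL

    @property
    def is_valid(self) -> bool:
        return self.is_complete and self.is_positive

    @property
    def is_projective(self) -> bool:
        return all(d <= MATRIX_TOL for d in self.idempotency_defects)


def povm_validate(elements: list) -> PovmReport:
    """Check completeness, positivity and idempotency of a POVM candidate."""
    if not elements:
        raise ValueError("POVM must contain at least one element")
    mats = [
        np.asarray(e.matrix if hasattr(e, "matrix") else e, dtype=complex)
        for e in elements
    ]
    total = sum(mats)
    completeness = float(np.max(np.abs(total - _I2)))
    min_eig = min(float(np.min(np.linalg.eigvalsh(m))) for m in mats)
    defects = tuple(float(np.max(np.abs(m @ m - m))) for m in mats)
    return PovmReport(
        completeness_deviation=completeness,
        min_eigenvalue=min_eig,
        idempotency_defects=defects,
    )
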