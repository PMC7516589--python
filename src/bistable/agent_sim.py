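"""Monte Carlo simulation of the two-system decision agent.

Each trial is a static two-coin process.  System 1 draws choice A with
probability k; System 2 then intervenes with probability 1 - p, and an
intervention deterministically flips System 1's binary choice (the
only reading consistent with the final-choice probability
P_k(A) = 1 - p - k + 2*k*p).  No temporal ordering is modeled: the
framework is agnostic to the order in which the two systems act.

Reproducibility: one seeded ``numpy.random.Generator`` per run, and
trial i consumes exactly two uniform draws — draw 2i for System 1,
draw 2i+1 for System 2 — so trial streams are byte-identical for
identical configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SingularInversionError, pk_plus, validate_probability

__all__ = [
    "AgentConfig",
    "SimulationResult",
    "KEstimate",
    "RecoveryResult",
    "simulate",
    "estimate_k",
    "recovery_experiment",
]


@dataclass(frozen=True)
class AgentConfig:
    """Configuration of one simulation run."""

    k: float
    p: float
    n_trials: int
    seed: int

    def __post_init__(self) -> None:
        validate_probability(self.k, "k")
        validate_probability(self.p, "p")
        if not isinstance(self.n_trials, (int, np.integer)) or self.n_trials < 1:
            raise ValueError(f"n_trials must be a positive integer, got {self.n_trials!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")


@dataclass(frozen=True)
class SimulationResult:
    """Trial records plus the empirical final-choice frequency.

    ``records`` has columns ``trial``, ``s1_choice`` ('A'/'B'),
    ``intervened`` (bool) and ``final`` ('A'/'B'); it is ``None`` when
    the run was summary-only.
    """

    config: AgentConfig
    freq_A: float
    n_A: int
    records: pd.DataFrame | None = None

    @property
    def expected_freq_A(self) -> float:
        """The model probability pk_plus(k, p) the frequency estimates."""
        return pk_plus(self.config.k, self.config.p)


def simulate(cfg: AgentConfig, *, records: bool = True) -> SimulationResult:
    """Run the two-system agent for ``cfg.n_trials`` trials.

    System 1 chooses A when its uniform draw is below k; System 2
    intervenes (flipping the choice) when its draw is at or above p.
    With ``records=False`` only the summary is computed, which is much
    faster for repeated-experiment harnesses; the trial stream is
    identical either way.
    """
    rng = np.random.default_rng(cfg.seed)
    u = rng.random((cfg.n_trials, 2))
    s1_is_A = u[:, 0] < cfg.k
    intervened = u[:, 1] >= cfg.p
    final_is_A = s1_is_A ^ intervened
    n_A = int(final_is_A.sum())
    frame = None
    if records:
        frame = pd.DataFrame(
            {
                "trial": np.arange(cfg.n_trials),
                "s1_choice": np.where(s1_is_A, "A", "B"),
                "intervened": intervened,
                "final": np.where(final_is_A, "A", "B"),
            }
        )
    return SimulationResult(
        config=cfg, freq_A=n_A / cfg.n_trials, n_A=n_A, records=frame
    )


@dataclass(frozen=True)
class KEstimate:
    """Moment estimate of k from an observed frequency, with its SE.

    ``in_range`` flags whether the raw estimate landed inside [0, 1];
    out-of-range estimates are reported as-is, never clipped, since
    they signal model misfit or sampling noise at small n.
    """

    k_hat: float
    std_error: float | None
    in_range: bool


def estimate_k(freq_A: float, p_known: float, n: int | None = None) -> KEstimate:
    """Invert the bistable map at a known p: k_hat = (freq - 1 + p) / (2p - 1).

    The delta-method standard error sqrt(f(1-f)/n) / |2p - 1| is
    attached when the sample size ``n`` is given.  At p = 0.5 the map
    is constant in k and the estimate is undefined.
    """
    freq_A = validate_probability(freq_A, "freq_A")
    p = validate_probability(p_known, "p_known")
    if p == 0.5:
        raise SingularInversionError(
            "k is not identifiable at p=0.5: the final-choice probability "
            "is 1/2 regardless of k"
        )
    slope = 2.0 * p - 1.0
    k_hat = (freq_A - 1.0 + p) / slope
    se = None
    if n is not None:
        if n < 1:
            raise ValueError("n must be a positive integer")
        se = math.sqrt(freq_A * (1.0 - freq_A) / n) / abs(slope)
    return KEstimate(k_hat=k_hat, std_error=se, in_range=0.0 <= k_hat <= 1.0)


@dataclass(frozen=True)
class RecoveryResult:
    """Bias and RMSE of k recovery over repeated simulations."""

    true_k: float
    true_p: float
    n_trials: int
    n_reps: int
    mean_k_hat: float
    bias: float
    rmse: float
    se_of_mean: float


def recovery_experiment(
    true_k: float,
    true_p: float,
    n_trials: int,
    n_reps: int,
    seed: int,
) -> RecoveryResult:
    """Repeat simulate + estimate_k and summarise estimator quality.

    Each repetition draws its own child seed from a generator seeded
    with ``seed``.  Because the estimator is affine in the binomial
    frequency it is exactly unbiased; the empirical bias shrinks as
    1/sqrt(n_reps * n_trials).
    """
    validate_probability(true_k, "true_k")
    p = validate_probability(true_p, "true_p")
    if p == 0.5:
        raise SingularInversionError("recovery impossible at p=0.5 (k unidentifiable)")
    if n_reps < 1:
        raise ValueError("n_reps must be a positive integer")
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n_reps)
    estimates = np.empty(n_reps)
    for i, child in enumerate(child_seeds):
        result = simulate(
            AgentConfig(k=true_k, p=true_p, n_trials=n_trials, seed=int(child)),
            records=False,
        )
        estimates[i] = estimate_k(result.freq_A, p, n=n_trials).k_hat
    mean = float(estimates.mean())
    bias = mean - true_k
    rmse = float(np.sqrt(np.mean((estimates - true_k) ** 2)))
    se_of_mean = float(estimates.std(ddof=1) / math.sqrt(n_reps)) if n_reps > 1 else float("nan")
    return RecoveryResult(
        true_k=float(true_k),
        true_p=float(true_p),
        n_trials=int(n_trials),
        n_reps=int(n_reps),
        mean_k_hat=mean,
        bias=bias,
        rmse=rmse,
        se_of_mean=se_of_mean,
    )
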