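# Methods

## The model

A binary decision (outcomes A and B) is produced by two interacting
processes. System 1, the fast intuitive process, favours A with
probability `k ∈ [0, 1]`. System 2, the slow deliberative process,
lets System 1's choice stand with probability `p ∈ [0, 1]` and
otherwise overrides it, flipping the binary choice. The final
probability of A is the *bistable map*

    P_k(A) = 1 − p − k + 2kp,       P_k(B) = 1 − P_k(A).

`k = 1` recovers the rational judgement (`P = p`), `k = 0` its
converse (`P = 1 − p`), and `k = 0.5` pins the outcome at 1/2
regardless of `p`: the decision maker is caught between two minds and
the decision is a coin flip. The model is static — no temporal
ordering of the two systems is assumed, and "override" is a
deterministic flip of the binary choice, the only reading consistent
with the map above.

The map is symmetric in `k` and `p`, so the two parameters cannot be
jointly identified from a single outcome frequency; `agent_sim`
therefore only estimates `k` at a *known* `p` (and refuses `p = 0.5`,
where the map is constant in `k`).

### Numerical form

`pk_plus` is evaluated as `(1 − k)(1 − p) + k·p`, algebraically
identical to the canonical form but better behaved in floating point:
it is exactly symmetric under `k ↔ p`, returns exactly `0.5` at
`k = 0.5` for every representable `p`, and cannot leave `[0, 1]`.
Probability arguments are validated on entry with a `1e-12` boundary
tolerance; larger excursions raise. Regime classification
(`rational` / `irrational-inverting` / `ambivalent` /
`partially-irrational`) compares against 1, 0 and 0.5 exactly — the
regimes are definitional, not estimated, so no tolerance band is
applied.

## POVM representation

The map has an exact quantum-measurement form. With Bloch direction
`n̂(ϑ, φ)` and sharp projectors `π± = (I ± σ·n̂)/2`, the bistable POVM
elements are

    P± = (1 − k) I + (2k − 1) π±,

a two-outcome positive-operator-valued measure with eigenvalues
`{k, 1 − k}` in every direction, equal to the standard unsharp
(noisy) measurement `I/2 ± (η/2) σ·n̂` at `η = 2k − 1` on the extended
interval `η ∈ [−1, 1]`. The rational probability is encoded in the
real state `|ψ⟩ = (√p, √(1 − p))ᵀ` and the decision probability is
`⟨ψ|P±|ψ⟩`, which in the z direction reproduces the scalar map to
machine precision.

**Amplitude convention (important).** The source literature writes
the state as `(p, 1 − p)ᵀ`. Taken literally that bilinear form gives
`kp² + (1 − k)(1 − p)²`, which does not reproduce the map (nor the
worked value 0.74 at k=0.8, p=0.9). This package therefore reads that
notation as labelling the *encoded probabilities* and builds the state
with square-root amplitudes. This is the single most consequential
interpretation in the package and the equivalence
`⟨ψ(p)|P±(k, z)|ψ(p)⟩ = P_k(±)` is asserted on a dense grid in the
test suite. States are real and nonnegative (no phases); matrices are
complex throughout because σ_y requires it.

Matrix-identity checks use a `1e-10` max-abs-entry tolerance;
POVM completeness holds to `1e-12`.

## Causal strength under bistability

Classically, `ΔP = P(Y|X) − P(Y|¬X)` and the causal power
`κ = ΔP / P(¬Y|¬X)`. Two bistable versions are provided:

* **Closed form** (`strength_bistable_closed`): `ΔP_k = k + p − 1`,
  `κ = (k + p − 1)/((1 − p)(1 − k))`, implemented verbatim as
  functions of `(k, p)`; `κ` is undefined (None) at `k = 1` or
  `p = 1`. Both are nondecreasing in `k`: rising irrationality
  weakens perceived causal strength.
* **Operator route** (`strength_bistable_matrix`, canonical): X is
  measured along z, Y along x, on the state encoding `p`, and
  `ΔP_k = ⟨P_Y(+) P_X(+)⟩ − ⟨P_Y(+) P_X(−)⟩`,
  `κ = ΔP_k / ⟨P_Y(−) P_X(−)⟩`. A computer-algebra reduction (kept in
  the test suite) shows this equals `(2k − 1)(2p − 1)/2`, which
  vanishes identically at `k = 0.5` — at maximal ambivalence no
  cause–effect relation can be established, for any `p`.

The literature's printed closed forms for the operator route,
`ΔP_k = ½(1 − k − p + 2kp)` and
`κ = (1 − p − k + 2kp)/(p + k − 2kp + (1 − 2k)p(1 − p))`, give
`ΔP = ¼` at `k = 0.5` and so contradict the vanishing-at-ambivalence
requirement. The matrix route is canonical here; the printed forms
are available behind `as_printed=True` (CLI `--as-printed`) and emit a
warning. A `conditional=True` variant normalises the joint
expectations by `⟨P_X(±)⟩` before differencing; the default matches
the printed derivation's joint-expectation structure.

### Independence perception

`factorization_gap` applies the map to marginals and joint and
measures `f_k(p_YZ) − f_k(p_Y) f_k(p_Z)`; at `k = 1` it is the
classical gap. `independence_verdict` classifies: truly independent
inputs are seen as `independent` (gap ≈ 0 at the observer's k) or
`spuriously-causal` (nonzero bistable gap); truly dependent inputs
are `causality-masked` when the observer's gap is indistinguishable
from what an *independent surrogate with the same marginals* would
produce at the same k (at `k = 0.5` every assignment collapses to
this state), else `causal`. The fourth label is this package's
addition: three labels cannot cover the dependent-and-still-visible
case. Default tolerance `1e-9`.

## Accessible-information polytope and PIIV

For two events, Boole's conditions `0 ≤ Pᵢ ≤ 1`, `P₁₂ ≥ 0`,
`P₁₂ ≤ Pᵢ`, `P₁ + P₂ − P₁₂ ≤ 1` bound the tetrahedron with vertices
(0,0,0), (0,1,0), (1,0,0), (1,1,1), volume 1/6. (One printed source
form of the fourth condition has the inequality reversed; the `≤ 1`
orientation is the standard union bound and the one consistent with
the three-event conditions, and is what `boole_check` implements.)

The bistable region replaces the two conjunction constraints by

    (2k − 1) Pᵢ − P₁₂ ≥ k − 1   (i = 1, 2)
    (2k − 1)(P₁ + P₂) − P₁₂ ≤ 2k − 1

plus the base constraints `0 ≤ P₁, P₂ ≤ 1`, `P₁₂ ≥ 0` (required to
bound the region and to reproduce both the k=1 tetrahedron and the
k=0.5 box `0 ≤ P₁₂ ≤ 1/2`, volume 1/2). `P₁, P₂` range over the full
`[0, 1]`: that choice is forced by the k=0.5 volume statement.

Vertices are enumerated exactly by half-space intersection
(`scipy.spatial.HalfspaceIntersection`, interior point from a
Chebyshev-center LP) and volumes by convex-hull triangulation —
deterministic, no Monte Carlo (a seeded rejection-sampling oracle is
kept in the tests for independent confirmation). Duplicate
intersection points are merged at 9-decimal rounding; vertex/facet
consistency is checked at `1e-9`. Empty or lower-dimensional regions
raise `EmptyRegionError` rather than returning 0.

The pure irrational information volume is `Δ(k) = V(k) − V(1)`,
computed as a numeric volume difference: zero at `k = 1`, rising
monotonically to 1/3 at `k = 0.5`. A closed algebraic expression for
Δ(k) circulates in garbled form; the numeric route is authoritative
here and no parsed guess is exposed. `k < 0.5` is handled by the same
machinery (the inequalities reorient naturally) but is outside the
documented `[0.5, 1]` range.

**A note on nesting.** The bistable regions are *not* nested: the
rational apex (1,1,1) violates `(2k−1)P₁ − P₁₂ ≥ k − 1` for every
`k < 1` (the conjunction coordinate is capped at `k` when both
marginals are 1), while the other three rational vertices remain
accessible at every `k ≥ 0.5`. What grows monotonically as `k` falls
is the volume, i.e. the accessible information — and that is the
quantity Δ(k) measures.

## Bell–Wigner polytope and attenuation sweeps

For three events, Boole's conditions comprise the marginal and pair
bounds, the pair and triple union bounds, and the three Bell–Wigner
inequalities `pᵢ − pᵢⱼ − pᵢₘ + pⱼₘ ≥ 0`. Any assignment derived from
a genuine joint distribution over the eight outcome triples satisfies
all of them (`assignment_from_joint` guarantees this by
construction); a property test over random joints confirms it.

`attenuate` distorts an assignment with one bistable parameter per
event. Marginals map through `f_kᵢ`; for the pairwise joints two
schemes exist because the source procedure is underdetermined (it
names only the marginals, yet its reported violation surfaces vary
with parameters absent from the corresponding inequality):

* `marginals_only=True` — the literal reading; joints untouched.
  Produces the strongest violations: a suppressed marginal falls
  below joints that still remember the undistorted frequencies.
* default — sequential composition `pᵢⱼ ↦ f_kᵢ(f_kⱼ(pᵢⱼ))`. The
  composition of two bistable maps is affine with slope
  `(2kᵢ−1)(2kⱼ−1)` and intercept `kᵢ + kⱼ − 2kᵢkⱼ`, symmetric in the
  two parameters, so application order is immaterial.

Neither scheme is claimed to be the source's exact procedure; both
are exposed (CLI `--marginals-only`). On the documented base fixture
— three independent events with marginal 0.9 — the `{0.5,…,1}³`
step-0.1 sweep produces violations under the marginals-only scheme
(208 of 216 cells violate at least one condition; the strongest
Bell–Wigner(1) violation, −0.31, occurs whenever `k₁ = 0.5`, i.e.
when exactly that event's probability turns maximally irrational).
The composed scheme needs correlated bases or `k < 0.5`; a fixed
witness (perfectly correlated events, `k = (0.2, 0.9, 0.05)`,
Bell–Wigner(1) = −0.138) is frozen in the test suite. Fig-5-style
sweeps in this package therefore use the marginals-only scheme.
Violation tolerance: `1e-12` beyond the inequality's direction.

## Synthetic agent simulator

`agent_sim.simulate` draws, per trial, two uniforms from one seeded
`numpy.random.Generator`: draw 2i decides System 1's choice (A iff
`u < k`), draw 2i+1 decides intervention (flip iff `u ≥ p`). Identical
configurations give byte-identical trial streams. The empirical
frequency of A converges to `P_k(A)` with binomial standard error
`√(P(1−P)/n)`; tests use a 3σ envelope at `n = 10⁵`.

`estimate_k` inverts the map at known `p`:
`k̂ = (f − 1 + p)/(2p − 1)`, with delta-method standard error
`√(f(1−f)/n)/|2p−1|`. Estimates outside `[0, 1]` are flagged
(`in_range=False`), never clipped. Because `k̂` is affine in a
binomial frequency it is exactly unbiased; `recovery_experiment`
(default study sizes: `n = 10⁴` trials, 200 replicates) confirms
|bias| < 0.01 and shrinking RMSE with n.

What the generator emulates — and does not. It emulates exactly the
two-coin bistable process, so passing tests show internal consistency
of model, POVM formalism and estimator, not that real decision data
follow the model: there is no trial-to-trial dependence, no learning
or fatigue drift in `k` or `p`, no response-time channel, and no
population heterogeneity. Fitting `k` and `p` jointly from one
condition is impossible in principle (the symmetry above), and no
behavioral-dataset estimation is attempted.

## Problem sizes

Default verification sizes were chosen so each check is statistically
decisive yet runs in seconds: 101×101 grids for operator/scalar
agreement, 1000 random POVM draws, 10⁶-point rejection oracle for the
two anchor volumes, 216-cell Bell–Wigner sweeps, 10⁵-trial
simulations and 200-replicate recovery studies.

## Known limitations

* Two-dimensional Hilbert space only; no mixed states, no sequential
  dynamics beyond the operator products used for causal strength.
* The closed-form Δ(k) and the exact surfaces of the source's
  three-parameter violation figures are not reproducible (garbled
  formula / unpublished inputs); both are covered qualitatively
  (monotonicity, existence and location of violations).
* `independence_verdict` is a perception classifier on a single
  (pY, pZ, pYZ) triple, not a causal-discovery procedure.
* The CLI emits numeric grids (JSON/CSV) only; no figure rendering.
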