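# bistable

Bistable probabilities: a computational framework for modeling
(ir)rational human decision making as the disagreement between two
cognitive systems.

## The problem

Dual-process psychology describes decisions as the joint product of a
fast, intuitive System 1 and a slow, deliberative System 2. When the
two disagree — the decision maker is "in two minds" — judgements
deviate from the axioms of probability theory (the conjunction
fallacy in the Linda problem being the classic case). This package
implements a minimal, fully analysable model of that deviation and
its consequences, for researchers in computational cognitive science
and quantum cognition.

## The model

System 1 favours outcome A with probability *k*; System 2 lets that
intuition stand with probability *p* and otherwise flips the choice.
The final probability of A is the **bistable map**

    P_k(A) = 1 − p − k + 2kp

with *k* = 1 rational (P = p), *k* = 0 inverting (P = 1 − p), and
*k* = 0.5 maximally ambivalent (P = 1/2 for every p). The package
builds four analyses on this map, each in its own module:

| module | contents |
|---|---|
| `bistable.core` | the scalar map, regime classification, inversion, the noise map η = 2k − 1 |
| `bistable.povm` | exact POVM form: `P± = (1−k)I + (2k−1)π±(n̂)`, Bloch directions, states, expectations |
| `bistable.causality` | causal strength ΔP and power κ under bistability; perceived (in)dependence |
| `bistable.polytope` | the accessible region in (P1, P2, P12); exact volumes; PIIV Δ(k) = V(k) − V(1) |
| `bistable.bell_wigner` | Boole's conditions for three events; bistable attenuation; violation sweeps |
| `bistable.agent_sim` | seeded Monte Carlo agent, frequency estimation, k-recovery experiments |
| `bistable.cli` / `bistable.io` | `bistable` command-line front end, config files, CSV/JSON output |

## Worked example

The Linda question without background text: intuition mildly favours
the single-proposition option (k = 0.8) and deliberation rarely
overrides it (p = 0.9):

    $ bistable prob --k 0.8 --p 0.9
    {
      "k": 0.8,
      "p": 0.9,
      "p_minus": 0.26,
      "p_plus": 0.7400000000000001,
      "regime": "partially-irrational"
    }

The final decision favours "bank teller" with probability 0.74. The
same number falls out of the POVM route —
`⟨ψ(0.9)| P+(0.8, ẑ) |ψ(0.9)⟩` — via `bistable povm --k 0.8 --theta 0
--phi 0 --p 0.9`.

How much extra probability space does irrationality open up?

    $ bistable polytope --k-grid 0.5:1.0:0.1 --format csv
    k,n_vertices,volume,piiv
    0.5,8,0.5,0.33333333333333337
    0.59999999999999998,8,0.43333333333333329,0.26666666666666661
    0.69999999999999996,8,0.3666666666666667,0.20000000000000004
    0.80000000000000004,8,0.29999999999999993,0.13333333333333328
    0.90000000000000002,8,0.23333333333333345,0.066666666666666791
    1,4,0.16666666666666666,0

The rational polytope (k = 1) is the Boole tetrahedron of volume 1/6;
at maximal ambivalence the accessible volume triples to 1/2, so the
pure irrational information volume Δ(k) climbs from 0 to 1/3 — an
irrational decision maker has strictly more accessible probability
assignments than a rational one.

And the simulated two-system agent reproduces the map empirically:

    $ bistable simulate --k 0.8 --p 0.9 --n 1000 --seed 7
    {
      "expected_freq_A": 0.7400000000000001,
      "freq_A": 0.735,
      ...
    }

the observed frequency 0.735 sitting well inside the binomial 3σ
envelope of the model value 0.74.

Bell–Wigner sweeps (`bistable bellwigner --grid 0.5:1.0:0.1
--marginals-only`) attenuate three independent events (marginal 0.9)
with per-event bistable parameters and flag every assignment pushed
outside Boole's conditions of possible experience — classically
impossible, "quantum-like" frequencies that arise as soon as one
parameter turns irrational.

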