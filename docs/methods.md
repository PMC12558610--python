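# Methods

This note documents the model, the numerical choices, and the boundaries of
what the test suite establishes.

## Model and assumptions

An infinite, well-mixed population plays one-shot donation games with binary
public reputations. All players share a single opinion of everyone at all
times (public assessment); the resident norm's assessment rule is a
population-level institution, so rare mutants can differ only in their
action rule. Action rules are deterministic by assumption: for generic
parameters the best response in each context is unique, so stochastic action
rules can at best be neutral, never strictly stable. Assessment rules may be
stochastic (entries anywhere in [0, 1]).

Reputation encoding: `B` is index 0, `G` is index 1, everywhere.

### Noise composition

The three error channels are composed in a fixed order — assessment flip
`μ`, then perception mixing `ε_DC` (D-column toward C-column), then
implementation mixing `μ_e` (C-column toward the perception-adjusted
D-column, D-column untouched) — because that is the order in which the
physical events occur: the act is executed, observed, then judged. The
composition is validated against the per-norm closed forms for the
leading-eight assessment differences `R_S(Δ,B)` (e.g.
`μ_e(1−ε_DC)(1−2μ)` for L1), which the test suite checks on a grid of all
three rates. Implementation errors additionally rescale payoffs:
`b‡ = (1−μ_e)b`, `c‡ = (1−μ_e)c`.

A symmetric perception error (`eps_cd`, cooperation seen as defection) is
exposed as an optional generalization but defaults to 0 and is not part of
any standard analysis here. When punishment is in the action set, `ε_DC`
and `μ_e` apply only to the C/D columns and `α`, `β` are never rescaled;
punishment analyses are anchored at `μ`-only noise.

### Stationary state and Δv

`h*` solves `c₂h² + c₁h + c₀ = 0` with the branch
`(−c₁ − √(c₁²−4c₂c₀))/(2c₂)`; when `|c₂| < 1e−12` the linear fallback
`−c₀/c₁` is used (numerically indistinguishable from `c₂ = 0`, avoids
catastrophic cancellation). The residual `|ḣ(h*)|` must be below `1e−10`
or the computation raises; `μ = 0` inputs run through the same code but the
result carries a `non_ergodic` flag. The other quadratic root lies outside
[0, 1] (asserted on random norms), and the flow derivative at `h*` is
negative, so the fixed point is unique and stable for `μ > 0`.

`Δv = numerator/(1−ρ)` with reputation persistence
`ρ = h*·R_S(Δ,G) + (1−h*)·R_S(Δ,B)`; `|ρ| ≤ 1−2μ < 1` for `μ > 0`, so the
gap is always finite there. The per-norm closed forms for the leading eight
(`leading_eight_delta_v`) are implemented with the effective `b‡, c‡` —
required for exact agreement with the generic formula once implementation
errors are active — and exist purely as a redundant cross-check.

### Stability verdicts

Strictness tolerance for margins is `1e−9` (absolute; payoffs are O(b)).
Any margin inside the ±tolerance band yields the verdict *knife-edge*
rather than a forced classification, matching the exclusion of equality
cases from the ESS analysis. The same tolerance governs equalizer residuals
and the brute-force strict-Nash verdict; random norms with minimum
|margin| ≤ 1e−6 are excluded from the oracle-equivalence panels.

With punishment, an action is the best response only if it beats *both*
alternatives; ties are knife-edge.

### Equalizer construction

For a discriminating second-order norm, `Δv = b` and the effective C/D
assessment gap is `(1−2μ)` times the intended one, so the equalizer
condition `[R̃(C) − R̃(D)]·Δv = c` pins the intended gap at `c/((1−2μ)b)`.
Generous Scoring is the base-level-(1, 1) member of this family and
Cautious Scoring the (1, gap) member. The construction is defined for
assessment noise only; feasibility requires `c ≤ (1−2μ)b`.

### Vanishing-error CESS

The limit conditions are evaluated symbolically at zero error rates (not by
numeric limits); the numeric small-`μ` consistency check is a test, not the
definition. Equalities within `1e−12` are knife-edge and classify as
not-CESS, so the boundaries `b = c` and `b = 2c` are excluded, as are the
measure-zero points where the (B,B) action is not forced.

Because the two reputation labels are interchangeable, every CESS has a
G↔B mirrored twin (the population settles all-bad and still cooperates).
`classify_cess` detects both orientations and reports mirrors via a
`relabeled` flag; the enumeration returns canonical (all-good) orientation
only, which is why the deterministic counts are 8 and 8+16 rather than
twice that. The critical ratios (1 for the cooperation branch, 2 for the
defection branch) are *computed* by bisection over branch non-emptiness of
the full 4096-candidate enumeration, to `1e−6`.

The punishment enumeration covers the 18 action rules compatible with the
CESS constraints (`S(G,G)=C`, `S(G,B)∈{D,P}`) crossed with all 4096
deterministic 12-entry assessment tables, grouped by the six
`(S(G,B), S(B,G))` classes with their closed-form Δv numerators
(`b`, `b+β`, `b−c`, `b−c+β`, `b−c+α`, `b−c+α+β`, each over `R(B,G,S(B,G))`).

## The independent oracles

* **Value recursion.** `Δv` is rebuilt by iterating the one-round payoff
  difference from gap 0; convergence is geometric with ratio `(1+ρ)/2`.
  Agreement with the closed form to `1e−9` on 200 seeded random stochastic
  norms is an acceptance property.
* **Invasion payoffs.** The mutant's stationary reputation solves a
  one-dimensional linear fixed point (its reputation changes only on donor
  rounds, under the shared public assessment rule; recipients keep their
  reputation). Payoffs follow the round structure — donor or recipient with
  probability 1/2 — with the mutant never meeting another mutant. The
  brute-force strict-Nash verdict enumerates all 15 (or 80) deviating
  action rules; its equivalence with the margin-based verdict is an
  acceptance property.
* **Monte Carlo.** The finite-population simulator draws a donor and a
  distinct recipient each round and applies implementation, perception and
  assessment noise event by event. Since reputations are public and binary,
  the population state is exactly the number of good players, which is what
  is simulated (an exact lumping, not an approximation). Standard errors
  use batch means (50 batches after a 10% burn-in), which absorb the
  chain's autocorrelation; the acceptance check asks for 3-SE agreement
  with the analytic `h*` at N = 500 and 10⁶ rounds.

## What the synthetic fixtures do and do not establish

Random-norm panels draw assessment entries uniformly on [0, 1] and action
entries uniformly, with `μ ∈ [0.01, 0.3]` and `c/b ∈ [0.1, 0.9]` — a broad,
unstructured sweep of the model's parameter space. Green oracle-equivalence
tests establish internal consistency of the closed forms and the
brute-force computations over that sweep; they do not (and cannot) test
private assessment, non-binary reputations, polymorphic populations, or
finite-population evolutionary dynamics, all of which are out of scope. The
Monte Carlo check validates the infinite-population fixed point at
N = 500, where the O(1/N) sampling-without-replacement bias is well inside
the statistical band; it says nothing about small populations.

## Known limitations

* `μ = 0` is accepted but only flagged: some degenerate all-or-nothing
  norms then have no valid fixed point and raise explicitly. The boundary
  `μ = 0.5` is accepted (all effective assessments 1/2) though every
  stability question is degenerate there.
* `GameParams` does not require `b > c`; analyses at `b ≤ c` simply return
  negative verdicts or empty enumerations.
* Stochastic CESS form a continuum and are spot-checked through
  `classify_cess` on random norms rather than enumerated.
* Mean mutant payoff gaps (the deviation-robustness comparison between
  Simple Standing and Stern Judging) use the unweighted mean over the 15
  mutants.
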