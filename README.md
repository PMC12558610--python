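# normstab

Evolutionary stability of social norms in indirect reciprocity with public
assessment and noise.

## What problem this solves

In indirect reciprocity, people cooperate to build a good reputation, and a
*social norm* governs the feedback loop: an **action rule** `S(X, Y)` says
what a donor with reputation `X` does to a recipient with reputation `Y` in
the donation game (pay cost `c` to confer benefit `b > c`), and an
**assessment rule** `R(X, Y, A)` gives the probability that observers assign
the donor a good reputation after action `A`. Reputations are binary
(good/bad) and public. The package answers, exactly and for arbitrary error
rates, the question: *which norms are evolutionarily stable, and which of
those sustain cooperation?*

It is aimed at researchers in evolutionary game theory who want analytic
verdicts with machine-checkable cross-validation rather than simulation-only
evidence.

## The framework

Three noise sources are composed in a fixed order: assessment error `μ`
(assigned reputations flip), perception error `ε_DC` (defections observed as
cooperation), and implementation error `μ_e` (intended cooperation fails).

1. **Stationary reputation dynamics.** The fraction of good players follows
   a quadratic ODE; its unique stable fixed point `h*` is solved in closed
   form.
2. **Reputation value gap.** The central quantity
   `Δv = lim (v_G(T) − v_B(T))` — the long-run payoff advantage of holding a
   good rather than a bad reputation — has the closed form

   `Δv = [b·χ̄_C(h*,Δ) − c·χ̄_C(Δ,h*)] / (1 − ρ)`,

   where the numerator averages cooperation asymmetries between good and bad
   players and `ρ` is the reputation persistence (costly punishment adds
   `−β·χ̄_P(h*,Δ) − α·χ̄_P(Δ,h*)`).
3. **Stability.** A norm is a strict ESS iff the prescribed action wins in
   every context: `[R̃(X,Y,S) − R̃(X,Y,A′)]·Δv > ζ_S − ζ_{A′}` for all
   alternatives `A′`, with instantaneous costs `ζ_C = c`, `ζ_D = 0`,
   `ζ_P = α`.
4. **Cooperative ESS (CESS).** In the vanishing-error limit the conditions
   become explicit inequalities on the intended assessments. Restricted to
   deterministic rules they reproduce the *leading eight* (stable for
   `b > c`) and the *secondary sixteen* (stable for `b > 2c`); with
   punishment the admissible norms fall into six classes.
5. **Equalizers.** Norms with `[R̃(C) − R̃(D)]·Δv = c` in every context pin
   every mutant's payoff to the residents' — Nash but not ESS, analogous to
   zero-determinant strategies in direct reciprocity.

Every closed-form verdict is cross-checkable against an independent oracle
(`normstab.oracle`): a finite-horizon value recursion for `Δv`, explicit
mutant-invasion payoffs for strict-Nash verdicts, and a finite-population
Monte Carlo simulator for `h*`.

## Worked example

```python
import normstab as ns

params = ns.GameParams(b=1.0, c=0.8)
err = ns.ErrorModel(mu=0.05, mu_e=0.05, eps_dc=0.05)

norm = ns.leading_eight("L6")          # Stern Judging
state = ns.stationary_h(norm, err)
gap = ns.delta_v(norm, params, err)
report = ns.is_ess(norm, params, err)

print(f"h*        = {state.h_star:.6f}")
print(f"p_C       = {ns.action_rates(norm, state)['C']:.6f}")
print(f"delta_v   = {gap.delta_v:.6f}")
print(f"threshold = {ns.l3_l6_threshold(err):.6f}")
print(f"verdict   = {report.verdict} (min margin {report.min_margin:.6f})")

brute = ns.brute_force_strict_nash(norm, params, err)
print(f"oracle    = {brute.verdict} over {brute.n_mutants} mutants "
      f"(min payoff gap {brute.min_gap:.6f})")
```

prints

```
h*        = 0.907041
p_C       = 0.907041
delta_v   = 0.950000
threshold = 1.231148
verdict   = strict ESS (min margin 0.011637)
oracle    = strict over 15 mutants (min payoff gap 0.001864)
```

Reading: under Stern Judging with 5% noise on all three channels, 90.7% of
the population is good at the stationary state and cooperates at the same
rate (Stern Judging cooperates exactly with good recipients); a good
reputation is worth `Δv = (1−μ_e)·b = 0.95` payoff units; the benefit-cost
ratio `b/c = 1.25` clears the critical threshold `1/((1−2μ)(1−μ_e)(1−ε_DC))
= 1.2311`, so the norm is a strict ESS — confirmed independently by the
brute-force comparison against all 15 deviating action rules.

## Command line

A thin CLI wraps the library:

```sh
normstab ess-region --norm L6 --b 1 --c 0.8 --vary mu,eps_dc --grid 50 --out region.csv
normstab payoff-gaps --norm L3 --norm L6 --c 0.2 --out gaps.csv
normstab enumerate --b 1.5 --c 1 --out cess.csv
normstab enumerate --b 3 --c 1 --punish --alpha 0.5 --beta 1 --out cess_p.csv
normstab equalizer-demo --out equalizer.csv
normstab verify --seed 0 --n 200
```

Each command prints a JSON reproducibility header to stderr and writes a
schema-stable CSV; `verify` cross-checks the closed forms against the
brute-force oracles on seeded random norms.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch: the reputation value gap of the all-defect action
rule under arbitrary assessment rules (closed form cross-checked against the
value recursion), and the critical benefit-to-cost ratio at which the
defect branch of the deterministic CESS enumeration becomes non-empty
(bisection over the full 4096-candidate enumeration), writing the results
as JSON.
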