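"""Independent brute-force verification layer.

Nothing here trusts the closed forms in :mod:`normstab.stability`. The
finite-horizon value recursion rebuilds Δv by iterating the one-step payoff
difference between a good and a bad player; the invasion machinery computes
resident and mutant payoffs directly from the round structure (donor or
recipient with probability 1/2 each); the Monte Carlo simulator plays the
donation-game loop itself at finite population size.

Mutant payoff model: in the public-assessment regime mutants share the
resident assessment rule, so a rare mutant differs only in its action rule.
The mutant's reputation evolves on its donor rounds under the shared rule
(receiving does not change a reputation), which gives a one-dimensional
linear fixed point for the mutant's stationary good-reputation probability.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from . import dynamics
from .norms import (
    ACTIONS_CD,
    BAD,
    CONTEXTS,
    COOPERATE,
    DEFECT,
    GOOD,
    PUNISH,
    ActionRule,
    ErrorModel,
    GameParams,
    Norm,
    NormError,
    all_action_rules,
    effective_assessment,
)
from .stability import STRICTNESS_TOL

__all__ = [
    "ValueRecursionState",
    "InvasionOutcome",
    "StrictNashReport",
    "MonteCarloSummary",
    "finite_horizon_gap",
    "mutant_stationary_reputation",
    "invasion_payoffs",
    "brute_force_strict_nash",
    "monte_carlo_population",
]


@dataclasses.dataclass(frozen=True)
class ValueRecursionState:
    """Finite-horizon value-gap recursion v_G(T) − v_B(T).

    The gap starts at 0 and converges geometrically with ratio (1 + ρ)/2,
    where ρ is the reputation persistence; ``gap`` is the last iterate.
    """

    gap: float
    horizon: int
    converged: bool
    rho: float


@dataclasses.dataclass(frozen=True)
class InvasionOutcome:
    """Resident vs rare-mutant comparison under a shared assessment rule."""

    h_mut: float
    pi_res: float
    pi_mut: float

    @property
    def gap(self) -> float:
        return self.pi_res - self.pi_mut


@dataclasses.dataclass(frozen=True)
class StrictNashReport:
    """Brute-force strict-Nash verdict over all deviating action rules."""

    verdict: str
    gaps: dict
    min_gap: float
    worst_mutant: str
    n_mutants: int

    @property
    def is_strict(self) -> bool:
        return self.verdict == "strict"


def finite_horizon_gap(
    norm: Norm,
    params: GameParams,
    err: ErrorModel,
    T: int | None = None,
    tol: float = 1e-12,
    t_max: int = 10**6,
) -> ValueRecursionState:
    """Iterate the one-round recursion for v_G(T) − v_B(T) from gap_0 = 0.

    With ``T`` given, exactly T steps are taken; otherwise iteration stops
    when successive gaps differ by less than ``tol`` (non-convergence within
    ``t_max`` steps is flagged, possible only in mu = 0 degenerate cases).
    """
    state = dynamics.stationary_h(norm, err)
    h = state.h_star
    s = norm.action_rule
    rs = dynamics.prescribed_assessment(norm, err)
    eff = params.effective(err)

    per_round = eff.b * (
        h * s.chi_recipient_diff(COOPERATE, GOOD)
        + (1.0 - h) * s.chi_recipient_diff(COOPERATE, BAD)
    ) - eff.c * (
        h * s.chi_donor_diff(COOPERATE, GOOD)
        + (1.0 - h) * s.chi_donor_diff(COOPERATE, BAD)
    )
    if PUNISH in norm.actions:
        per_round -= params.beta * (
            h * s.chi_recipient_diff(PUNISH, GOOD)
            + (1.0 - h) * s.chi_recipient_diff(PUNISH, BAD)
        ) + params.alpha * (
            h * s.chi_donor_diff(PUNISH, GOOD)
            + (1.0 - h) * s.chi_donor_diff(PUNISH, BAD)
        )
    rho = h * rs.diff_donor(GOOD) + (1.0 - h) * rs.diff_donor(BAD)

    gap = 0.0
    if T is not None:
        for _ in range(T):
            gap = 0.5 * (per_round + gap * (1.0 + rho))
        return ValueRecursionState(gap, T, True, rho)
    for step in range(1, t_max + 1):
        new = 0.5 * (per_round + gap * (1.0 + rho))
        if abs(new - gap) < tol:
            return ValueRecursionState(new, step, True, rho)
        gap = new
    return ValueRecursionState(gap, t_max, False, rho)


def mutant_stationary_reputation(
    resident: Norm,
    mutant_actions: ActionRule,
    err: ErrorModel,
    h_star: float | None = None,
) -> float:
    """Stationary good-reputation probability of a rare mutant.

    Solves h_m = h_m·g_G + (1 − h_m)·g_B with
    g_X = h*·R̃‡(X, G, S'(X, G)) + (1 − h*)·R̃‡(X, B, S'(X, B)).
    """
    if h_star is None:
        h_star = dynamics.stationary_h(resident, err).h_star
    eff = effective_assessment(resident.assessment_rule, err)
    g = {}
    for x in (GOOD, BAD):
        g[x] = h_star * eff[(x, GOOD, mutant_actions[(x, GOOD)])] + (
            1.0 - h_star
        ) * eff[(x, BAD, mutant_actions[(x, BAD)])]
    denom = 1.0 - g[GOOD] + g[BAD]
    if abs(denom) < 1e-14:
        raise dynamics.DegenerateDynamicsError(
            "mutant reputation chain degenerate (denominator ~ 0; mu = 0 case)"
        )
    return g[BAD] / denom


def _role_payoffs(
    donor_rule: ActionRule,
    h_donor: float,
    h_recipient: float,
    params: GameParams,
    err: ErrorModel,
) -> tuple:
    """(expected recipient-side gain, expected donor-side cost) per game."""
    eff = params.effective(err)
    p_d = {GOOD: h_donor, BAD: 1.0 - h_donor}
    p_r = {GOOD: h_recipient, BAD: 1.0 - h_recipient}
    gain = 0.0
    cost = 0.0
    for x in (GOOD, BAD):
        for y in (GOOD, BAD):
            w = p_d[x] * p_r[y]
            action = donor_rule[(x, y)]
            if action == COOPERATE:
                gain += w * eff.b
                cost += w * eff.c
            elif action == PUNISH:
                gain -= w * params.beta
                cost += w * params.alpha
    return gain, cost


def invasion_payoffs(
    resident: Norm,
    mutant_actions: ActionRule,
    params: GameParams,
    err: ErrorModel,
) -> InvasionOutcome:
    """Per-round expected payoffs of residents and a rare mutant.

    The mutant never meets another mutant (vanishing fraction). In each
    round a player is donor or recipient with probability 1/2; donors facing
    the mutant are residents who react only to the mutant's current public
    reputation.
    """
    if PUNISH in mutant_actions.actions_used and PUNISH not in resident.actions:
        raise NormError("mutant uses P but the resident norm has no P assessment")
    h = dynamics.stationary_h(resident, err).h_star
    h_mut = mutant_stationary_reputation(resident, mutant_actions, err, h_star=h)

    res_gain, res_cost = _role_payoffs(resident.action_rule, h, h, params, err)
    pi_res = 0.5 * (res_gain - res_cost)

    # Mutant as recipient: resident donors (reputation ~ h*) react to the
    # mutant's reputation (~ h_mut). Mutant as donor: plays its own rule.
    mut_gain, _ = _role_payoffs(resident.action_rule, h, h_mut, params, err)
    _, mut_cost = _role_payoffs(mutant_actions, h_mut, h, params, err)
    pi_mut = 0.5 * (mut_gain - mut_cost)
    return InvasionOutcome(h_mut, pi_res, pi_mut)


def brute_force_strict_nash(
    resident: Norm,
    params: GameParams,
    err: ErrorModel,
    tol: float = STRICTNESS_TOL,
) -> StrictNashReport:
    """Enumerate every deviating deterministic action rule and compare payoffs.

    15 mutants in the C/D game, 80 with punishment. Verdict ``"strict"`` iff
    every resident-minus-mutant gap exceeds ``tol``; any gap inside the ±tol
    band gives ``"knife-edge"``; otherwise ``"not strict"``.
    """
    resident_code = resident.action_rule.as_string()
    gaps = {}
    for rule in all_action_rules(resident.actions):
        code = rule.as_string()
        if code == resident_code:
            continue
        gaps[code] = invasion_payoffs(resident, rule, params, err).gap
    worst = min(gaps, key=gaps.get)
    min_gap = gaps[worst]
    if any(abs(g) <= tol for g in gaps.values()):
        verdict = "knife-edge"
    elif min_gap > tol:
        verdict = "strict"
    else:
        verdict = "not strict"
    return StrictNashReport(verdict, gaps, min_gap, worst, len(gaps))


# ---------------------------------------------------------------------------
# Finite-population Monte Carlo
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class MonteCarloSummary:
    """Time-averaged statistics of the finite-population simulation.

    Standard errors come from batch means over the post-burn-in rounds, so
    they account for the autocorrelation of the reputation chain.
    """

    good_fraction: float
    good_se: float
    coop_rate: float
    coop_se: float
    n_players: int
    rounds: int
    burn_in: int
    seed: int | None


def monte_carlo_population(
    resident: Norm,
    params: GameParams,
    err: ErrorModel,
    n_players: int = 500,
    rounds: int = 10**6,
    seed: int | None = None,
    burn_in_frac: float = 0.1,
    n_batches: int = 50,
) -> MonteCarloSummary:
    """Simulate the public-reputation donation-game loop at finite N.

    Each round: a random donor and a distinct random recipient are drawn;
    the donor plays its prescribed action subject to implementation error;
    the observed action (subject to perception error) feeds the assessment
    rule, and the assigned reputation is flipped with probability mu. Since
    reputations are public and binary, the population state reduces exactly
    to the number of good players, which is what is simulated.

    Returns time-averaged good fraction and realized cooperation rate with
    batch-means standard errors. The first ``burn_in_frac`` of rounds is
    discarded.
    """
    if n_players < 2:
        raise NormError("need at least 2 players")
    rng = np.random.default_rng(seed)
    s = resident.action_rule
    r = resident.assessment_rule

    # effective good-assessment probability given (X, Y, observed action),
    # with the assessment flip folded in
    r_eff = {
        key: (1.0 - err.mu) * val + err.mu * (1.0 - val)
        for key, val in r.table.items()
    }

    u = rng.random((rounds, 5))
    burn_in = int(burn_in_frac * rounds)
    n_good = n_players // 2
    good_sum = 0.0
    coop_count = 0
    keep = rounds - burn_in
    batch = max(keep // n_batches, 1)
    good_batches: list = []
    coop_batches: list = []
    bg_sum = 0.0
    bc_sum = 0
    bn = 0

    inv_n = 1.0 / n_players
    inv_n1 = 1.0 / (n_players - 1)
    for t in range(rounds):
        donor_good = u[t, 0] < n_good * inv_n
        recip_pool = n_good - (1 if donor_good else 0)
        recip_good = u[t, 1] < recip_pool * inv_n1
        x = GOOD if donor_good else BAD
        y = GOOD if recip_good else BAD
        intended = s[(x, y)]
        actual = intended
        if intended == COOPERATE and u[t, 2] < err.mu_e:
            actual = DEFECT
        observed = actual
        if actual == DEFECT and u[t, 3] < err.eps_dc:
            observed = COOPERATE
        elif actual == COOPERATE and err.eps_cd > 0.0 and u[t, 3] < err.eps_cd:
            observed = DEFECT
        new_good = u[t, 4] < r_eff[(x, y, observed)]
        n_good += (1 if new_good else 0) - (1 if donor_good else 0)
        if t >= burn_in:
            frac = n_good * inv_n
            good_sum += frac
            is_coop = actual == COOPERATE
            coop_count += is_coop
            bg_sum += frac
            bc_sum += is_coop
            bn += 1
            if bn == batch:
                good_batches.append(bg_sum / bn)
                coop_batches.append(bc_sum / bn)
                bg_sum, bc_sum, bn = 0.0, 0, 0

    def se(batches):
        arr = np.asarray(batches, dtype=float)
        if arr.size < 2:
            return float("nan")
        return float(arr.std(ddof=1) / np.sqrt(arr.size))

    return MonteCarloSummary(
        good_fraction=good_sum / keep,
        good_se=se(good_batches),
        coop_rate=coop_count / keep,
        coop_se=se(coop_batches),
        n_players=n_players,
        rounds=rounds,
        burn_in=burn_in,
        seed=seed,
    )
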