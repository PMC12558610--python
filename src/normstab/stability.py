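"""Reputation value gap Δv and evolutionary-stability verdicts.

Δv is the long-run payoff advantage of currently holding a good rather than
a bad reputation. In closed form it is a ratio: the numerator averages the
benefit/cost (and punishment) asymmetries between good and bad players at
the stationary state, and the denominator ``1 − ρ`` measures how quickly the
initial reputation is forgotten (``ρ`` is the reputation persistence).

A norm is a strict ESS exactly when, in every context, the prescribed
action's payoff margin over each alternative action is strictly positive:

    [R̃‡(X,Y,S) − R̃‡(X,Y,A')]·Δv − (ζ_S − ζ_{A'}) > 0

with instantaneous costs ζ_C = c‡, ζ_D = 0, ζ_P = α. Margins within the
strictness tolerance are reported as knife-edge rather than classified.
"""

from __future__ import annotations

import dataclasses

from . import dynamics
from .norms import (
    ACTIONS_CD,
    BAD,
    CONTEXTS,
    COOPERATE,
    DEFECT,
    GOOD,
    PUNISH,
    ErrorModel,
    GameParams,
    Norm,
    NormError,
    effective_assessment,
    equalizer_gap,
    leading_eight,
    named_action_rule,
    _second_order_assessment,
)

__all__ = [
    "STRICTNESS_TOL",
    "ReputationValueGap",
    "ESSReport",
    "EqualizerReport",
    "delta_v",
    "leading_eight_delta_v",
    "is_ess",
    "l3_l6_threshold",
    "equalizer_check",
    "make_second_order_equalizer",
]

#: Absolute strictness tolerance on payoff margins (payoffs are O(b)).
STRICTNESS_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class ReputationValueGap:
    """Δv together with its building blocks.

    ``numerator_benefit``/``numerator_cost`` are the stationary-averaged
    cooperation asymmetries χ̄_C(h*, Δ) and χ̄_C(Δ, h*); the punishment
    analogues are zero without the P action. ``rho`` is the reputation
    persistence h*·R_S(Δ,G) + (1−h*)·R_S(Δ,B); Δv = numerator / (1 − rho).
    """

    delta_v: float
    numerator_benefit: float
    numerator_cost: float
    numerator_punish_received: float
    numerator_punish_paid: float
    rho: float
    h_star: float
    state: dynamics.StationaryState


@dataclasses.dataclass(frozen=True)
class ESSReport:
    """Best-response margins and the resulting stability verdict.

    ``margins`` maps (context, alternative action) to the payoff advantage
    of the prescribed action over that alternative. The verdict is
    ``"strict ESS"`` iff every margin exceeds the tolerance, ``"knife-edge"``
    if some margin is within ±tolerance of zero, else ``"not ESS"``.
    """

    margins: dict
    verdict: str
    binding_context: tuple
    gap: ReputationValueGap
    tolerance: float = STRICTNESS_TOL

    @property
    def is_strict_ess(self) -> bool:
        return self.verdict == "strict ESS"

    @property
    def min_margin(self) -> float:
        return min(self.margins.values())

    def to_records(self) -> list:
        """Flat records (context, alternative, margin, verdict) for CSV."""
        return [
            {
                "context": "".join(ctx),
                "alternative": alt,
                "margin": margin,
                "verdict": self.verdict,
            }
            for (ctx, alt), margin in sorted(self.margins.items())
        ]


@dataclasses.dataclass(frozen=True)
class EqualizerReport:
    """Per-context residuals of the equalizer condition [R̃C−R̃D]Δv = c."""

    is_equalizer: bool
    residuals: dict
    gap: ReputationValueGap
    tolerance: float


def delta_v(
    norm: Norm,
    params: GameParams,
    err: ErrorModel,
    state: dynamics.StationaryState | None = None,
) -> ReputationValueGap:
    """Closed-form reputation value gap Δv at the stationary state.

    With implementation errors active the effective parameters b‡, c‡ and
    the fully composed assessment table enter; punishment terms are included
    iff P is in the action set.
    """
    if state is None:
        state = dynamics.stationary_h(norm, err)
    h = state.h_star
    eff = params.effective(err)
    s = norm.action_rule
    rs = dynamics.prescribed_assessment(norm, err)

    chi_c_recv = h * s.chi_recipient_diff(COOPERATE, GOOD) + (1.0 - h) * s.chi_recipient_diff(COOPERATE, BAD)
    chi_c_paid = h * s.chi_donor_diff(COOPERATE, GOOD) + (1.0 - h) * s.chi_donor_diff(COOPERATE, BAD)
    numerator = eff.b * chi_c_recv - eff.c * chi_c_paid

    chi_p_recv = 0.0
    chi_p_paid = 0.0
    if PUNISH in norm.actions:
        chi_p_recv = h * s.chi_recipient_diff(PUNISH, GOOD) + (1.0 - h) * s.chi_recipient_diff(PUNISH, BAD)
        chi_p_paid = h * s.chi_donor_diff(PUNISH, GOOD) + (1.0 - h) * s.chi_donor_diff(PUNISH, BAD)
        if params.beta is None:
            raise NormError("punishment action present but alpha/beta not set")
        numerator -= params.beta * chi_p_recv + params.alpha * chi_p_paid

    rho = h * rs.diff_donor(GOOD) + (1.0 - h) * rs.diff_donor(BAD)
    if rho >= 1.0 - 1e-15:
        raise dynamics.DegenerateDynamicsError(
            f"reputation persistence rho = {rho:.6g} >= 1: Δv diverges "
            "(possible only at mu = 0)"
        )
    return ReputationValueGap(
        delta_v=numerator / (1.0 - rho),
        numerator_benefit=chi_c_recv,
        numerator_cost=chi_c_paid,
        numerator_punish_received=chi_p_recv,
        numerator_punish_paid=chi_p_paid,
        rho=rho,
        h_star=h,
        state=state,
    )


def leading_eight_delta_v(
    name: str,
    params: GameParams,
    err: ErrorModel,
    state: dynamics.StationaryState | None = None,
) -> float:
    """Closed-form Δv for the leading eight; a redundant cross-check.

    These are the per-norm simplifications of the generic closed form using
    each norm's χ indicators and assessment-difference rows (for example
    Δv = b‡ for L3 and L6, and Δv = b‡ / (1 − (1−h*)(1−2μ)) for L7),
    evaluated with the implementation-error rescaled b‡ and c‡.
    """
    norm = leading_eight(name)  # also validates the name
    if state is None:
        state = dynamics.stationary_h(norm, err)
    u = 1.0 - state.h_star
    z = 1.0 - 2.0 * err.mu
    e = err.eps_dc
    eff = params.effective(err)
    key = norm.name
    if key in ("L1", "L2"):
        numerator = eff.b * state.h_star + eff.c * u
        rs_delta_b = {
            "L1": err.mu_e * (1.0 - e) * z,
            "L2": (err.mu_e - e - err.mu_e * e) * z,
        }[key]
        return numerator / (1.0 - u * rs_delta_b)
    denominator = {
        "L3": 1.0,
        "L4": 1.0 - u * z * e,
        "L5": 1.0 + u * z * e,
        "L6": 1.0,
        "L7": 1.0 - u * z,
        "L8": 1.0 - u * z * (1.0 - e),
    }[key]
    return eff.b / denominator


def is_ess(
    norm: Norm,
    params: GameParams,
    err: ErrorModel,
    tol: float = STRICTNESS_TOL,
) -> ESSReport:
    """Evaluate the strict best-response margins in every context.

    For each context and each alternative action the margin
    ``[R̃‡(X,Y,S) − R̃‡(X,Y,A')]·Δv − (ζ_S − ζ_{A'})`` is reported. All
    margins strictly positive (beyond ``tol``) ⇒ strict ESS; any margin in
    the ±tol band ⇒ knife-edge (never silently classified); otherwise not
    an ESS.
    """
    gap = delta_v(norm, params, err)
    eff_rule = effective_assessment(norm.assessment_rule, err)
    eff_params = params.effective(err)
    margins = {}
    for ctx in CONTEXTS:
        prescribed = norm.action_rule[ctx]
        for alt in norm.actions:
            if alt == prescribed:
                continue
            key = (ctx[0], ctx[1], prescribed)
            margins[(ctx, alt)] = (
                (eff_rule[key] - eff_rule[(ctx[0], ctx[1], alt)]) * gap.delta_v
                - (eff_params.zeta(prescribed) - eff_params.zeta(alt))
            )
    worst = min(margins, key=margins.get)
    min_margin = margins[worst]
    if any(abs(m) <= tol for m in margins.values()):
        verdict = "knife-edge"
    elif min_margin > tol:
        verdict = "strict ESS"
    else:
        verdict = "not ESS"
    return ESSReport(margins, verdict, worst[0], gap, tol)


def l3_l6_threshold(err: ErrorModel) -> float:
    """Critical b/c for Simple Standing (L3) and Stern Judging (L6).

    Both norms are strict ESS iff b/c > 1/((1−2μ)(1−μ_e)(1−ε_DC)); the
    bound diverges as any rate approaches its upper limit.
    """
    factors = (1.0 - 2.0 * err.mu, 1.0 - err.mu_e, 1.0 - err.eps_dc)
    if any(f <= 0.0 for f in factors):
        raise NormError(
            "critical ratio diverges: cooperation cannot be maintained at "
            f"rates mu={err.mu}, mu_e={err.mu_e}, eps_dc={err.eps_dc}"
        )
    return 1.0 / (factors[0] * factors[1] * factors[2])


def equalizer_check(
    norm: Norm,
    params: GameParams,
    err: ErrorModel,
    tol: float = STRICTNESS_TOL,
) -> EqualizerReport:
    """Is the norm an equalizer (every mutant earns exactly the residents' payoff)?

    True iff ``[R̃‡(X,Y,C) − R̃‡(X,Y,D)]·Δv = c‡`` holds in all four
    contexts. Equalizers are Nash equilibria but not ESS: mutants invade
    neutrally.
    """
    if set(norm.actions) != set(ACTIONS_CD):
        raise NormError("equalizer analysis is defined for the C/D action set")
    gap = delta_v(norm, params, err)
    eff_rule = effective_assessment(norm.assessment_rule, err)
    c_eff = params.effective(err).c
    residuals = {
        ctx: (
            eff_rule[(ctx[0], ctx[1], COOPERATE)] - eff_rule[(ctx[0], ctx[1], DEFECT)]
        )
        * gap.delta_v
        - c_eff
        for ctx in CONTEXTS
    }
    ok = all(abs(r) <= tol for r in residuals.values())
    return EqualizerReport(ok, residuals, gap, tol)


def make_second_order_equalizer(
    params: GameParams,
    err: ErrorModel,
    base_levels: tuple = (1.0, 1.0),
) -> Norm:
    """Construct a discriminating second-order equalizer norm.

    ``base_levels = (r_G, r_B)`` are the assessments after cooperation with a
    good and a bad recipient; the corresponding defection entries sit exactly
    the equalizer gap c/((1−2μ)b) below. ``(1, 1)`` yields Generous Scoring,
    ``(1, gap)`` yields Cautious Scoring. Only the assessment error may be
    active (the construction is defined for mu-only noise).
    """
    if err.mu_e != 0.0 or err.eps_dc != 0.0 or err.eps_cd != 0.0:
        raise NormError(
            "second-order equalizers are constructed for assessment error only"
        )
    gap = equalizer_gap(params, err)
    r_g, r_b = base_levels
    for label, level in (("G", r_g), ("B", r_b)):
        if not gap <= level <= 1.0:
            raise NormError(
                f"base level {level} for recipient {label} must lie in "
                f"[{gap:.6g}, 1] to keep all entries in [0, 1]"
            )
    return Norm(
        named_action_rule("DISC"),
        _second_order_assessment(r_g, r_b, gap),
        "equalizer",
    )
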