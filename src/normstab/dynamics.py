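"""Stationary reputation dynamics of a homogeneous resident population.

The fraction ``h(t)`` of players with a good reputation follows a quadratic
ODE whose coefficients are built from the prescribed effective assessments
``R_S(X, Y) = R̃‡(X, Y, S(X, Y))``. For ``mu > 0`` the flow has a unique,
stable fixed point ``h*`` in [0, 1], obtained in closed form from the
quadratic (with a linear fallback when the quadratic coefficient vanishes).
"""

from __future__ import annotations

import dataclasses
import math

from .norms import (
    ACTIONS_CD,
    BAD,
    CONTEXTS,
    COOPERATE,
    GOOD,
    ErrorModel,
    Norm,
    effective_assessment,
)

__all__ = [
    "DegenerateDynamicsError",
    "PrescribedAssessment",
    "StationaryState",
    "prescribed_assessment",
    "h_dot",
    "stationary_h",
    "action_rates",
    "realized_action_rates",
    "is_self_cooperative",
]

#: Quadratic coefficients below this magnitude route through the linear
#: branch of the fixed-point formula (avoids catastrophic cancellation).
_C2_EPS = 1e-12

#: Maximum tolerated |h_dot(h*)| residual; larger residuals raise.
_RESIDUAL_TOL = 1e-10


class DegenerateDynamicsError(RuntimeError):
    """No valid stationary reputation fraction (mu = 0 edge cases only)."""


@dataclasses.dataclass(frozen=True)
class PrescribedAssessment:
    """The 4-entry table R_S(X, Y) = R̃‡(X, Y, S(X, Y))."""

    table: dict

    def __getitem__(self, ctx: tuple) -> float:
        return self.table[ctx]

    def diff_donor(self, recipient: str) -> float:
        """R_S(Δ, Y) = R_S(G, Y) − R_S(B, Y)."""
        return self.table[(GOOD, recipient)] - self.table[(BAD, recipient)]


@dataclasses.dataclass(frozen=True)
class StationaryState:
    """Stationary reputation state of the resident population.

    ``c2 h² + c1 h + c0 = 0`` is the fixed-point equation; ``h_star`` the
    root in [0, 1]; ``p_rates`` the stationary probability of each action in
    a resident-resident interaction. ``non_ergodic`` flags mu = 0 inputs.
    """

    c2: float
    c1: float
    c0: float
    h_star: float
    p_rates: dict
    non_ergodic: bool = False


def prescribed_assessment(norm: Norm, err: ErrorModel) -> PrescribedAssessment:
    """Effective assessment of the action the norm itself prescribes."""
    eff = effective_assessment(norm.assessment_rule, err)
    return PrescribedAssessment(
        {(x, y): eff[(x, y, norm.action_rule[(x, y)])] for (x, y) in CONTEXTS}
    )


def h_dot(h: float, rs: PrescribedAssessment) -> float:
    """Drift of the good fraction at ``h``."""
    return (
        h * h * rs[(GOOD, GOOD)]
        + h * (1.0 - h) * (rs[(GOOD, BAD)] + rs[(BAD, GOOD)])
        + (1.0 - h) * (1.0 - h) * rs[(BAD, BAD)]
        - h
    )


def stationary_h(norm: Norm, err: ErrorModel) -> StationaryState:
    """Solve for the stationary fraction of good players.

    Returns the quadratic coefficients, the root ``h*`` (branch
    ``(−c1 − sqrt(c1² − 4 c2 c0)) / (2 c2)``, or ``−c0/c1`` when the
    quadratic coefficient is numerically zero) and the stationary action
    rates. The residual ``h_dot(h*)`` is verified to be ~0.
    """
    rs = prescribed_assessment(norm, err)
    c2 = rs[(GOOD, GOOD)] - rs[(GOOD, BAD)] - rs[(BAD, GOOD)] + rs[(BAD, BAD)]
    c1 = rs[(GOOD, BAD)] + rs[(BAD, GOOD)] - 2.0 * rs[(BAD, BAD)] - 1.0
    c0 = rs[(BAD, BAD)]

    if abs(c2) < _C2_EPS:
        if abs(c1) < _C2_EPS:
            raise DegenerateDynamicsError(
                "reputation dynamics degenerate (c2 = c1 = 0); requires mu > 0"
            )
        h = -c0 / c1
    else:
        disc = c1 * c1 - 4.0 * c2 * c0
        if disc < 0.0:
            if disc < -1e-12:
                raise DegenerateDynamicsError(
                    f"no real stationary point (discriminant {disc:.3g})"
                )
            disc = 0.0
        h = (-c1 - math.sqrt(disc)) / (2.0 * c2)

    if not -1e-12 <= h <= 1.0 + 1e-12:
        raise DegenerateDynamicsError(
            f"stationary root h* = {h:.6g} outside [0, 1] (mu = 0 edge case)"
        )
    h = min(max(h, 0.0), 1.0)

    residual = h_dot(h, rs)
    if abs(residual) > _RESIDUAL_TOL:
        raise DegenerateDynamicsError(
            f"fixed-point residual |h_dot(h*)| = {abs(residual):.3g} exceeds "
            f"{_RESIDUAL_TOL}"
        )

    rates = _action_rates(norm, h)
    return StationaryState(c2, c1, c0, h, rates, non_ergodic=err.non_ergodic)


def _action_rates(norm: Norm, h: float) -> dict:
    s = norm.action_rule
    rates = {}
    for action in norm.actions:
        rates[action] = (
            h * h * s.chi(action, GOOD, GOOD)
            + h * (1.0 - h) * (s.chi(action, GOOD, BAD) + s.chi(action, BAD, GOOD))
            + (1.0 - h) * (1.0 - h) * s.chi(action, BAD, BAD)
        )
    return rates


def action_rates(norm: Norm, state: StationaryState) -> dict:
    """Stationary probability of each *intended* action (resident→resident)."""
    return _action_rates(norm, state.h_star)


def realized_action_rates(norm: Norm, state: StationaryState, err: ErrorModel) -> dict:
    """Action rates after implementation errors.

    A fraction ``mu_e`` of intended cooperations is executed as defection;
    intended defections (and punishments) are executed faithfully.
    """
    rates = dict(action_rates(norm, state))
    slip = err.mu_e * rates.get(COOPERATE, 0.0)
    if COOPERATE in rates:
        rates[COOPERATE] -= slip
        rates["D"] = rates.get("D", 0.0) + slip
    return rates


def is_self_cooperative(norm: Norm) -> bool:
    """Does the population cooperate fully in the vanishing-error limit?

    Evaluated at the intended (error-free) assessment values: the all-good
    branch requires ``R_S(G,G) = 1``, ``R_S(G,B) + R_S(B,G) > 1`` and
    ``S(G,G) = C``. Because the two reputation labels are interchangeable,
    the G↔B relabeled norm is checked symmetrically (all-bad branch).
    """
    return _self_cooperative_branch(norm) or _self_cooperative_branch(norm.relabeled())


def _self_cooperative_branch(norm: Norm) -> bool:
    s, r = norm.action_rule, norm.assessment_rule

    def rs(x, y):
        return r[(x, y, s[(x, y)])]

    return (
        s[(GOOD, GOOD)] == COOPERATE
        and rs(GOOD, GOOD) == 1.0
        and rs(GOOD, BAD) + rs(BAD, GOOD) > 1.0
    )
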