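"""Core domain types for indirect reciprocity with binary public reputations.

The model: an infinite population plays pairwise donation games. A donor with
reputation ``X`` meeting a recipient with reputation ``Y`` acts according to a
deterministic action rule ``S(X, Y)``; observers then assign the donor a good
reputation with probability ``R(X, Y, A)`` (the assessment rule). The pair
``(S, R)`` is a *social norm*. Reputations are binary (``G``/``B``) and public:
everyone agrees on them at all times.

Three noise sources are supported and composed in a fixed order:

1. assessment error ``mu``: the assigned reputation is flipped,
2. perception error ``eps_dc``: a defection is observed as cooperation
   (optionally also ``eps_cd``, the symmetric variant),
3. implementation error ``mu_e``: an intended cooperation comes out as a
   defection (defections are always implemented faithfully).

Reputation encoding used everywhere in this package: ``B`` is index 0 and
``G`` is index 1.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GOOD",
    "BAD",
    "REPUTATIONS",
    "COOPERATE",
    "DEFECT",
    "PUNISH",
    "ACTIONS_CD",
    "ACTIONS_CDP",
    "CONTEXTS",
    "NormError",
    "flip_reputation",
    "ErrorModel",
    "GameParams",
    "ActionRule",
    "AssessmentRule",
    "Norm",
    "effective_assessment",
    "effective_game_params",
    "equalizer_gap",
    "leading_eight",
    "LEADING_EIGHT_NAMES",
    "named_action_rule",
    "ACTION_RULE_NAMES",
    "generous_scoring",
    "cautious_scoring",
    "catalog_norm",
    "catalog_names",
    "sample_random_norm",
    "extend_with_punishment",
    "all_action_rules",
    "save_norm",
    "load_norm",
]

GOOD = "G"
BAD = "B"
#: Canonical reputation order; ``B`` indexed 0, ``G`` indexed 1.
REPUTATIONS = (BAD, GOOD)

COOPERATE = "C"
DEFECT = "D"
PUNISH = "P"
ACTIONS_CD = (COOPERATE, DEFECT)
ACTIONS_CDP = (COOPERATE, DEFECT, PUNISH)

#: Donor/recipient reputation contexts (X, Y) in canonical order.
CONTEXTS = ((GOOD, GOOD), (GOOD, BAD), (BAD, GOOD), (BAD, BAD))

_CONTEXT_KEYS = {"".join(ctx): ctx for ctx in CONTEXTS}


class NormError(ValueError):
    """Invalid norm, rule, rate, parameter, or catalog lookup."""


def flip_reputation(reputation: str) -> str:
    """Return the opposite reputation label."""
    if reputation == GOOD:
        return BAD
    if reputation == BAD:
        return GOOD
    raise NormError(f"unknown reputation {reputation!r}")


@dataclasses.dataclass(frozen=True)
class ErrorModel:
    """Noise rates of the reputation system.

    Parameters
    ----------
    mu:
        Assessment error in ``[0, 0.5]``: the assigned reputation is the
        opposite of the prescribed one with this probability. ``mu > 0``
        makes the reputation dynamics ergodic; ``mu = 0`` is accepted but
        flagged via :attr:`non_ergodic` (and ``mu = 0.5`` is the degenerate
        boundary where all effective assessments equal one half).
    mu_e:
        Implementation error in ``[0, 1)``: an intended cooperation is
        executed as defection with this probability.
    eps_dc:
        Perception error in ``[0, 1)``: an executed defection is observed as
        cooperation with this probability.
    eps_cd:
        Optional symmetric perception error (cooperation observed as
        defection); a generalization kept at 0 in all standard analyses.
    """

    mu: float = 0.0
    mu_e: float = 0.0
    eps_dc: float = 0.0
    eps_cd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 0.5:
            raise NormError(f"assessment error mu={self.mu} outside [0, 0.5]")
        for name in ("mu_e", "eps_dc", "eps_cd"):
            val = getattr(self, name)
            if not 0.0 <= val < 1.0:
                raise NormError(f"error rate {name}={val} outside [0, 1)")

    @property
    def non_ergodic(self) -> bool:
        """True when ``mu = 0`` (ergodicity of reputations not guaranteed)."""
        return self.mu == 0.0


@dataclasses.dataclass(frozen=True)
class GameParams:
    """Payoff parameters of the (extended) donation game.

    ``b`` is the benefit a cooperating donor confers, ``c`` the cost they
    pay; the interesting regime is ``b > c > 0`` but ``b <= c`` is accepted
    (stability analyses then simply fail). With costly punishment, the donor
    pays ``alpha > 0`` to reduce the recipient's payoff by ``beta > 0``.
    """

    b: float
    c: float
    alpha: float | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise NormError(f"benefit b={self.b} must be positive")
        if not self.c > 0:
            raise NormError(f"cost c={self.c} must be positive")
        if (self.alpha is None) != (self.beta is None):
            raise NormError("alpha and beta must be supplied together")
        if self.alpha is not None and not (self.alpha > 0 and self.beta > 0):
            raise NormError("punishment parameters alpha, beta must be positive")

    @property
    def has_punishment(self) -> bool:
        return self.alpha is not None

    def effective(self, err: ErrorModel) -> "GameParams":
        """Implementation-error rescaled parameters b‡=(1−mu_e)b, c‡=(1−mu_e)c.

        ``alpha`` and ``beta`` are left unchanged (implementation errors are
        defined for the cooperate/defect pair only).
        """
        scale = 1.0 - err.mu_e
        return GameParams(self.b * scale, self.c * scale, self.alpha, self.beta)

    def zeta(self, action: str) -> float:
        """Instantaneous cost of an action: c for C, 0 for D, alpha for P."""
        if action == COOPERATE:
            return self.c
        if action == DEFECT:
            return 0.0
        if action == PUNISH:
            if self.alpha is None:
                raise NormError("punishment cost alpha not set")
            return self.alpha
        raise NormError(f"unknown action {action!r}")


def _check_context(ctx: tuple) -> None:
    if ctx not in _CONTEXT_KEYS.values():
        raise NormError(f"unknown context {ctx!r}")


@dataclasses.dataclass
class ActionRule:
    """Deterministic map from context (X, Y) to the donor's action.

    Stochastic action rules are excluded by design: for generic parameters
    the best response in each context is unique, so only deterministic rules
    can be evolutionarily stable.
    """

    table: dict

    def __post_init__(self) -> None:
        if set(self.table) != set(CONTEXTS):
            raise NormError("action rule must be defined on all 4 contexts")
        for ctx, action in self.table.items():
            if action not in ACTIONS_CDP:
                raise NormError(f"unknown action {action!r} in context {ctx}")

    def __getitem__(self, ctx: tuple) -> str:
        return self.table[ctx]

    @property
    def actions_used(self) -> frozenset:
        return frozenset(self.table.values())

    def chi(self, action: str, donor: str, recipient: str) -> float:
        """Indicator χ_A(X, Y): 1 if the rule prescribes ``action`` here."""
        return 1.0 if self.table[(donor, recipient)] == action else 0.0

    def chi_recipient_diff(self, action: str, donor: str) -> float:
        """χ_A(X, Δ) = χ_A(X, G) − χ_A(X, B)."""
        return self.chi(action, donor, GOOD) - self.chi(action, donor, BAD)

    def chi_donor_diff(self, action: str, recipient: str) -> float:
        """χ_A(Δ, Y) = χ_A(G, Y) − χ_A(B, Y)."""
        return self.chi(action, GOOD, recipient) - self.chi(action, BAD, recipient)

    def relabeled(self) -> "ActionRule":
        """The same rule with the G and B labels interchanged."""
        return ActionRule(
            {
                (x, y): self.table[(flip_reputation(x), flip_reputation(y))]
                for (x, y) in CONTEXTS
            }
        )

    def as_string(self) -> str:
        """Compact 4-letter encoding over contexts (GG, GB, BG, BB)."""
        return "".join(self.table[ctx] for ctx in CONTEXTS)

    @classmethod
    def from_string(cls, code: str) -> "ActionRule":
        if len(code) != 4:
            raise NormError(f"action string {code!r} must have 4 letters")
        return cls(dict(zip(CONTEXTS, code)))


@dataclasses.dataclass
class AssessmentRule:
    """Map from (context, action) to the probability of a good assessment.

    Entries lie in ``[0, 1]``; the rule is *deterministic* when every entry
    is 0 or 1. The table must cover every action in ``actions`` (8 entries
    for the C/D game, 12 when punishment is active).
    """

    table: dict
    actions: tuple = ACTIONS_CD

    def __post_init__(self) -> None:
        expected = {(x, y, a) for (x, y) in CONTEXTS for a in self.actions}
        if set(self.table) != expected:
            missing = expected - set(self.table)
            extra = set(self.table) - expected
            raise NormError(
                f"assessment table mismatch (missing {sorted(missing)}, "
                f"unexpected {sorted(extra)})"
            )
        for key, value in self.table.items():
            if not 0.0 <= value <= 1.0:
                raise NormError(f"assessment {key} = {value} outside [0, 1]")

    def __getitem__(self, key: tuple) -> float:
        return self.table[key]

    @property
    def deterministic(self) -> bool:
        return all(v in (0.0, 1.0) for v in self.table.values())

    def relabeled(self) -> "AssessmentRule":
        """G↔B relabeling: contexts mirrored and probabilities complemented."""
        return AssessmentRule(
            {
                (x, y, a): 1.0
                - self.table[(flip_reputation(x), flip_reputation(y), a)]
                for (x, y, a) in self.table
            },
            self.actions,
        )


@dataclasses.dataclass
class Norm:
    """A social norm: an action rule paired with an assessment rule."""

    action_rule: ActionRule
    assessment_rule: AssessmentRule
    name: str | None = None

    def __post_init__(self) -> None:
        unused = self.action_rule.actions_used - set(self.assessment_rule.actions)
        if unused:
            raise NormError(
                f"action rule uses {sorted(unused)} not covered by the "
                f"assessment rule (actions {self.assessment_rule.actions})"
            )

    @property
    def actions(self) -> tuple:
        """The active action set of the analysis."""
        return self.assessment_rule.actions

    def relabeled(self) -> "Norm":
        name = f"{self.name}-relabeled" if self.name else None
        return Norm(self.action_rule.relabeled(), self.assessment_rule.relabeled(), name)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "actions": list(self.actions),
            "action_rule": {
                "".join(ctx): self.action_rule[ctx] for ctx in CONTEXTS
            },
            "assessment_rule": {
                f"{x}{y}.{a}": float(self.assessment_rule[(x, y, a)])
                for (x, y) in CONTEXTS
                for a in self.actions
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "Norm":
        allowed = {"name", "actions", "action_rule", "assessment_rule"}
        unknown = set(data) - allowed
        if unknown:
            raise NormError(f"unknown norm-file fields {sorted(unknown)}")
        for field in ("actions", "action_rule", "assessment_rule"):
            if field not in data:
                raise NormError(f"norm file missing field {field!r}")
        actions = tuple(data["actions"])
        if actions not in (ACTIONS_CD, ACTIONS_CDP):
            raise NormError(f"actions must be {ACTIONS_CD} or {ACTIONS_CDP}")
        action_table = {}
        for key, action in dict(data["action_rule"]).items():
            if key not in _CONTEXT_KEYS:
                raise NormError(f"unknown action_rule context {key!r}")
            action_table[_CONTEXT_KEYS[key]] = action
        assess_table = {}
        for key, value in dict(data["assessment_rule"]).items():
            try:
                ctx_key, action = key.split(".")
                ctx = _CONTEXT_KEYS[ctx_key]
            except (ValueError, KeyError):
                raise NormError(f"malformed assessment key {key!r}") from None
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise NormError(f"assessment {key!r} = {value!r} is not a number")
            assess_table[(ctx[0], ctx[1], action)] = float(value)
        return cls(
            ActionRule(action_table),
            AssessmentRule(assess_table, actions),
            data.get("name"),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=kwargs.pop("indent", 2), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "Norm":
        return cls.from_dict(json.loads(text))


def save_norm(norm: Norm, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(norm.to_json())
        fh.write("\n")


def load_norm(path: str | os.PathLike) -> Norm:
    with open(path, "r", encoding="utf-8") as fh:
        return Norm.from_json(fh.read())


# ---------------------------------------------------------------------------
# Effective (noise-composed) rules
# ---------------------------------------------------------------------------


def effective_assessment(rule: AssessmentRule, err: ErrorModel) -> AssessmentRule:
    """Compose the assessment rule with all noise sources.

    The composition order is fixed: first the assessment error ``mu`` flips
    every entry (``R̃ = (1−mu)R + mu(1−R)``), then the perception error mixes
    the D column toward the C column (``R̃*(D) = (1−eps_dc)R̃(D) +
    eps_dc·R̃(C)``; symmetrically for ``eps_cd``), and finally the
    implementation error mixes the C column toward the perception-adjusted D
    column (``R̃‡(C) = (1−mu_e)R̃*(C) + mu_e·R̃*(D)``; the D column is
    untouched). A punishment column, if present, is subject to the
    assessment error only.

    With only ``mu`` active every effective entry lies in ``[mu, 1−mu]``.
    """
    out = {}
    for (x, y) in CONTEXTS:
        tilde = {
            a: (1.0 - err.mu) * rule[(x, y, a)] + err.mu * (1.0 - rule[(x, y, a)])
            for a in rule.actions
        }
        star = dict(tilde)
        if COOPERATE in tilde and DEFECT in tilde:
            star[DEFECT] = (1.0 - err.eps_dc) * tilde[DEFECT] + err.eps_dc * tilde[COOPERATE]
            star[COOPERATE] = (1.0 - err.eps_cd) * tilde[COOPERATE] + err.eps_cd * tilde[DEFECT]
            final_c = (1.0 - err.mu_e) * star[COOPERATE] + err.mu_e * star[DEFECT]
            star[COOPERATE] = final_c
        for a, value in star.items():
            out[(x, y, a)] = value
    return AssessmentRule(out, rule.actions)


def effective_game_params(params: GameParams, err: ErrorModel) -> GameParams:
    """Alias for :meth:`GameParams.effective` (b‡, c‡ rescaling)."""
    return params.effective(err)


# ---------------------------------------------------------------------------
# Catalog of named norms
# ---------------------------------------------------------------------------

# The leading eight, encoded over contexts (GG, GB, BG, BB) as the action
# string, the assessments after observed cooperation, and after observed
# defection.
_LEADING_EIGHT = {
    "L1": ("CDCC", "1111", "0100"),  # Standing
    "L2": ("CDCC", "1011", "0100"),  # Consistent Standing
    "L3": ("CDCD", "1111", "0101"),  # Simple Standing
    "L4": ("CDCD", "1110", "0101"),
    "L5": ("CDCD", "1011", "0101"),
    "L6": ("CDCD", "1010", "0101"),  # Stern Judging
    "L7": ("CDCD", "1110", "0100"),  # Staying
    "L8": ("CDCD", "1010", "0100"),  # Judging
}

LEADING_EIGHT_NAMES = tuple(_LEADING_EIGHT)

_LEADING_EIGHT_ALIASES = {
    "standing": "L1",
    "consistent standing": "L2",
    "simple standing": "L3",
    "stern judging": "L6",
    "staying": "L7",
    "judging": "L8",
}

_ACTION_RULES = {
    "ALLC": "CCCC",
    "ALLD": "DDDD",
    "DISC": "CDCD",
    "ADISC": "DCDC",
}

ACTION_RULE_NAMES = tuple(_ACTION_RULES)


def leading_eight(name: str) -> Norm:
    """Return one of the leading-eight norms (L1..L8) cell-for-cell."""
    key = _LEADING_EIGHT_ALIASES.get(name.lower(), name.upper())
    if key not in _LEADING_EIGHT:
        raise NormError(
            f"unknown leading-eight norm {name!r}; available: {LEADING_EIGHT_NAMES}"
        )
    s_code, rc, rd = _LEADING_EIGHT[key]
    table = {}
    for i, ctx in enumerate(CONTEXTS):
        table[(ctx[0], ctx[1], COOPERATE)] = float(rc[i])
        table[(ctx[0], ctx[1], DEFECT)] = float(rd[i])
    return Norm(ActionRule.from_string(s_code), AssessmentRule(table), key)


def named_action_rule(name: str) -> ActionRule:
    """ALLC, ALLD, DISC (cooperate with G only) or ADISC action rules."""
    key = name.upper()
    if key not in _ACTION_RULES:
        raise NormError(
            f"unknown action rule {name!r}; available: {ACTION_RULE_NAMES}"
        )
    return ActionRule.from_string(_ACTION_RULES[key])


def equalizer_gap(params: GameParams, err: ErrorModel) -> float:
    """The intended C/D assessment gap c/((1−2mu)b) of an equalizer norm.

    An equalizer must satisfy ``[R̃(C) − R̃(D)]·Δv = c`` in every context;
    for a discriminating second-order norm Δv = b and the effective gap is
    (1−2mu) times the intended one, so the intended gap is c/((1−2mu)b).
    """
    if err.mu >= 0.5:
        raise NormError("equalizer norms require mu < 0.5")
    gap = params.c / ((1.0 - 2.0 * err.mu) * params.b)
    if gap > 1.0:
        raise NormError(
            f"equalizer gap c/((1-2mu)b) = {gap:.6g} exceeds 1: infeasible"
        )
    return gap


def _second_order_assessment(c_level_g: float, c_level_b: float, gap: float) -> AssessmentRule:
    levels = {GOOD: c_level_g, BAD: c_level_b}
    table = {}
    for (x, y) in CONTEXTS:
        table[(x, y, COOPERATE)] = levels[y]
        table[(x, y, DEFECT)] = levels[y] - gap
    return AssessmentRule(table)


def generous_scoring(params: GameParams, err: ErrorModel) -> Norm:
    """Generous Scoring (GSCO): first-order equalizer, R(*,*,C)=1."""
    gap = equalizer_gap(params, err)
    norm = Norm(
        named_action_rule("DISC"), _second_order_assessment(1.0, 1.0, gap), "GSCO"
    )
    return norm


def cautious_scoring(params: GameParams, err: ErrorModel) -> Norm:
    """Cautious Scoring: second-order equalizer with R(*,B,D)=0."""
    gap = equalizer_gap(params, err)
    return Norm(
        named_action_rule("DISC"),
        _second_order_assessment(1.0, gap, gap),
        "CautiousScoring",
    )


def catalog_names() -> tuple:
    return LEADING_EIGHT_NAMES + ("GSCO", "CautiousScoring") + ACTION_RULE_NAMES


def catalog_norm(
    name: str,
    params: GameParams | None = None,
    err: ErrorModel | None = None,
    assessment: AssessmentRule | None = None,
) -> Norm:
    """Look up a named norm.

    L1..L8 need no parameters; GSCO and CautiousScoring need ``params`` and
    ``err`` (their assessment entries depend on b, c, mu); the pure action
    rules ALLC/ALLD/DISC/ADISC need an ``assessment`` rule to pair with.
    """
    key = _LEADING_EIGHT_ALIASES.get(name.lower(), name)
    upper = key.upper()
    if upper in _LEADING_EIGHT:
        return leading_eight(upper)
    if upper in ("GSCO", "GENEROUS SCORING"):
        if params is None or err is None:
            raise NormError("GSCO requires params (b, c) and err (mu)")
        return generous_scoring(params, err)
    if upper in ("CAUTIOUSSCORING", "CAUTIOUS SCORING", "CSCO"):
        if params is None or err is None:
            raise NormError("CautiousScoring requires params (b, c) and err (mu)")
        return cautious_scoring(params, err)
    if upper in _ACTION_RULES:
        if assessment is None:
            raise NormError(
                f"{upper} is an action rule; supply an assessment rule to pair with"
            )
        return Norm(named_action_rule(upper), assessment, upper)
    raise NormError(f"unknown norm {name!r}; available: {catalog_names()}")


# ---------------------------------------------------------------------------
# Fixture generation and enumeration helpers
# ---------------------------------------------------------------------------


def sample_random_norm(
    seed: int | np.random.Generator,
    deterministic: bool = False,
    actions: tuple = ACTIONS_CD,
) -> Norm:
    """Draw a reproducible random norm.

    Action entries are uniform over ``actions``; assessment entries are
    uniform on [0, 1] (stochastic) or on {0, 1} (``deterministic=True``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    action_table = {ctx: actions[rng.integers(len(actions))] for ctx in CONTEXTS}
    assess_table = {}
    for (x, y) in CONTEXTS:
        for a in actions:
            if deterministic:
                assess_table[(x, y, a)] = float(rng.integers(2))
            else:
                assess_table[(x, y, a)] = float(rng.uniform())
    return Norm(ActionRule(action_table), AssessmentRule(assess_table, actions))


def all_action_rules(actions: tuple = ACTIONS_CD) -> Iterable[ActionRule]:
    """All deterministic action rules over the action set (16 or 81)."""
    n = len(actions)
    for idx in range(n ** 4):
        digits = []
        rem = idx
        for _ in range(4):
            digits.append(actions[rem % n])
            rem //= n
        yield ActionRule(dict(zip(CONTEXTS, digits)))


def extend_with_punishment(norm: Norm, r_p: float = 0.0) -> Norm:
    """Extend a C/D norm to the C/D/P action set.

    The action rule is unchanged; assessments after an observed punishment
    are set to the constant ``r_p`` (default: punishing is always assessed
    as bad).
    """
    if PUNISH in norm.actions:
        return norm
    table = dict(norm.assessment_rule.table)
    for (x, y) in CONTEXTS:
        table[(x, y, PUNISH)] = r_p
    return Norm(
        norm.action_rule,
        AssessmentRule(table, ACTIONS_CDP),
        norm.name,
    )
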