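"""Cooperative-ESS (CESS) characterization in the vanishing-error limit.

A CESS is a norm that is both an ESS and fully self-cooperative as errors
vanish. In that limit the population settles in the all-good state, the
value gap Δv takes a simple closed form, and the ESS inequalities become
explicit algebraic conditions on the intended assessment rule. The
conditions split into two branches by the action of a bad donor toward a
good recipient: a cooperation branch (the leading eight when restricted to
deterministic assessments, stable for b > c) and a defection branch (the
secondary sixteen, stable for b > 2c). With costly punishment the
admissible (S(G,B), S(B,G)) pairs fall into six classes, each with its own
closed form for Δv.

All conditions here are *strict* inequalities evaluated symbolically at
zero error; parameter points where a condition holds with equality are
reported as knife-edge, not classified.
"""

from __future__ import annotations

import dataclasses
import functools
import itertools

from .norms import (
    ACTIONS_CD,
    ACTIONS_CDP,
    BAD,
    CONTEXTS,
    COOPERATE,
    DEFECT,
    GOOD,
    PUNISH,
    ActionRule,
    AssessmentRule,
    GameParams,
    Norm,
    NormError,
)

__all__ = [
    "CESSVerdict",
    "PunishmentClass",
    "EnumerationResult",
    "classify_cess",
    "enumerate_deterministic_cess",
    "secondary_branch_threshold",
    "enumerate_punishment_classes",
    "cess_with_punishment",
    "enumerate_deterministic_cess_punishment",
]

_EQ_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class CESSVerdict:
    """Outcome of a CESS classification.

    ``branch`` is ``"coop"`` (S(B,G)=C), ``"defect"`` (S(B,G)=D), a
    punishment class label like ``"punish(D,P)"``, or ``None``.
    ``relabeled`` marks norms that satisfy the conditions only after the
    G↔B relabeling (the all-bad orientation). ``knife_edge`` marks parameter
    points where some condition holds with equality.
    """

    is_cess: bool
    branch: str | None
    conditions: tuple
    required_sbb: str | None
    relabeled: bool = False
    knife_edge: bool = False


def _strict(lhs: float, rhs: float) -> tuple:
    """(holds, knife_edge) for the strict inequality lhs > rhs."""
    if abs(lhs - rhs) <= _EQ_TOL:
        return False, True
    return lhs > rhs, False


def _classify_two_action(norm: Norm, params: GameParams) -> CESSVerdict:
    s, r = norm.action_rule, norm.assessment_rule
    b, c = params.b, params.c
    conditions = []
    knife = False

    def record(name: str, holds: bool) -> bool:
        conditions.append((name, holds))
        return holds

    ok = record("S(G,G)=C", s[(GOOD, GOOD)] == COOPERATE)
    ok &= record("S(G,B)=D", s[(GOOD, BAD)] == DEFECT)
    ok &= record("R(G,G,C)=1", abs(r[(GOOD, GOOD, COOPERATE)] - 1.0) <= _EQ_TOL)
    if not ok:
        return CESSVerdict(False, None, tuple(conditions), None)

    if s[(BAD, GOOD)] == COOPERATE:
        branch = "coop"
        scale = b
        anchor = r[(BAD, GOOD, COOPERATE)]
        recovery = r[(GOOD, BAD, DEFECT)] + r[(BAD, GOOD, COOPERATE)]
        sign_bg = +1  # cooperation at (B,G) must beat defection
    else:
        branch = "defect"
        scale = b - c
        anchor = r[(BAD, GOOD, DEFECT)]
        recovery = r[(GOOD, BAD, DEFECT)] + r[(BAD, GOOD, DEFECT)]
        sign_bg = -1  # defection at (B,G) must beat cooperation

    k = c * anchor
    holds, ke = _strict(recovery, 1.0)
    knife |= ke
    ok &= record("R(G,B,S)+R(B,G,S)>1", holds)

    holds, ke = _strict((r[(GOOD, GOOD, COOPERATE)] - r[(GOOD, GOOD, DEFECT)]) * scale, k)
    knife |= ke
    ok &= record("(G,G) margin", holds)

    holds, ke = _strict(k, (r[(GOOD, BAD, COOPERATE)] - r[(GOOD, BAD, DEFECT)]) * scale)
    knife |= ke
    ok &= record("(G,B) margin", holds)

    bg_gap = (r[(BAD, GOOD, COOPERATE)] - r[(BAD, GOOD, DEFECT)]) * scale
    if sign_bg > 0:
        holds, ke = _strict(bg_gap, k)
    else:
        holds, ke = _strict(k, bg_gap)
    knife |= ke
    ok &= record("(B,G) margin", holds)

    sbb_gap = (r[(BAD, BAD, COOPERATE)] - r[(BAD, BAD, DEFECT)]) * scale
    if abs(sbb_gap - k) <= _EQ_TOL:
        knife = True
        required = None
        ok = False
        record("(B,B) forced action", False)
    else:
        required = COOPERATE if sbb_gap > k else DEFECT
        ok &= record("(B,B) forced action", s[(BAD, BAD)] == required)

    return CESSVerdict(
        ok and not knife, branch if ok and not knife else None,
        tuple(conditions), required, knife_edge=knife,
    )


def classify_cess(norm: Norm, params: GameParams) -> CESSVerdict:
    """Classify a C/D norm as CESS (vanishing-error limit) or not.

    The conditions are evaluated symbolically at zero error on the intended
    assessment values. Both reputation-label orientations are tested: a norm
    whose mirror image satisfies the conditions is a CESS with
    ``relabeled=True`` (the population settles all-bad instead of all-good).
    """
    if set(norm.actions) != set(ACTIONS_CD):
        raise NormError(
            "classify_cess handles the C/D game; use cess_with_punishment for C/D/P"
        )
    direct = _classify_two_action(norm, params)
    if direct.is_cess or direct.knife_edge:
        return direct
    mirrored = _classify_two_action(norm.relabeled(), params)
    if mirrored.is_cess or mirrored.knife_edge:
        return dataclasses.replace(mirrored, relabeled=True)
    return direct


@dataclasses.dataclass(frozen=True)
class EnumerationResult:
    """Deterministic CESS norms, split by branch (canonical orientation)."""

    coop: tuple
    defect: tuple

    @property
    def norms(self) -> tuple:
        return self.coop + self.defect

    def __len__(self) -> int:
        return len(self.coop) + len(self.defect)


@functools.lru_cache(maxsize=1)
def _deterministic_candidates() -> tuple:
    """All 4096 deterministic third-order C/D norms."""
    norms = []
    action_rules = [
        ActionRule(dict(zip(CONTEXTS, combo)))
        for combo in itertools.product(ACTIONS_CD, repeat=4)
    ]
    keys = [(x, y, a) for (x, y) in CONTEXTS for a in ACTIONS_CD]
    for bits in itertools.product((0.0, 1.0), repeat=8):
        assessment = AssessmentRule(dict(zip(keys, bits)))
        for rule in action_rules:
            norms.append(Norm(rule, assessment))
    return tuple(norms)


def enumerate_deterministic_cess(params: GameParams) -> EnumerationResult:
    """Exhaustively filter the 4096 deterministic norms by the CESS conditions.

    Returned norms are in canonical (all-good) orientation; every one has a
    G↔B mirrored twin among the candidates that is excluded here. For
    b/c in (1, 2) the cooperation branch holds exactly the leading eight;
    for b/c > 2 the defection branch adds the secondary sixteen.
    """
    coop, defect = [], []
    for norm in _deterministic_candidates():
        verdict = _classify_two_action(norm, params)
        if verdict.is_cess:
            (coop if verdict.branch == "coop" else defect).append((norm, verdict))
    return EnumerationResult(tuple(coop), tuple(defect))


def secondary_branch_threshold(
    branch: str = "defect",
    c: float = 1.0,
    lo: float | None = None,
    hi: float = 4.0,
    tol: float = 1e-6,
) -> float:
    """Critical b/c above which a CESS branch becomes non-empty, by bisection.

    The defect branch (secondary sixteen) switches on at b/c = 2, the coop
    branch (leading eight) at b/c = 1; both values are *computed* here by
    bisecting branch non-emptiness of the deterministic enumeration, not
    hard-coded.
    """
    if branch not in ("coop", "defect"):
        raise NormError(f"unknown branch {branch!r}")
    if lo is None:
        lo = 0.5 * c if branch == "coop" else c

    def nonempty(b: float) -> bool:
        result = enumerate_deterministic_cess(GameParams(b, c))
        return len(getattr(result, branch)) > 0

    if nonempty(lo):
        raise NormError(f"lower bracket b={lo} already non-empty")
    if not nonempty(hi):
        raise NormError(f"upper bracket b={hi} still empty")
    while hi - lo > tol * c:
        mid = 0.5 * (lo + hi)
        if nonempty(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi) / c


# ---------------------------------------------------------------------------
# Costly punishment
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PunishmentClass:
    """One of the six admissible (S(G,B), S(B,G)) pairs with its Δv form."""

    a_gb: str
    a_bg: str
    numerator_terms: str

    @property
    def label(self) -> str:
        return f"punish({self.a_gb},{self.a_bg})"

    def delta_v(self, norm: Norm, params: GameParams) -> float:
        """Evaluate the class's closed-form Δv = numerator / R(B,G,A_BG)."""
        numerator = params.b
        if self.a_bg != COOPERATE:
            numerator -= params.c
        if self.a_bg == PUNISH:
            numerator += params.alpha
        if self.a_gb == PUNISH:
            numerator += params.beta
        denominator = norm.assessment_rule[(BAD, GOOD, self.a_bg)]
        if denominator <= 0.0:
            raise NormError(
                f"Δv for class {self.label} undefined: R(B,G,{self.a_bg}) = 0"
            )
        return numerator / denominator


def enumerate_punishment_classes() -> tuple:
    """The six punishment classes: S(G,B) in {D,P} crossed with S(B,G) in {C,D,P}."""
    terms = {
        (DEFECT, COOPERATE): "b",
        (PUNISH, COOPERATE): "b+beta",
        (DEFECT, DEFECT): "b-c",
        (PUNISH, DEFECT): "b-c+beta",
        (DEFECT, PUNISH): "b-c+alpha",
        (PUNISH, PUNISH): "b-c+alpha+beta",
    }
    return tuple(
        PunishmentClass(a_gb, a_bg, terms[(a_gb, a_bg)])
        for a_gb in (DEFECT, PUNISH)
        for a_bg in (COOPERATE, DEFECT, PUNISH)
    )


def _others(action: str) -> tuple:
    return tuple(a for a in ACTIONS_CDP if a != action)


def _classify_punishment(norm: Norm, params: GameParams) -> CESSVerdict:
    s, r = norm.action_rule, norm.assessment_rule
    conditions = []
    knife = False

    def record(name: str, holds: bool) -> bool:
        conditions.append((name, holds))
        return holds

    ok = record("S(G,G)=C", s[(GOOD, GOOD)] == COOPERATE)
    ok &= record("S(G,B)!=C", s[(GOOD, BAD)] != COOPERATE)
    ok &= record("R(G,G,C)=1", abs(r[(GOOD, GOOD, COOPERATE)] - 1.0) <= _EQ_TOL)
    if not ok:
        return CESSVerdict(False, None, tuple(conditions), None)

    a_gb, a_bg = s[(GOOD, BAD)], s[(BAD, GOOD)]
    cls = next(
        pc for pc in enumerate_punishment_classes()
        if pc.a_gb == a_gb and pc.a_bg == a_bg
    )
    holds, ke = _strict(r[(GOOD, BAD, a_gb)] + r[(BAD, GOOD, a_bg)], 1.0)
    knife |= ke
    ok &= record("R(G,B,A_GB)+R(B,G,A_BG)>1", holds)
    if r[(BAD, GOOD, a_bg)] <= 0.0:
        return CESSVerdict(False, None, tuple(conditions), None, knife_edge=knife)
    dv = cls.delta_v(norm, params)

    def margin(ctx, action, alt):
        return (r[(ctx[0], ctx[1], action)] - r[(ctx[0], ctx[1], alt)]) * dv - (
            params.zeta(action) - params.zeta(alt)
        )

    for ctx in ((GOOD, GOOD), (GOOD, BAD), (BAD, GOOD)):
        prescribed = s[ctx]
        for alt in _others(prescribed):
            holds, ke = _strict(margin(ctx, prescribed, alt), 0.0)
            knife |= ke
            ok &= record(f"({ctx[0]},{ctx[1]}) {prescribed} vs {alt}", holds)

    # (B,B): the best response is forced by the assessment entries and Δv.
    payoff = {
        a: r[(BAD, BAD, a)] * dv - params.zeta(a) for a in ACTIONS_CDP
    }
    best = max(payoff, key=payoff.get)
    ties = [a for a in ACTIONS_CDP if a != best and abs(payoff[a] - payoff[best]) <= _EQ_TOL]
    if ties:
        knife = True
        required = None
        ok = False
        record("(B,B) forced action", False)
    else:
        required = best
        ok &= record("(B,B) forced action", s[(BAD, BAD)] == required)

    return CESSVerdict(
        ok and not knife, cls.label if ok and not knife else None,
        tuple(conditions), required, knife_edge=knife,
    )


def cess_with_punishment(norm: Norm, params: GameParams) -> CESSVerdict:
    """CESS classification for the C/D/P game in the vanishing-error limit.

    Selects the punishment class from (S(G,B), S(B,G)), substitutes its
    closed-form Δv and checks every strict best-response inequality,
    including the forced action at (B,B). Both label orientations are tried.
    """
    if set(norm.actions) != set(ACTIONS_CDP):
        raise NormError("cess_with_punishment requires the C/D/P action set")
    if not params.has_punishment:
        raise NormError("punishment parameters alpha, beta are required")
    direct = _classify_punishment(norm, params)
    if direct.is_cess or direct.knife_edge:
        return direct
    mirrored = _classify_punishment(norm.relabeled(), params)
    if mirrored.is_cess or mirrored.knife_edge:
        return dataclasses.replace(mirrored, relabeled=True)
    return direct


def enumerate_deterministic_cess_punishment(params: GameParams) -> dict:
    """All deterministic C/D/P CESS norms, grouped by punishment class.

    Scope: action rules obeying the CESS constraints (S(G,G)=C, S(G,B) in
    {D,P}, S(B,G) and S(B,B) free: 18 rules) crossed with all 4096
    deterministic 12-entry assessment tables. Returns a dict mapping class
    labels to lists of (norm, verdict), canonical orientation only.
    """
    keys = [(x, y, a) for (x, y) in CONTEXTS for a in ACTIONS_CDP]
    action_rules = [
        ActionRule({
            (GOOD, GOOD): COOPERATE,
            (GOOD, BAD): a_gb,
            (BAD, GOOD): a_bg,
            (BAD, BAD): a_bb,
        })
        for a_gb in (DEFECT, PUNISH)
        for a_bg in ACTIONS_CDP
        for a_bb in ACTIONS_CDP
    ]
    grouped: dict = {}
    for bits in itertools.product((0.0, 1.0), repeat=12):
        assessment = AssessmentRule(dict(zip(keys, bits)), ACTIONS_CDP)
        for rule in action_rules:
            norm = Norm(rule, assessment)
            verdict = _classify_punishment(norm, params)
            if verdict.is_cess:
                grouped.setdefault(verdict.branch, []).append((norm, verdict))
    return grouped
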