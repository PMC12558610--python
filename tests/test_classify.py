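"""Vanishing-error CESS classification and deterministic enumeration."""

import numpy as np
import pytest

import normstab as ns
from normstab.norms import CONTEXTS


def _tables(norm):
    return (
        tuple(sorted(norm.action_rule.table.items())),
        tuple(sorted(norm.assessment_rule.table.items())),
    )


class TestClassify:
    def test_l1_coop_branch_forced_c(self):
        verdict = ns.classify_cess(ns.leading_eight("L1"), ns.GameParams(1.5, 1.0))
        assert verdict.is_cess and verdict.branch == "coop"
        assert verdict.required_sbb == "C" and not verdict.relabeled

    def test_l6_coop_branch_forced_d(self):
        verdict = ns.classify_cess(ns.leading_eight("L6"), ns.GameParams(1.5, 1.0))
        assert verdict.is_cess and verdict.branch == "coop"
        assert verdict.required_sbb == "D"

    @pytest.mark.parametrize("name", ns.LEADING_EIGHT_NAMES)
    def test_leading_eight_fail_below_cost(self, name):
        verdict = ns.classify_cess(ns.leading_eight(name), ns.GameParams(0.9, 1.0))
        assert not verdict.is_cess

    def test_boundary_b_equals_c_is_knife_edge(self):
        verdict = ns.classify_cess(ns.leading_eight("L3"), ns.GameParams(1.0, 1.0))
        assert not verdict.is_cess and verdict.knife_edge

    def test_mirrored_norm_detected(self):
        verdict = ns.classify_cess(ns.leading_eight("L6").relabeled(), ns.GameParams(1.5, 1.0))
        assert verdict.is_cess and verdict.relabeled

    def test_stochastic_cess_example(self):
        """A stochastic rule inside the coop-branch inequalities is a CESS."""
        table = dict(ns.leading_eight("L6").assessment_rule.table)
        table[("G", "B", "C")] = 0.37  # (G,B) margin allows any value here
        table[("B", "B", "C")] = 0.2
        norm = ns.Norm(ns.leading_eight("L6").action_rule, ns.AssessmentRule(table))
        verdict = ns.classify_cess(norm, ns.GameParams(1.5, 1.0))
        assert verdict.is_cess and verdict.branch == "coop"


class TestEnumeration:
    def test_leading_eight_cell_for_cell(self, leading_eight_norms):
        result = ns.enumerate_deterministic_cess(ns.GameParams(1.5, 1.0))
        assert len(result.coop) == 8 and len(result.defect) == 0
        found = {_tables(norm) for norm, _ in result.coop}
        expected = {_tables(norm) for norm in leading_eight_norms.values()}
        assert found == expected

    def test_secondary_sixteen(self):
        result = ns.enumerate_deterministic_cess(ns.GameParams(3.0, 1.0))
        assert len(result.coop) == 8
        assert len(result.defect) == 16
        for norm, verdict in result.defect:
            assert norm.action_rule[("B", "G")] == "D"
            assert norm.assessment_rule[("G", "B", "D")] == 1.0
            assert norm.assessment_rule[("B", "G", "D")] == 1.0
            assert verdict.branch == "defect"

    def test_below_cost_empty(self):
        assert len(ns.enumerate_deterministic_cess(ns.GameParams(0.8, 1.0))) == 0

    def test_enumerated_norms_are_ess_at_small_error(self):
        """Every vanishing-error CESS is a strict ESS at small mu, with p_C -> 1."""
        result = ns.enumerate_deterministic_cess(ns.GameParams(1.5, 1.0))
        params = ns.GameParams(1.5, 1.0)
        for norm, _ in result.norms:
            p_c = {}
            for mu in (1e-4, 1e-6):
                err = ns.ErrorModel(mu=mu)
                assert ns.is_ess(norm, params, err).is_strict_ess
                state = ns.stationary_h(norm, err)
                p_c[mu] = ns.action_rates(norm, state)["C"]
            assert 1.0 - p_c[1e-6] < 1.0 - p_c[1e-4] < 1e-3

    def test_rejected_norms_are_not_cooperative_ess(self):
        """Deterministic norms rejected in both orientations are never both
        self-cooperative and strict ESS at mu = 1e-6."""
        params = ns.GameParams(1.5, 1.0)
        rng = np.random.default_rng(1)
        from normstab.classify import _deterministic_candidates

        candidates = list(_deterministic_candidates())
        for idx in rng.choice(len(candidates), size=400, replace=False):
            norm = candidates[idx]
            verdict = ns.classify_cess(norm, params)
            if verdict.is_cess or verdict.knife_edge:
                continue
            if not ns.is_self_cooperative(norm):
                continue
            report = ns.is_ess(norm, params, ns.ErrorModel(mu=1e-6))
            assert not report.is_strict_ess, norm.to_dict()


class TestBranchThreshold:
    # the bisection itself is exercised in the acceptance suite; here only
    # the bracketing diagnostics
    def test_bad_brackets_raise(self):
        with pytest.raises(ns.NormError, match="non-empty"):
            ns.secondary_branch_threshold("defect", lo=2.5)
        with pytest.raises(ns.NormError, match="empty"):
            ns.secondary_branch_threshold("defect", hi=1.5)

    def test_unknown_branch(self):
        with pytest.raises(ns.NormError):
            ns.secondary_branch_threshold("both")


class TestPunishment:
    def test_six_classes(self):
        classes = ns.enumerate_punishment_classes()
        assert len(classes) == 6
        assert all(cls.a_gb in ("D", "P") for cls in classes)
        assert {(cls.a_gb, cls.a_bg) for cls in classes} == {
            ("D", "C"), ("P", "C"), ("D", "D"), ("P", "D"), ("D", "P"), ("P", "P"),
        }

    @pytest.mark.parametrize(
        "a_gb,a_bg,expected",
        [
            ("D", "C", lambda b, c, al, be: b),
            ("P", "C", lambda b, c, al, be: b + be),
            ("D", "D", lambda b, c, al, be: b - c),
            ("P", "D", lambda b, c, al, be: b - c + be),
            ("D", "P", lambda b, c, al, be: b - c + al),
            ("P", "P", lambda b, c, al, be: b - c + al + be),
        ],
    )
    def test_delta_v_forms(self, a_gb, a_bg, expected):
        params = ns.GameParams(3.0, 1.0, alpha=0.5, beta=0.7)
        cls = next(
            c for c in ns.enumerate_punishment_classes()
            if (c.a_gb, c.a_bg) == (a_gb, a_bg)
        )
        r_bg = 0.8
        table = {(x, y, a): 1.0 for (x, y) in CONTEXTS for a in "CDP"}
        table[("B", "G", a_bg)] = r_bg
        norm = ns.Norm(
            ns.ActionRule({
                ("G", "G"): "C", ("G", "B"): a_gb, ("B", "G"): a_bg, ("B", "B"): "D",
            }),
            ns.AssessmentRule(table, ns.ACTIONS_CDP),
        )
        assert cls.delta_v(norm, params) == pytest.approx(
            expected(3.0, 1.0, 0.5, 0.7) / r_bg
        )

    def test_punishing_stern_judging_variant_is_cess(self):
        """Stern-Judging-like norm that punishes bad-with-good defectors."""
        table = {(x, y, a): 0.0 for (x, y) in CONTEXTS for a in "CDP"}
        for ctx, good_action in {
            ("G", "G"): "C", ("G", "B"): "P", ("B", "G"): "C", ("B", "B"): "D",
        }.items():
            table[(*ctx, good_action)] = 1.0
        norm = ns.Norm(
            ns.ActionRule({("G", "G"): "C", ("G", "B"): "P", ("B", "G"): "C", ("B", "B"): "D"}),
            ns.AssessmentRule(table, ns.ACTIONS_CDP),
        )
        params = ns.GameParams(1.5, 1.0, alpha=0.5, beta=0.5)
        verdict = ns.cess_with_punishment(norm, params)
        assert verdict.is_cess and verdict.branch == "punish(P,C)"

    def test_cooperating_at_gb_never_cess(self):
        table = {(x, y, a): 1.0 for (x, y) in CONTEXTS for a in "CDP"}
        norm = ns.Norm(
            ns.ActionRule({("G", "G"): "C", ("G", "B"): "C", ("B", "G"): "C", ("B", "B"): "C"}),
            ns.AssessmentRule(table, ns.ACTIONS_CDP),
        )
        verdict = ns.cess_with_punishment(norm, ns.GameParams(2.0, 1.0, alpha=0.3, beta=0.4))
        assert not verdict.is_cess

    def test_extended_leading_eight_reduces_to_cd_verdict(self):
        """P-margins do not disturb the C/D verdict for P-extended norms."""
        err = ns.ErrorModel(mu=0.05)
        cd_params = ns.GameParams(1.0, 0.5)
        cdp_params = ns.GameParams(1.0, 0.5, alpha=0.4, beta=0.6)
        for name in ns.LEADING_EIGHT_NAMES:
            norm = ns.leading_eight(name)
            cd = ns.is_ess(norm, cd_params, err).verdict
            cdp = ns.is_ess(ns.extend_with_punishment(norm), cdp_params, err).verdict
            assert cd == cdp

    def test_full_punishment_enumeration_grouped(self):
        grouped = ns.enumerate_deterministic_cess_punishment(
            ns.GameParams(3.0, 1.0, alpha=0.5, beta=1.0)
        )
        assert set(grouped) <= {
            c.label for c in ns.enumerate_punishment_classes()
        }
        # every returned norm re-classifies as CESS
        for label, entries in grouped.items():
            for norm, verdict in entries[:5]:
                check = ns.cess_with_punishment(norm, ns.GameParams(3.0, 1.0, alpha=0.5, beta=1.0))
                assert check.is_cess and check.branch == label
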