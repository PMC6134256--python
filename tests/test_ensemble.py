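"""Combination rules, the sequential protocol, and external-tool handling."""

import itertools

import numpy as np
import pytest

from splicedelta.delta import NEGATIVE, NOT_EVALUABLE, POSITIVE, DeltaResult
from splicedelta.ensemble import (
    CombinationRule,
    RuleConfigError,
    applicability_filter,
    combine,
    load_external_scores,
    recommended_rules,
    sequential_mes_ssf,
)
from splicedelta.genome import RegionPosition
from splicedelta.variants import Variant

TOOLS = ["HSF", "SSF_like", "MES", "NNSplice", "dbscSNV", "SPANR"]


def result(tool, call, delta=-10.0):
    if call == NOT_EVALUABLE:
        return DeltaResult(tool, None, NOT_EVALUABLE)
    return DeltaResult(tool, delta if call == POSITIVE else 0.0, call)


def brute_force_call(calls, mode):
    """Independent rule evaluator over explicit positive/negative calls."""
    n_pos = sum(calls)
    k = len(calls)
    if mode == "single":
        return POSITIVE if calls[0] else NEGATIVE
    if mode == "any_of_two":
        return POSITIVE if n_pos >= 1 else NEGATIVE
    if mode == "all_but_one":
        return POSITIVE if n_pos >= k - 1 else NEGATIVE
    raise AssertionError(mode)


class TestCombine:
    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 6])
    def test_truth_table_equivalence(self, k):
        # combine() must match brute-force evaluation for every 2^k assignment
        mode = {1: "single", 2: "any_of_two"}.get(k, "all_but_one")
        tools = TOOLS[:k]
        rule = CombinationRule(f"r{k}", tuple(tools), mode)
        for assignment in itertools.product([True, False], repeat=k):
            results = [result(t, POSITIVE if c else NEGATIVE) for t, c in zip(tools, assignment)]
            assert combine(results, rule).call == brute_force_call(assignment, mode)

    def test_paper_examples(self):
        two = CombinationRule("two", ("HSF", "SSF_like"), "any_of_two")
        # one of two firing is enough
        pred = combine([result("HSF", POSITIVE), result("SSF_like", NEGATIVE)], two)
        assert pred.call == POSITIVE
        three = CombinationRule("three", ("HSF", "SSF_like", "MES"), "all_but_one")
        one_of_three = [result("HSF", POSITIVE), result("SSF_like", NEGATIVE), result("MES", NEGATIVE)]
        assert combine(one_of_three, three).call == NEGATIVE
        two_of_three = [result("HSF", POSITIVE), result("SSF_like", POSITIVE), result("MES", NEGATIVE)]
        assert combine(two_of_three, three).call == POSITIVE
        all_neg = [result(t, NEGATIVE) for t in ("HSF", "SSF_like", "MES")]
        assert combine(all_neg, three).call == NEGATIVE

    def test_not_evaluable_dropped_from_k(self):
        three = CombinationRule("three", ("HSF", "SSF_like", "MES"), "all_but_one")
        # MES unavailable: k becomes 2, one positive of two suffices ("all but one")
        mixed = [result("HSF", POSITIVE), result("SSF_like", NEGATIVE), result("MES", NOT_EVALUABLE)]
        assert combine(mixed, three).call == POSITIVE
        assert combine(mixed, three).n_evaluable == 2
        # below the minimum of 2 evaluable tools the rule abstains
        sparse = [result("HSF", POSITIVE), result("SSF_like", NOT_EVALUABLE), result("MES", NOT_EVALUABLE)]
        assert combine(sparse, three).call == NOT_EVALUABLE

    def test_missing_tool_is_config_error(self):
        rule = CombinationRule("two", ("HSF", "SSF_like"), "any_of_two")
        with pytest.raises(RuleConfigError, match="SSF_like"):
            combine([result("HSF", POSITIVE)], rule)

    def test_rule_arity_validation(self):
        with pytest.raises(RuleConfigError):
            CombinationRule("bad", ("HSF",), "any_of_two")
        with pytest.raises(RuleConfigError):
            CombinationRule("bad", ("HSF", "SSF_like"), "all_but_one")

    def test_recommended_rules_well_formed(self):
        rules = recommended_rules()
        assert rules["donor_recommended"].mode == "any_of_two"
        assert rules["acceptor_recommended"].tools == ("SSF_like",)
        assert rules["acceptor_sequential"].mode == "sequential"


class TestSequential:
    def test_both_fire_confirmatory_positive(self):
        pred = sequential_mes_ssf(result("MES", POSITIVE, -20.0), result("SSF_like", POSITIVE, -6.0))
        assert pred.call == POSITIVE

    def test_policy_truth_table(self):
        mes_pos, ssf_neg = result("MES", POSITIVE, -20.0), result("SSF_like", NEGATIVE, -1.0)
        assert sequential_mes_ssf(mes_pos, ssf_neg, "confirmatory").call == NEGATIVE
        assert sequential_mes_ssf(mes_pos, ssf_neg, "triage").call == POSITIVE
        mes_neg, ssf_pos = result("MES", NEGATIVE, -3.0), result("SSF_like", POSITIVE, -6.0)
        assert sequential_mes_ssf(mes_neg, ssf_pos, "confirmatory").call == NEGATIVE
        assert sequential_mes_ssf(mes_neg, ssf_pos, "triage").call == POSITIVE

    def test_mes_not_evaluable_falls_back_to_ssf(self):
        pred = sequential_mes_ssf(result("MES", NOT_EVALUABLE), result("SSF_like", POSITIVE, -6.0))
        assert pred.call == POSITIVE
        assert "SSF-like alone" in pred.note

    def test_unknown_policy_rejected(self):
        with pytest.raises(RuleConfigError):
            sequential_mes_ssf(result("MES", POSITIVE), result("SSF_like", POSITIVE), "vote")


class TestEnsembleGuarantees:
    """Dominance properties on random labeled benchmarks."""

    def _random_benchmark(self, rng, n=60):
        labels = rng.random(n) < 0.45
        calls = {t: rng.random(n) < (0.8 if t == "a" else 0.6) for t in ("a", "b")}
        # correlate calls with labels so sensitivities are non-trivial
        for t in calls:
            calls[t] = np.where(labels, calls[t] | (rng.random(n) < 0.3), calls[t] & (rng.random(n) < 0.7))
        return labels, calls

    def test_any_of_two_sensitivity_dominates_members(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            labels, calls = self._random_benchmark(rng)
            pos = labels.sum()
            if pos == 0:
                continue
            sens_or = ((calls["a"] | calls["b"]) & labels).sum() / pos
            for t in ("a", "b"):
                assert sens_or >= (calls[t] & labels).sum() / pos

    def test_confirmatory_sequential_specificity_dominates_ssf(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            labels, calls = self._random_benchmark(rng)
            neg = (~labels).sum()
            if neg == 0:
                continue
            spec_and = ((~(calls["a"] & calls["b"])) & ~labels).sum() / neg
            spec_ssf = ((~calls["b"]) & ~labels).sum() / neg
            assert spec_and >= spec_ssf


class TestApplicability:
    V_SNV = Variant("c", 100, "A", "G")
    V_INS = Variant("c", 100, "A", "AGG")

    @pytest.mark.parametrize(
        "kind,offset,side,expected",
        [
            ("donor", 9, "intronic", False),  # dbscSNV donor coverage ends at +8
            ("donor", 8, "intronic", True),
            ("donor", -3, "exonic", True),
            ("acceptor", -12, "intronic", True),
            ("acceptor", -13, "intronic", False),
            ("acceptor", 2, "exonic", True),
            ("acceptor", 3, "exonic", False),
        ],
    )
    def test_dbscsnv_windows(self, kind, offset, side, expected):
        pos = RegionPosition(kind, offset, side)
        assert applicability_filter(self.V_SNV, pos, "dbscSNV") is expected

    def test_indels_excluded_for_spanr_and_dbscsnv(self):
        pos = RegionPosition("donor", 5, "intronic")
        assert not applicability_filter(self.V_INS, pos, "SPANR")
        assert not applicability_filter(self.V_INS, pos, "dbscSNV")
        assert applicability_filter(self.V_INS, pos, "SSF_like")

    def test_pwm_tools_unrestricted(self):
        pos = RegionPosition("donor", 20, "intronic")
        assert applicability_filter(self.V_SNV, pos, "HSF")


class TestExternalScores:
    HEADER = "variant_id\ttranscript_id\tsite_kind\ttool\twt_score\tvar_score\tscore_change\n"

    def test_load_and_lookup(self, tmp_path):
        p = tmp_path / "ext.tsv"
        p.write_text(self.HEADER + "v1\ttx\tacceptor\tdbscSNV\t\t\t0.97\n")
        scores = load_external_scores(p)
        s = scores[("v1", "tx", "acceptor", "dbscSNV")]
        assert s.score_change == pytest.approx(0.97)
        assert s.source == "external"
        assert ("v2", "tx", "acceptor", "dbscSNV") not in scores

    def test_duplicate_keys_rejected(self, tmp_path):
        p = tmp_path / "ext.tsv"
        p.write_text(self.HEADER + "v1\ttx\tdonor\tNNSplice\t90\t50\t\n" * 2)
        with pytest.raises(RuleConfigError, match="duplicate"):
            load_external_scores(p)

    def test_malformed_score_names_line(self, tmp_path):
        p = tmp_path / "ext.tsv"
        p.write_text(self.HEADER + "v1\ttx\tdonor\tNNSplice\tninety\t50\t\n")
        with pytest.raises(RuleConfigError, match=":2"):
            load_external_scores(p)
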