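import math

import pytest
from hypothesis import given, settings, strategies as st

from oracles import ratio_via_lcs
from saedr.faers_outcomes import CaseRecord, outcome_proportions
from saedr.seed_selection import (
    RankedTerms,
    filter_lexically_distinct,
    indel_similarity,
    make_seed_sets,
    rank_from_outcomes,
)

words = st.text(alphabet="abcdefgh ", min_size=0, max_size=12)


class TestIndelSimilarity:
    def test_identity(self):
        assert indel_similarity("death", "death") == 1.0

    def test_fully_distinct_single_chars(self):
        # D("a","b") = 2 (substitution cost 2), lengths sum 2 -> 0.0
        assert indel_similarity("a", "b") == 0.0

    def test_empty_convention(self):
        assert indel_similarity("", "") == 1.0
        assert indel_similarity("", "x") == 0.0

    def test_worked_pair_exceeds_threshold(self):
        value = indel_similarity("cardiac arrest", "cardiac arrest acute")
        assert value == pytest.approx(ratio_via_lcs("cardiac arrest", "cardiac arrest acute"))
        assert value > 0.5

    @given(words, words)
    @settings(max_examples=200)
    def test_matches_lcs_oracle(self, a, b):
        assert indel_similarity(a, b) == pytest.approx(ratio_via_lcs(a, b))

    @given(words, words)
    def test_symmetric_and_bounded(self, a, b):
        assert indel_similarity(a, b) == indel_similarity(b, a)
        assert 0.0 <= indel_similarity(a, b) <= 1.0


class TestFilterLexicallyDistinct:
    def test_published_worked_example(self):
        severe = RankedTerms(["death", "cardiac arrest acute", "cardiac arrest"])
        benign = RankedTerms(["dry skin", "yawning", "cold sweat"])
        assert filter_lexically_distinct(severe).terms == ["death", "cardiac arrest acute"]
        assert filter_lexically_distinct(benign).terms == ["dry skin", "yawning", "cold sweat"]

    def test_exact_duplicate_removed(self):
        # duplicate strings cannot live in one RankedTerms; near-exact does
        ranked = RankedTerms(["fever", "fevers", "cough"])
        assert filter_lexically_distinct(ranked).terms == ["fever", "cough"]

    def test_all_distinct_passes_through(self):
        terms = ["aaaa", "bbbb", "cccc", "dddd"]
        for i, a in enumerate(terms):
            for b in terms[:i]:
                assert ratio_via_lcs(a, b) <= 0.5
        assert filter_lexically_distinct(RankedTerms(terms)).terms == terms

    def test_blocks_chained_near_duplicates(self):
        # c is >0.5-similar to a (kept) though not to b: must still be dropped
        ranked = RankedTerms(["abcdef", "zzzzzz", "abcdefg"])
        assert filter_lexically_distinct(ranked).terms == ["abcdef", "zzzzzz"]

    def test_scores_follow_terms(self):
        ranked = RankedTerms(["fever", "fevers", "cough"], scores=[3.0, 2.0, 1.0])
        out = filter_lexically_distinct(ranked)
        assert out.scores == [3.0, 1.0]

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            filter_lexically_distinct(RankedTerms(["a"]), threshold=1.5)

    @given(st.lists(words.filter(bool), min_size=0, max_size=12, unique=True))
    @settings(max_examples=100)
    def test_subsequence_and_pairwise_distinct(self, terms):
        out = filter_lexically_distinct(RankedTerms(terms)).terms
        it = iter(terms)
        assert all(any(t == u for u in it) for t in out)  # subsequence
        for i, a in enumerate(out):
            for b in out[:i]:
                assert ratio_via_lcs(a, b) <= 0.5


def make_outcome_table(case_specs):
    cases = [
        CaseRecord(case_id=f"C{i}", is_duplicate=False, country="US",
                   reactions=list(reactions), outcomes=list(outcomes))
        for i, (reactions, outcomes) in enumerate(case_specs)
    ]
    return outcome_proportions(cases)


class TestRankFromOutcomes:
    def test_ratio_arithmetic(self):
        # ADR "a": 5 death-or-serious cases with it, 50 without it -> 0.1
        specs = [(["a"], ["Death"])] * 5 + [(["b"], ["Death"])] * 50
        specs += [(["a"], [])] * 3  # non-serious noise
        ranked = rank_from_outcomes(make_outcome_table(specs))
        stats = dict(zip(ranked.terms, ranked.scores))
        assert stats["a"] == pytest.approx(5 / 50)

    def test_never_serious_is_most_benign(self):
        specs = [(["a"], ["Death"]), (["b"], []), (["b"], []), (["c"], ["Hospitalization"])]
        ranked = rank_from_outcomes(make_outcome_table(specs))
        assert ranked.terms[-1] == "b"
        assert dict(zip(ranked.terms, ranked.scores))["b"] == 0.0

    def test_zero_denominator_is_inf_first(self):
        # every death-or-serious case contains "a"
        specs = [(["a"], ["Death"]), (["a", "b"], ["Life-Threatening"]), (["b"], [])]
        ranked = rank_from_outcomes(make_outcome_table(specs))
        assert ranked.terms[0] == "a"
        assert math.isinf(ranked.scores[0])

    def test_three_adr_brute_force(self):
        specs = [
            (["a", "b"], ["Death"]),
            (["b"], ["Hospitalization"]),
            (["c"], []),
            (["a", "c"], []),
            (["b", "c"], ["Other Serious"]),
        ]
        # brute force: death-or-serious cases = #1, #2, #5
        # a: with=1, without=2 -> 0.5 ; b: with=3, without=0 -> inf ; c: with=1, without=2 -> 0.5
        ranked = rank_from_outcomes(make_outcome_table(specs))
        stats = dict(zip(ranked.terms, ranked.scores))
        assert math.isinf(stats["b"])
        assert stats["a"] == pytest.approx(0.5)
        assert stats["c"] == pytest.approx(0.5)
        assert ranked.terms == ["b", "a", "c"]  # ties broken alphabetically

    def test_proportions_variant(self):
        specs = [(["a"], ["Death"])] * 2 + [(["a"], [])] * 2 + [(["b"], ["Death"])] * 1 + [(["b"], [])] * 3
        table = make_outcome_table(specs)
        ranked = rank_from_outcomes(table, use_proportions=True)
        stats = dict(zip(ranked.terms, ranked.scores))
        # a: p_with = 2/4, p_without = 1/4 -> 2.0
        assert stats["a"] == pytest.approx(2.0)


class TestMakeSeedSets:
    severe_fill = ["sepsis", "stroke", "coma", "organ failure", "shock"]
    benign_fill = ["itch", "sneeze", "hiccups", "mild rash", "dandruff"]
    nodes = ["death", "cardiac arrest acute", "cardiac arrest",
             "dry skin", "yawning", "cold sweat"] + severe_fill + benign_fill

    def test_truncation_to_minimum(self):
        # top 37.5% of each 8-term list = the 3 published seed candidates
        severe = RankedTerms(["death", "cardiac arrest acute", "cardiac arrest"] + self.severe_fill)
        benign = RankedTerms(["dry skin", "yawning", "cold sweat"] + self.benign_fill)
        seeds = make_seed_sets(severe, benign, 37.5, self.nodes)
        assert seeds.severe == ["death", "cardiac arrest acute"]
        assert seeds.benign == ["dry skin", "yawning"]

    def test_clean_lists_pass_through(self):
        severe = RankedTerms(["death", "sepsis"] + self.severe_fill[1:])
        benign = RankedTerms(["dry skin", "yawning"] + self.benign_fill)
        n_sev, n_ben = len(severe.terms), len(benign.terms)
        pct = 100 * 2 / min(n_sev, n_ben)
        seeds = make_seed_sets(severe, benign, pct, self.nodes)
        assert seeds.severe == ["death", "sepsis"]
        assert seeds.benign[0] == "dry skin"

    def test_non_node_terms_dropped(self):
        severe = RankedTerms(["notanode", "death", "sepsis"] + self.severe_fill[1:])
        benign = RankedTerms(["dry skin", "yawning"] + self.benign_fill)
        seeds = make_seed_sets(severe, benign, 30, self.nodes)
        assert "notanode" not in seeds.severe
        assert len(seeds.severe) == len(seeds.benign)

    def test_empty_after_filter_is_error(self):
        severe = RankedTerms(["notanode"])
        benign = RankedTerms(["dry skin"])
        with pytest.raises(ValueError):
            make_seed_sets(severe, benign, 10, self.nodes)

    def test_bad_pct(self):
        with pytest.raises(ValueError):
            make_seed_sets(RankedTerms(["death"]), RankedTerms(["itch"]), 50, self.nodes)

    def test_equal_length_and_disjoint(self, planted_small):
        from saedr.synthetic_data import planted_ranking

        ranking = planted_ranking(planted_small)
        nodes = list(planted_small.latent_severity)
        seeds = make_seed_sets(ranking, ranking.reversed(), 15, nodes)
        assert len(seeds.severe) == len(seeds.benign)
        assert not set(seeds.severe) & set(seeds.benign)
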