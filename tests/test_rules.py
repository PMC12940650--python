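import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ssir import count_rules, count_terms, embrace, enumerate_rules, parse_rule
from ssir.rules import RuleParseError, Term
from ssir.scaffold import Scaffold, Site

LETTERS = "ABCDEFGH"


def _scaffold(sizes):
    return Scaffold(tuple(Site(f"R{k+1}", tuple(LETTERS[: m])) for k, m in enumerate(sizes)))


# --------------------------------------------------------------------------
# parsing and notation
# --------------------------------------------------------------------------


def test_parse_basic_forms(toy):
    sc = toy.scaffold
    r = parse_rule("[A]XX", sc)
    assert r.order == 1 and r.terms[0] == Term(1, frozenset({"A"}))
    r = parse_rule("[B,C][C,D]X", sc)
    assert r.order == 2 and r.terms[1].subset == {"C", "D"}
    # compact multi-character bracket form
    assert parse_rule("[BC][CD]X", sc) == parse_rule("[B,C][C,D]X", sc)


def test_parse_negation_normalises_to_complement(toy):
    sc = toy.scaffold
    r = parse_rule("X[|A]X", sc)
    assert r.terms[0] == Term(2, frozenset({"B", "C", "D"}))
    assert r.notation(sc) == "X[B,C,D]X"


def test_parse_degenerate_rules_rejected(toy):
    sc = toy.scaffold
    with pytest.raises(RuleParseError):
        parse_rule("XXX", sc)  # order 0
    with pytest.raises(RuleParseError):
        parse_rule("[A,B,C,D]XX", sc)  # full term collapses to wildcard -> order 0
    with pytest.raises(RuleParseError):
        parse_rule("[E]XX", sc)  # unknown token
    with pytest.raises(RuleParseError):
        parse_rule("[A]X", sc)  # wrong number of sites


def test_notation_roundtrip(toy):
    sc = toy.scaffold
    for text in ["[A]XX", "X[B,C,D]X", "[B,C][C,D]X", "[A][A][A,B]"]:
        assert parse_rule(text, sc).notation(sc) == text


# --------------------------------------------------------------------------
# counting and enumeration
# --------------------------------------------------------------------------


def test_count_terms_examples():
    assert count_terms(4, 3) == 14  # 4 + 6 + 4
    assert count_terms(3, 2) == 6  # 3 + 3
    assert count_terms(4, 1) == 4  # classical
    assert count_terms(5, 10) == 2**5 - 2  # cap beyond m-1 is exhaustive


def test_count_rules_toy(toy):
    sc = toy.scaffold
    assert count_rules(sc, order=1, max_level=1) == 11
    assert count_rules(sc, order=2) == 364
    assert count_rules(sc, order=3) == 1176
    assert count_rules(sc, order="all") == 1574


def test_enumeration_matches_closed_form_toy(toy):
    sc = toy.scaffold
    for order in (1, 2, 3, "all"):
        assert sum(1 for _ in enumerate_rules(sc, order)) == count_rules(sc, order)


def test_enumeration_no_duplicates(toy):
    sc = toy.scaffold
    seen = {r.notation(sc) for r in enumerate_rules(sc, "all")}
    assert len(seen) == 1574


@given(
    sizes=st.lists(st.integers(2, 5), min_size=1, max_size=3),
    max_level=st.one_of(st.none(), st.integers(1, 4)),
)
def test_enumeration_matches_closed_form_random(sizes, max_level):
    sc = _scaffold(sizes)
    n = sum(1 for _ in enumerate_rules(sc, "all", max_level=max_level))
    assert n == count_rules(sc, "all", max_level=max_level)
    if max_level is None:
        assert n == math.prod(2**m - 1 for m in sizes) - 1


# --------------------------------------------------------------------------
# matching
# --------------------------------------------------------------------------


def test_embrace_toy_worked_rules(toy):
    sc = toy.scaffold
    res = embrace(parse_rule("[A]XX", sc), toy)
    assert (res.s, res.i) == (3, 3)
    res = embrace(parse_rule("X[A]X", sc), toy)
    assert (res.s, res.i) == (4, 3)
    res = embrace(parse_rule("XX[A]", sc), toy)
    assert (res.s, res.i) == (3, 1)
    res = embrace(parse_rule("X[|A]X", sc), toy)
    assert (res.s, res.i) == (5, 0)


def test_negation_matching_equivalence(toy):
    # [|A] at a site embraces exactly the complement of [A] at that site
    sc = toy.scaffold
    pos = embrace(parse_rule("X[A]X", sc), toy).member_mask
    neg = embrace(parse_rule("X[|A]X", sc), toy).member_mask
    assert np.array_equal(neg, ~pos)


@given(st.data())
def test_multilevel_term_is_union_of_singletons(toy, data):
    sc = toy.scaffold
    site = data.draw(st.integers(1, 3))
    alphabet = sc.sites[site - 1].alphabet
    subset = data.draw(
        st.sets(st.sampled_from(alphabet), min_size=1, max_size=len(alphabet) - 1)
    )
    from ssir.rules import Rule

    multi = embrace(Rule((Term(site, frozenset(subset)),)), toy).member_mask
    union = np.zeros(toy.L, dtype=bool)
    for tok in subset:
        union |= embrace(Rule((Term(site, frozenset({tok})),)), toy).member_mask
    assert np.array_equal(multi, union)


def test_adding_residue_never_decreases_s(toy):
    # enlarging any term keeps every previously embraced compound
    sc = toy.scaffold
    from ssir.rules import Rule

    for site in (1, 2, 3):
        alphabet = sc.sites[site - 1].alphabet
        for lvl in range(1, len(alphabet) - 1):
            for sub in itertools.combinations(alphabet, lvl):
                base = embrace(Rule((Term(site, frozenset(sub)),)), toy)
                for extra in set(alphabet) - set(sub):
                    grown = embrace(
                        Rule((Term(site, frozenset(sub) | {extra}),)), toy
                    )
                    assert grown.s >= base.s and grown.i >= base.i
                    assert np.all(grown.member_mask >= base.member_mask)


def test_observed_universe_counts(trn):
    from ssir import observed_alphabets

    sc = trn.scaffold
    n_obs = count_rules(sc, order=1, max_level=1, universe="observed", dataset=trn)
    # one level-1 term per observed residue, except at sites whose observed
    # alphabet is a single residue (no proper subset exists there)
    expected = sum(len(a) for a in observed_alphabets(trn) if len(a) > 1)
    assert n_obs == expected == 58


def test_vectorised_scan_agrees_with_naive_embrace(toy):
    # the packed-bitset engine and the pure-python matcher see the same s, i
    import numpy as np

    from ssir._scan import RuleScanner

    scanner = RuleScanner(toy)
    res = scanner.scan(
        np.ones(toy.L, dtype=bool),
        theta=49.0,
        orders=(1, 2),
        max_level=None,
        universe_alphabets=toy.scaffold.alphabets(),
        negatives=True,
        collect_rules=True,
    )
    from ssir.rules import Rule
    from ssir.significance import pvalue_lower, pvalue_upper

    assert res.n_generated == count_rules(toy.scaffold, (1, 2))
    assert len(res.votes) > 0
    for (sites, subsets), s, i, vote in zip(res.rule_ids, res.s, res.i, res.votes):
        rule = Rule(tuple(Term(k, frozenset(sub)) for k, sub in zip(sites, subsets)))
        ref = embrace(rule, toy)
        assert (ref.s, ref.i) == (int(s), int(i))
        if vote > 0:
            assert 100 * pvalue_upper(ref.i, ref.s, toy.I, toy.L) <= 49.0
        else:
            assert 100 * pvalue_lower(ref.i, ref.s, toy.I, toy.L) <= 49.0
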