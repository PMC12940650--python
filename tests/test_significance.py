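import itertools
from fractions import Fraction

import pytest
from hypothesis import given, strategies as st

from ssir import (
    SelectionConfig,
    build_voting_system,
    classify_rule,
    embrace,
    hypergeom_point,
    parse_rule,
    pvalue_lower,
    pvalue_upper,
)
from ssir._scan import pvalue_table
from ssir.metrics import score


# --------------------------------------------------------------------------
# worked examples
# --------------------------------------------------------------------------


def test_worked_pvalues_toy(toy):
    # [A]XX: s=3, i=3 -> 1/84 = 1.19%
    assert pvalue_upper(3, 3, 3, 9, exact=True) == Fraction(1, 84)
    assert round(100 * pvalue_upper(3, 3, 3, 9), 1) == 1.2
    # X[A]X: s=4, i=3 -> 1/21 = 4.76%
    assert pvalue_upper(3, 4, 3, 9, exact=True) == Fraction(1, 21)
    assert round(100 * pvalue_upper(3, 4, 3, 9), 1) == 4.8
    # XX[A]: s=3, i=1 -> 76.19%
    assert pvalue_upper(1, 3, 3, 9, exact=True) == Fraction(16, 21)
    assert round(100 * pvalue_upper(1, 3, 3, 9), 1) == 76.2
    # X[|A]X: s=5, i=0 -> upper tail 100%, lower tail 1/21
    assert pvalue_upper(0, 5, 3, 9, exact=True) == 1
    assert pvalue_lower(0, 5, 3, 9, exact=True) == Fraction(1, 21)


def test_pvalue_argument_validation():
    with pytest.raises(ValueError):
        pvalue_upper(1, 10, 3, 9)  # s > L
    with pytest.raises(ValueError):
        pvalue_upper(-1, 3, 3, 9)


# --------------------------------------------------------------------------
# hypergeometric properties (exact arithmetic)
# --------------------------------------------------------------------------


@given(st.data())
def test_hypergeom_normalisation(data):
    L = data.draw(st.integers(1, 12))
    I = data.draw(st.integers(0, L))
    s = data.draw(st.integers(0, L))
    total = sum(hypergeom_point(i, s, I, L, exact=True) for i in range(0, min(I, s) + 1))
    assert total == 1
    # tails are complementary: P(j >= i) + P(j <= i-1) = 1
    for i in range(0, min(I, s) + 1):
        assert pvalue_upper(i, s, I, L, exact=True) + (
            pvalue_lower(i - 1, s, I, L, exact=True) if i > 0 else 0
        ) == 1


@given(st.data())
def test_hypergeom_brute_force_oracle(data):
    # enumerate every s-subset of a small labelled library and compare the
    # exact tail frequencies with the closed-form p-values
    L = data.draw(st.integers(2, 9))
    I = data.draw(st.integers(1, L - 1))
    s = data.draw(st.integers(1, L))
    labels = [True] * I + [False] * (L - I)
    counts = [0] * (min(I, s) + 1)
    n_draws = 0
    for draw in itertools.combinations(range(L), s):
        counts[sum(labels[j] for j in draw)] += 1
        n_draws += 1
    for i in range(0, min(I, s) + 1):
        upper = Fraction(sum(counts[i:]), n_draws)
        lower = Fraction(sum(counts[: i + 1]), n_draws)
        assert pvalue_upper(i, s, I, L, exact=True) == upper
        assert pvalue_lower(i, s, I, L, exact=True) == lower
        assert hypergeom_point(i, s, I, L, exact=True) == Fraction(counts[i], n_draws)


@given(st.data())
def test_pvalue_table_matches_scalar(data):
    L = data.draw(st.integers(2, 20))
    I = data.draw(st.integers(1, L - 1))
    tab = pvalue_table(I, L)
    s = data.draw(st.integers(1, L))
    i = data.draw(st.integers(max(0, s - (L - I)), min(I, s)))
    assert tab[s, i] == pytest.approx(100 * pvalue_upper(i, s, I, L), abs=1e-12)


# --------------------------------------------------------------------------
# vote classification
# --------------------------------------------------------------------------


def test_classify_rule_signs():
    assert classify_rule(1.19, 100.0, 5.0) == 1
    assert classify_rule(4.76, 100.0, 5.0) == 1
    assert classify_rule(76.19, 100.0, 5.0) == 0
    assert classify_rule(100.0, 4.76, 5.0) == -1  # depletion
    assert classify_rule(15.0, 100.0, 15.0) == 1  # inclusive threshold
    with pytest.raises(ValueError):
        classify_rule(1.0, 100.0, 0.0)
    with pytest.raises(ValueError):
        classify_rule(1.0, 100.0, 50.0)


@given(st.data())
def test_classify_never_both_signs(data):
    L = data.draw(st.integers(2, 12))
    I = data.draw(st.integers(1, L - 1))
    s = data.draw(st.integers(1, L - 1))
    i = data.draw(st.integers(max(0, s - (L - I)), min(I, s)))
    theta = data.draw(st.floats(0.1, 49.9))
    p = 100 * pvalue_upper(i, s, I, L)
    pl = 100 * pvalue_lower(i, s, I, L)
    # the tails overlap at j = i, so they sum to > 100 and at most one is <= theta
    assert p + pl > 100 - 1e-9
    vote = classify_rule(p, pl, theta)
    assert vote in (-1, 0, 1)


# --------------------------------------------------------------------------
# voting-system construction
# --------------------------------------------------------------------------


def test_toy_voting_system_classical(toy):
    cfg = SelectionConfig(theta=5.0, orders=(1,), max_level=1, universe="full",
                          allow_negative_votes=False)
    vs = build_voting_system(toy, cfg)
    assert {v.rule.notation(toy.scaffold) for v in vs.voters} == {"[A]XX", "X[A]X"}
    assert all(v.vote == 1 for v in vs.voters)
    assert vs.n_generated == 11


def test_toy_negation_becomes_negative_voter(toy):
    cfg = SelectionConfig(theta=5.0, orders=(1,), max_level=None, universe="full",
                          allow_negative_votes=True)
    vs = build_voting_system(toy, cfg)
    negation = parse_rule("X[|A]X", toy.scaffold)
    negatives = {v.rule for v in vs.negatives()}
    assert negation in negatives
    stats = next(v for v in vs.voters if v.rule == negation)
    assert (stats.s, stats.i, stats.vote) == (5, 0, -1)


def test_degenerate_training_set_rejected(toy):
    from ssir.scaffold import Compound, Dataset

    all_pos = Dataset(toy.scaffold, [Compound(c.id, c.code, True) for c in toy])
    with pytest.raises(ValueError, match="degenerate"):
        build_voting_system(all_pos, SelectionConfig(theta=5.0, orders=(1,), max_level=1))


def test_selection_config_validation():
    with pytest.raises(ValueError):
        SelectionConfig(theta=0.0)
    with pytest.raises(ValueError):
        SelectionConfig(theta=50.0)
    assert SelectionConfig(orders=2).orders == (2,)


def test_voting_system_save_load_roundtrip(tmp_path, toy):
    cfg = SelectionConfig(theta=10.0, orders=(1, 2), max_level=2, universe="full")
    vs = build_voting_system(toy, cfg)
    path = tmp_path / "vs.json"
    vs.save(path)
    from ssir import VotingSystem

    vs2 = VotingSystem.load(path)
    assert len(vs2) == len(vs)
    assert vs2.config == cfg
    before = score(vs, toy).frame
    after = score(vs2, toy).frame
    assert (before["score"] == after["score"]).all()


def test_voting_system_report_sorted(toy):
    cfg = SelectionConfig(theta=10.0, orders=(1, 2), max_level=2, universe="full")
    vs = build_voting_system(toy, cfg)
    rep = vs.report()
    assert list(rep.columns) == ["notation", "s", "i", "p_percent", "p_lower_percent", "vote"]
    assert (rep["p_percent"].diff().dropna() >= 0).all()


def test_scan_stats_match_embrace_for_all_voters(toy):
    cfg = SelectionConfig(theta=25.0, orders=(1, 2, 3), max_level=None, universe="full")
    vs = build_voting_system(toy, cfg)
    assert len(vs) > 0
    for v in vs.voters:
        ref = embrace(v.rule, toy)
        assert (ref.s, ref.i) == (v.s, v.i)
        assert v.p_percent == pytest.approx(100 * pvalue_upper(v.i, v.s, toy.I, toy.L))
        assert v.p_lower_percent == pytest.approx(100 * pvalue_lower(v.i, v.s, toy.I, toy.L))
        assert v.vote == classify_rule(v.p_percent, v.p_lower_percent, 25.0)
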