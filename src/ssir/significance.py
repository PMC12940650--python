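"""Hypergeometric rule significance and the expert voting system.

A rule that embraces ``s`` of the ``L`` training compounds, ``i`` of them of
interest, is scored by the upper-tail hypergeometric probability

    p(i+, s; I, L) = sum_{j = i..min(I, s)} C(I, j) C(L-I, s-j) / C(L, s)

i.e. the chance that a random draw of ``s`` compounds contains ``i`` or more
of the ``I`` of interest.  Rules with ``p <= theta`` (theta in percent) are
enrichment voters (+1); rules whose *lower* tail ``P(j <= i)`` is at most
theta are depletion voters (-1) — the mirror-image test, significant scarcity
of compounds of interest.  With ``0 < theta < 50`` no rule can be both.  The
selected voters together form the expert voting system.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import _scan
from .rules import Rule, Term, parse_rule, resolve_universe
from .scaffold import Dataset, Scaffold, parse_scaffold

__all__ = [
    "hypergeom_point",
    "pvalue_upper",
    "pvalue_lower",
    "classify_rule",
    "RuleStats",
    "SelectionConfig",
    "VotingSystem",
    "build_voting_system",
]


def _check_args(i: int, s: int, I: int, L: int) -> None:
    if min(i, s, I, L) < 0:
        raise ValueError("hypergeometric arguments must be non-negative")
    if s > L or I > L:
        raise ValueError("need s <= L and I <= L")


def hypergeom_point(i: int, s: int, I: int, L: int, exact: bool = False):
    """P(i, s; I, L) = C(I, i) C(L-I, s-i) / C(L, s); 0 outside the support."""
    _check_args(i, s, I, L)
    if i > min(I, s) or s - i > L - I:
        return Fraction(0) if exact else 0.0
    frac = Fraction(math.comb(I, i) * math.comb(L - I, s - i), math.comb(L, s))
    return frac if exact else float(frac)


def pvalue_upper(i: int, s: int, I: int, L: int, exact: bool = False):
    """Upper-tail p(i+, s; I, L), as a probability in [0, 1].

    Exact integer arithmetic throughout; the float conversion happens once,
    so thresholding is deterministic.
    """
    _check_args(i, s, I, L)
    lo = max(0, s - (L - I))
    hi = min(I, s)
    num = sum(math.comb(I, j) * math.comb(L - I, s - j) for j in range(max(i, lo), hi + 1))
    frac = Fraction(num, math.comb(L, s))
    return frac if exact else float(frac)


def pvalue_lower(i: int, s: int, I: int, L: int, exact: bool = False):
    """Lower-tail P(j <= i; s, I, L): significance of *depletion*.

    Equals ``1 - p((i+1)+, s; I, L)``; it is the mirror image of
    :func:`pvalue_upper` and drives the negative votes.
    """
    _check_args(i, s, I, L)
    hi = min(I, s)
    num = sum(math.comb(I, j) * math.comb(L - I, s - j) for j in range(0, min(i, hi) + 1))
    frac = Fraction(num, math.comb(L, s))
    return frac if exact else float(frac)


def classify_rule(p_percent: float, p_lower_percent: float, theta: float) -> int:
    """Vote of a rule: +1 (enrichment), -1 (depletion) or 0 (no vote).

    Thresholding is inclusive on both sides: +1 iff the upper tail
    ``p <= theta``; -1 iff the lower tail ``P(j <= i) <= theta`` (both in
    percent).  With theta < 50 the two conditions are mutually exclusive,
    since the tails overlap at j = i and sum to more than 100%.
    """
    if not 0 < theta < 50:
        raise ValueError("theta must lie in (0, 50) percent")
    if p_percent <= theta:
        return 1
    if p_lower_percent <= theta:
        return -1
    return 0


@dataclass(frozen=True)
class RuleStats:
    """A rule with its training statistics and (possibly zero) vote."""

    rule: Rule
    s: int
    i: int
    p_percent: float  # upper tail p(i+), percent
    p_lower_percent: float = 100.0  # lower tail P(j <= i), percent
    vote: int = 0


@dataclass(frozen=True)
class SelectionConfig:
    """How the voting system is selected from the rule universe.

    theta
        p-value threshold, in percent, strictly between 0 and 50.
    orders
        rule orders to enumerate (e.g. ``(3,)`` for order-3 rules only).
    max_level
        largest term level (residue-subset size); ``1`` is the classical
        single-residue method, ``None`` means exhaustive (``m - 1`` per site).
    universe
        ``"observed"`` (training residues; default) or ``"full"`` alphabets.
    allow_negative_votes
        include depletion rules as -1 voters (the multilevel runs do; the
        classical runs use enrichment voters only).
    """

    theta: float = 15.0
    orders: tuple[int, ...] = (3,)
    max_level: Optional[int] = 2
    universe: str = "observed"
    allow_negative_votes: bool = True

    def __post_init__(self):
        if not 0 < self.theta < 50:
            raise ValueError("theta must lie in (0, 50) percent")
        object.__setattr__(
            self,
            "orders",
            (self.orders,) if isinstance(self.orders, int) else tuple(self.orders),
        )


@dataclass
class VotingSystem:
    """The expert system: significant rules, each carrying a +1 or -1 vote."""

    scaffold: Scaffold
    voters: list[RuleStats]
    config: Optional[SelectionConfig] = None
    n_generated: int = 0
    n_matchable: int = 0
    train_L: int = 0
    train_I: int = 0

    def __post_init__(self):
        notations = [v.rule.notation(self.scaffold) for v in self.voters]
        if len(set(notations)) != len(notations):
            raise ValueError("duplicate rules in the voting system")

    def __len__(self) -> int:
        return len(self.voters)

    @property
    def n_positive(self) -> int:
        return sum(1 for v in self.voters if v.vote > 0)

    @property
    def n_negative(self) -> int:
        return sum(1 for v in self.voters if v.vote < 0)

    def positives(self) -> list[RuleStats]:
        return [v for v in self.voters if v.vote > 0]

    def negatives(self) -> list[RuleStats]:
        return [v for v in self.voters if v.vote < 0]

    def report(self):
        """Rules report as a DataFrame: notation, s, i, p (%), vote; p ascending."""
        import pandas as pd

        rows = sorted(self.voters, key=lambda v: (v.p_percent, v.rule.notation(self.scaffold)))
        return pd.DataFrame(
            {
                "notation": [v.rule.notation(self.scaffold) for v in rows],
                "s": [v.s for v in rows],
                "i": [v.i for v in rows],
                "p_percent": [v.p_percent for v in rows],
                "p_lower_percent": [v.p_lower_percent for v in rows],
                "vote": [v.vote for v in rows],
            }
        )

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.report().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def save(self, path: Union[str, Path]) -> None:
        """Serialise to JSON (scaffold + canonical rule notations + votes)."""
        obj = {
            "scaffold": {
                "name": self.scaffold.name,
                "sites": [
                    {"name": s.name, "residues": list(s.alphabet)} for s in self.scaffold.sites
                ],
            },
            "train_L": self.train_L,
            "train_I": self.train_I,
            "n_generated": self.n_generated,
            "n_matchable": self.n_matchable,
            "config": (
                {
                    "theta": self.config.theta,
                    "orders": list(self.config.orders),
                    "max_level": self.config.max_level,
                    "universe": self.config.universe,
                    "allow_negative_votes": self.config.allow_negative_votes,
                }
                if self.config
                else None
            ),
            "voters": [
                {
                    "notation": v.rule.notation(self.scaffold),
                    "s": v.s,
                    "i": v.i,
                    "p_percent": v.p_percent,
                    "p_lower_percent": v.p_lower_percent,
                    "vote": v.vote,
                }
                for v in self.voters
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "VotingSystem":
        with open(path) as fh:
            obj = json.load(fh)
        scaffold = parse_scaffold(obj["scaffold"])
        cfg = None
        if obj.get("config"):
            c = obj["config"]
            cfg = SelectionConfig(
                theta=c["theta"],
                orders=tuple(c["orders"]),
                max_level=c["max_level"],
                universe=c["universe"],
                allow_negative_votes=c["allow_negative_votes"],
            )
        voters = [
            RuleStats(
                rule=parse_rule(v["notation"], scaffold),
                s=v["s"],
                i=v["i"],
                p_percent=v["p_percent"],
                p_lower_percent=v.get("p_lower_percent", 100.0),
                vote=v["vote"],
            )
            for v in obj["voters"]
        ]
        return cls(
            scaffold=scaffold,
            voters=voters,
            config=cfg,
            n_generated=obj.get("n_generated", 0),
            n_matchable=obj.get("n_matchable", 0),
            train_L=obj.get("train_L", 0),
            train_I=obj.get("train_I", 0),
        )


def build_voting_system(train: Dataset, cfg: SelectionConfig) -> VotingSystem:
    """Enumerate the rule universe on the training set and select the voters.

    Rules embracing no training compound (trivially p = 100%) or all of them
    (order-0 equivalent) are dropped before significance assessment.
    """
    if train.I == 0 or train.I == train.L:
        raise ValueError(
            f"degenerate training set (I={train.I} of L={train.L}): both classes required"
        )
    scanner = _scan.RuleScanner(train)
    universe = resolve_universe(train.scaffold, cfg.universe, train)
    res = scanner.scan(
        np.ones(train.L, dtype=bool),
        theta=cfg.theta,
        orders=cfg.orders,
        max_level=cfg.max_level,
        universe_alphabets=universe,
        negatives=cfg.allow_negative_votes,
        collect_rules=True,
    )
    voters = []
    for (sites, subsets), s, i, p, pl, vote in zip(
        res.rule_ids, res.s, res.i, res.p_percent, res.p_lower_percent, res.votes
    ):
        rule = Rule(tuple(Term(k, frozenset(sub)) for k, sub in zip(sites, subsets)))
        voters.append(
            RuleStats(
                rule=rule,
                s=int(s),
                i=int(i),
                p_percent=float(p),
                p_lower_percent=float(pl),
                vote=int(vote),
            )
        )
    return VotingSystem(
        scaffold=train.scaffold,
        voters=voters,
        config=cfg,
        n_generated=res.n_generated,
        n_matchable=res.n_matchable,
        train_L=train.L,
        train_I=train.I,
    )
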