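"""Terms and rules over a scaffold: parsing, exhaustive enumeration, counting, matching.

A *term* constrains one substitution site to a non-empty proper subset of its
residue universe (a "multilevel" term when the subset has two or more
residues; the full subset is the wildcard ``X`` and is never part of a term).
A *rule* juxtaposes one term per focused site; its *order* is the number of
focused sites.  Negation notation such as ``[|A]`` is input sugar: it
normalises to the complement subset, so every negation rule has an exact
multilevel equivalent.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np

from .scaffold import Compound, Dataset, Scaffold

__all__ = [
    "Term",
    "Rule",
    "EmbraceResult",
    "RuleParseError",
    "parse_rule",
    "count_terms",
    "count_rules",
    "enumerate_rules",
    "embrace",
    "resolve_universe",
]


class RuleParseError(ValueError):
    """Malformed or degenerate rule notation."""


def resolve_universe(
    scaffold: Scaffold, universe: str = "full", dataset: Optional[Dataset] = None
) -> tuple[tuple[str, ...], ...]:
    """Per-site residue alphabets over which terms are defined.

    ``"full"`` uses the scaffold alphabets; ``"observed"`` restricts each site
    to the residues actually present in ``dataset`` (rules over residues never
    seen in training embrace nothing there and are statistically vacuous).
    """
    from .scaffold import observed_alphabets

    if universe == "full":
        return scaffold.alphabets()
    if universe == "observed":
        if dataset is None:
            raise ValueError("universe='observed' requires a dataset")
        return observed_alphabets(dataset)
    raise ValueError(f"unknown universe {universe!r}")


@dataclass(frozen=True)
class Term:
    """A residue-subset constraint at one (1-based) site."""

    site_index: int
    subset: frozenset[str]

    def __post_init__(self):
        if len(self.subset) == 0:
            raise RuleParseError(f"void term at site {self.site_index}")

    @property
    def level(self) -> int:
        return len(self.subset)


@dataclass(frozen=True)
class Rule:
    """One term per focused site; wildcard everywhere else."""

    terms: tuple[Term, ...]

    def __post_init__(self):
        sites = [t.site_index for t in self.terms]
        if len(self.terms) == 0:
            raise RuleParseError("a rule needs at least one term (order >= 1)")
        if len(set(sites)) != len(sites):
            raise RuleParseError("a site appears in more than one term")
        if sites != sorted(sites):
            object.__setattr__(self, "terms", tuple(sorted(self.terms, key=lambda t: t.site_index)))

    @property
    def order(self) -> int:
        return len(self.terms)

    @property
    def sites(self) -> tuple[int, ...]:
        return tuple(t.site_index for t in self.terms)

    def term_at(self, site_index: int) -> Optional[Term]:
        for t in self.terms:
            if t.site_index == site_index:
                return t
        return None

    def matches(self, compound: Union[Compound, Sequence[str]]) -> bool:
        code = compound.code if isinstance(compound, Compound) else compound
        return all(code[t.site_index - 1] in t.subset for t in self.terms)

    def notation(self, scaffold: Scaffold) -> str:
        """Canonical notation: site-ordered, residues in alphabet order, no negations."""
        parts = []
        for k, site in enumerate(scaffold.sites, start=1):
            term = self.term_at(k)
            if term is None:
                parts.append("X")
            else:
                ordered = [t for t in site.alphabet if t in term.subset]
                missing = term.subset - set(site.alphabet)
                if missing:
                    raise ValueError(f"term tokens {sorted(missing)} not in site {k} alphabet")
                parts.append("[" + ",".join(ordered) + "]")
        return "".join(parts)


@dataclass(frozen=True)
class EmbraceResult:
    """Compounds matched by a rule: membership mask, count s, of-interest count i."""

    member_mask: np.ndarray
    s: int
    i: int

    def members(self, dataset: Dataset) -> list[Compound]:
        return [c for c, flag in zip(dataset.compounds, self.member_mask) if flag]


def _tokenize_bracket(content: str, alphabet: Sequence[str]) -> list[str]:
    """Split bracket content into raw tokens, honouring both the comma form
    ``[A,C,D]`` and the compact single-character form ``[ACD]``."""
    if content == "":
        raise RuleParseError("empty bracket []")
    if "," in content:
        return [p.strip() for p in content.split(",")]
    if content.lstrip("|") in alphabet:
        return [content]
    # compact form: each character is a token, '|' negates the one that follows
    tokens, negate = [], False
    for ch in content:
        if ch == "|":
            negate = True
            continue
        tokens.append(("|" + ch) if negate else ch)
        negate = False
    if negate:
        raise RuleParseError(f"dangling negation in bracket [{content}]")
    return tokens


def parse_rule(
    notation: str,
    scaffold: Scaffold,
    universe: Optional[Sequence[Sequence[str]]] = None,
) -> Rule:
    """Parse rule notation such as ``X[A]X``, ``[B,C][C,D]X`` or ``X[|A]X``.

    Negated tokens are normalised against the per-site ``universe`` (the full
    scaffold alphabets by default): the resulting subset is *(universe minus
    negated tokens) union (positive tokens)*.  A full-universe subset at a
    site collapses to the wildcard; a rule with no remaining term is invalid.
    """
    if universe is None:
        universe = scaffold.alphabets()
    # split the notation into per-site chunks
    chunks: list[str] = []
    pos = 0
    while pos < len(notation):
        ch = notation[pos]
        if ch == "X":
            chunks.append("X")
            pos += 1
        elif ch == "[":
            end = notation.find("]", pos)
            if end < 0:
                raise RuleParseError(f"unbalanced bracket in {notation!r}")
            chunks.append(notation[pos + 1 : end])
            pos = end + 1
        else:
            raise RuleParseError(f"unexpected character {ch!r} in {notation!r}")
    if len(chunks) != scaffold.n_sites:
        raise RuleParseError(
            f"{notation!r} has {len(chunks)} site positions, scaffold has {scaffold.n_sites}"
        )
    terms = []
    for k, (chunk, site_universe, site) in enumerate(
        zip(chunks, universe, scaffold.sites), start=1
    ):
        if chunk == "X":
            continue
        raw = _tokenize_bracket(chunk, site.alphabet)
        positive = {t for t in raw if not t.startswith("|")}
        negated = {t[1:] for t in raw if t.startswith("|")}
        for tok in positive | negated:
            if tok not in site.alphabet:
                raise RuleParseError(f"unknown token {tok!r} at site {k}")
        if negated:
            subset = (set(site_universe) - negated) | positive
        else:
            subset = positive
        if len(subset) == 0:
            raise RuleParseError(f"term at site {k} normalises to the void subset")
        if subset >= set(site_universe):
            continue  # full term == wildcard: drop it (lowers the order)
        terms.append(Term(k, frozenset(subset)))
    if not terms:
        raise RuleParseError(f"{notation!r} normalises to the order-0 all-wildcard rule")
    return Rule(tuple(terms))


def count_terms(m: int, max_level: int) -> int:
    """Number of definable terms at a site with ``m`` residues and level cap.

    Terms are non-empty proper subsets, so levels run from 1 to
    ``min(max_level, m - 1)``; with the exhaustive cap ``m - 1`` the total is
    ``2**m - 2`` (all subsets minus the void and the full/wildcard one).
    """
    if m < 1 or max_level < 1:
        raise ValueError("m and max_level must be >= 1")
    top = min(max_level, m - 1)
    return sum(math.comb(m, r) for r in range(1, top + 1))


def _universe_sizes(
    scaffold: Scaffold, universe, dataset
) -> tuple[tuple[str, ...], ...]:
    if isinstance(universe, str):
        return resolve_universe(scaffold, universe, dataset)
    return tuple(tuple(a) for a in universe)


def _orders_list(order, n_sites: int) -> list[int]:
    if order == "all":
        return list(range(1, n_sites + 1))
    if isinstance(order, int):
        orders = [order]
    else:
        orders = sorted(set(order))
    for r in orders:
        if not 1 <= r <= n_sites:
            raise ValueError(f"rule order {r} outside 1..{n_sites}")
    return orders


def count_rules(
    scaffold: Scaffold,
    order: Union[int, str, Iterable[int]] = "all",
    max_level: Optional[int] = None,
    universe: Union[str, Sequence[Sequence[str]]] = "full",
    dataset: Optional[Dataset] = None,
) -> int:
    """Closed-form count of definable rules for the given orders and level cap.

    For a fixed order ``r`` the count sums, over every r-subset of sites, the
    product of per-site term counts.  With all orders and the exhaustive level
    cap this telescopes to ``prod(2**m_i - 1) - 1``.
    """
    alphabets = _universe_sizes(scaffold, universe, dataset)
    orders = _orders_list(order, scaffold.n_sites)
    tc = [
        count_terms(len(a), (len(a) - 1 if max_level is None else max_level))
        if len(a) > 1
        else 0
        for a in alphabets
    ]
    # sites with a single observed residue admit no proper subset term
    total = 0
    for r in orders:
        for combo in itertools.combinations(range(scaffold.n_sites), r):
            total += math.prod(tc[k] for k in combo)
    return total


def _site_terms(
    alphabet: Sequence[str], max_level: Optional[int]
) -> list[tuple[str, ...]]:
    """All term subsets at a site, ordered by level then alphabet positions."""
    m = len(alphabet)
    top = m - 1 if max_level is None else min(max_level, m - 1)
    out: list[tuple[str, ...]] = []
    for level in range(1, top + 1):
        out.extend(itertools.combinations(alphabet, level))
    return out


def enumerate_rules(
    scaffold: Scaffold,
    order: Union[int, str, Iterable[int]] = "all",
    max_level: Optional[int] = None,
    universe: Union[str, Sequence[Sequence[str]]] = "full",
    dataset: Optional[Dataset] = None,
) -> Iterator[Rule]:
    """Yield every definable rule exactly once, in deterministic order.

    Order of emission: ascending rule order, then site combinations in
    lexicographic order, then per-site subsets by (level, alphabet positions)
    with the last focused site varying fastest.  No term is ever the full
    site universe, so fixing the order excludes hidden wildcards.
    """
    alphabets = _universe_sizes(scaffold, universe, dataset)
    orders = _orders_list(order, scaffold.n_sites)
    site_terms = [_site_terms(a, max_level) for a in alphabets]
    for r in orders:
        for combo in itertools.combinations(range(scaffold.n_sites), r):
            pools = [site_terms[k] for k in combo]
            if any(len(p) == 0 for p in pools):
                continue
            for subsets in itertools.product(*pools):
                yield Rule(
                    tuple(Term(k + 1, frozenset(sub)) for k, sub in zip(combo, subsets))
                )


def embrace(rule: Rule, dataset: Dataset) -> EmbraceResult:
    """Match a rule against a dataset: membership mask, embraced count ``s``
    and embraced-of-interest count ``i``.

    Membership is the intersection of per-(site, residue-subset) membership
    vectors: a compound matches iff, at every focused site, its residue
    belongs to the term subset.
    """
    n = dataset.L
    mask = np.ones(n, dtype=bool)
    codes = dataset.codes()
    for t in rule.terms:
        if t.site_index > dataset.scaffold.n_sites:
            raise ValueError(f"rule focuses site {t.site_index}, scaffold has fewer sites")
        col = np.fromiter(
            (codes[j][t.site_index - 1] in t.subset for j in range(n)), bool, count=n
        )
        mask &= col
    labels = np.fromiter((bool(c.label) for c in dataset.compounds), bool, count=n)
    s = int(mask.sum())
    i = int((mask & labels).sum())
    return EmbraceResult(member_mask=mask, s=s, i=i)
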