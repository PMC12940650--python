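"""In-silico generation of candidate analogues and vote-based screening.

New candidate codes are drawn from the neighbourhood of the training set:
only codes differing in at most ``max_diff`` sites (Hamming distance) from at
least ``min_support`` training compounds are accepted, which keeps proposals
inside the chemical space the voting system actually learned from.  The
similarity index of two codes is the number of shared sites, i.e. number of
sites minus the Hamming distance.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .metrics import score as vote_score
from .rules import resolve_universe
from .scaffold import Compound, Dataset
from .significance import VotingSystem

__all__ = [
    "hamming_similarity",
    "hamming_distance",
    "DifferenceProfile",
    "difference_profile",
    "ScreenConfig",
    "enumerate_candidates",
    "screen",
]


def _code_of(x: Union[Compound, Sequence[str]]) -> tuple[str, ...]:
    return x.code if isinstance(x, Compound) else tuple(x)


def hamming_distance(a, b) -> int:
    """Number of sites at which two codes differ."""
    ca, cb = _code_of(a), _code_of(b)
    if len(ca) != len(cb):
        raise ValueError(f"code lengths differ: {len(ca)} vs {len(cb)}")
    return sum(x != y for x, y in zip(ca, cb))


def hamming_similarity(a, b) -> int:
    """Similarity index: number of sites at which two codes share the residue."""
    ca, cb = _code_of(a), _code_of(b)
    if len(ca) != len(cb):
        raise ValueError(f"code lengths differ: {len(ca)} vs {len(cb)}")
    return sum(x == y for x, y in zip(ca, cb))


@dataclass(frozen=True)
class DifferenceProfile:
    """Distance histogram of one candidate against a training set."""

    candidate: Compound
    histogram: dict[int, int]  # number of differing sites -> count of training compounds

    def support(self, max_diff: int) -> int:
        """Training compounds within Hamming distance ``max_diff``."""
        return sum(c for d, c in self.histogram.items() if d <= max_diff)


def difference_profile(candidate: Union[Compound, Sequence[str]], training: Dataset) -> DifferenceProfile:
    code = _code_of(candidate)
    hist: Counter = Counter(hamming_distance(code, t.code) for t in training.compounds)
    comp = candidate if isinstance(candidate, Compound) else Compound(
        training.scaffold.render_code(code), code
    )
    return DifferenceProfile(candidate=comp, histogram=dict(sorted(hist.items())))


@dataclass(frozen=True)
class ScreenConfig:
    """Similarity-restricted candidate generation.

    max_diff
        largest allowed Hamming distance to a supporting training compound.
    min_support
        minimum number of training compounds within that distance.
    universe
        residue alphabets the new codes may draw from: ``"observed"``
        (default; training residues only, so every candidate is fully
        described by the voting system) or ``"full"`` scaffold alphabets.
    exclude
        ``"train"`` (default): candidates are new relative to the training
        compounds; ``"known"``: also drop every compound of the supplied
        exclusion dataset (e.g. external test sets).
    """

    max_diff: int = 2
    min_support: int = 3
    universe: str = "observed"
    exclude: str = "train"

    def __post_init__(self):
        if self.max_diff < 1 or self.min_support < 1:
            raise ValueError("max_diff and min_support must be >= 1")


def enumerate_candidates(
    training: Dataset,
    cfg: ScreenConfig,
    known: Optional[Dataset] = None,
) -> list[Compound]:
    """All new codes within ``max_diff`` of at least ``min_support`` training compounds.

    The candidate space is built from the <= max_diff Hamming neighbourhoods
    of the training codes over the generation universe (never by scanning the
    full combinatorial product).  A code at distance exactly d from a training
    compound is generated exactly once from it, so the per-code generation
    count equals its support.  Codes listed in the exclusion set are removed;
    the result is sorted lexicographically.
    """
    scaffold = training.scaffold
    alphabets = resolve_universe(scaffold, cfg.universe, training)
    n_sites = scaffold.n_sites
    support: Counter = Counter()
    for t in training.compounds:
        code = t.code
        support[code] += 1  # distance 0
        for d in range(1, cfg.max_diff + 1):
            for sites in itertools.combinations(range(n_sites), d):
                pools = [[tok for tok in alphabets[k] if tok != code[k]] for k in sites]
                for repl in itertools.product(*pools):
                    new = list(code)
                    for k, tok in zip(sites, repl):
                        new[k] = tok
                    support[tuple(new)] += 1
    if cfg.exclude == "train":
        excluded = {c.code for c in training.compounds}
    else:
        source = known if known is not None else training
        excluded = {c.code for c in source.compounds}
    out = sorted(
        code
        for code, cnt in support.items()
        if cnt >= cfg.min_support and code not in excluded
    )
    return [Compound(scaffold.render_code(code), code) for code in out]


def screen(
    candidates: Iterable[Compound],
    vs: VotingSystem,
    training: Optional[Dataset] = None,
    max_diff: Optional[int] = None,
) -> pd.DataFrame:
    """Rank candidate compounds by summed votes (descending; ties by code).

    Returns a DataFrame with columns rank, code, votes and, when a training
    set is supplied, min_diff (closest training distance) and the support at
    ``max_diff``.
    """
    candidates = list(candidates)
    if len(vs) == 0:
        raise ValueError("empty voting system")
    table = vote_score(vs, candidates)
    df = table.frame[["code", "score"]].rename(columns={"score": "votes"})
    if training is not None:
        profiles = [difference_profile(c, training) for c in candidates]
        df["min_diff"] = [min(p.histogram) for p in profiles]
        if max_diff is not None:
            df[f"support_at_{max_diff}"] = [p.support(max_diff) for p in profiles]
    df = df.sort_values(["votes", "code"], ascending=[False, True], kind="stable")
    df.insert(0, "rank", range(1, len(df) + 1))
    return df.reset_index(drop=True)
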