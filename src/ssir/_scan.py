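"""Vectorised exhaustive rule scan.

The hot path of the method is the enumeration of every definable rule against
a training set, each rule needing its embraced count ``s`` and embraced-of-
interest count ``i``.  Compound membership is held as packed bitsets (one bit
per compound of the *evaluation* dataset, little-endian uint8 words); the
membership of a rule is the bitwise AND of its term masks, a term mask being
the OR of per-(site, residue) masks.  Whole blocks of rules (the cartesian
product of term lists over a site combination) are evaluated at once with
``numpy.bitwise_count``, so scans of millions of rules take fractions of a
second and per-fold re-selection inside cross-validation stays cheap.

Statistics (``s``, ``i``, the hypergeometric p-value) are computed against a
*training mask* that may cover only part of the evaluation dataset; the bits
of the remaining compounds ride along for free, which is what makes held-out
and external scoring cheap.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

__all__ = ["RuleScanner", "ScanResult", "pack_rows", "unpack_masks", "pvalue_table"]


def pack_rows(bools: np.ndarray) -> np.ndarray:
    """Pack a boolean membership vector into little-endian uint8 words."""
    return np.packbits(np.asarray(bools, dtype=bool), bitorder="little")


def unpack_masks(masks: np.ndarray, n: int) -> np.ndarray:
    """Unpack (n_rules, n_bytes) masks back to a (n_rules, n) 0/1 matrix."""
    return np.unpackbits(masks, axis=-1, count=n, bitorder="little")


@lru_cache(maxsize=256)
def pvalue_table(I: int, L: int) -> np.ndarray:
    """Upper-tail hypergeometric p-values, in percent, for a library (I, L).

    ``P[s, i]`` is ``100 * p(i+, s; I, L)``.  Computed with exact integer
    arithmetic (Python bignums) and converted once to float, so threshold
    comparisons are deterministic.  Entries with ``i`` above ``min(I, s)``
    are impossible draws and are left at 0.
    """
    P = np.zeros((L + 1, I + 1), dtype=np.float64)
    for s in range(L + 1):
        lo = max(0, s - (L - I))
        hi = min(I, s)
        denom = math.comb(L, s)
        tail = 0
        for i in range(hi, lo - 1, -1):
            tail += math.comb(I, i) * math.comb(L - I, s - i)
            P[s, i] = 100.0 * tail / denom
        P[s, :lo] = 100.0  # below the support the tail holds all the mass
    return P


@dataclass
class ScanResult:
    """Significant rules found by one exhaustive scan."""

    n_generated: int
    n_matchable: int  # rules kept after dropping s == 0 and s == L_train
    masks: np.ndarray  # (n_sig, n_bytes) packed membership over the eval dataset
    votes: np.ndarray  # (n_sig,) int8, +1 or -1
    s: np.ndarray
    i: np.ndarray
    p_percent: np.ndarray  # upper-tail p(i+) in percent
    p_lower_percent: np.ndarray = field(default_factory=lambda: np.zeros(0))
    rule_ids: Optional[list] = None  # [(sites_tuple, subsets_tuple), ...] if collected
    n_bits: int = 0

    @property
    def n_significant(self) -> int:
        return len(self.votes)

    @property
    def n_positive(self) -> int:
        return int((self.votes > 0).sum())

    @property
    def n_negative(self) -> int:
        return int((self.votes < 0).sum())

    def scores(self, rows: Optional[Sequence[int]] = None) -> np.ndarray:
        """Summed votes per evaluation compound (optionally a row subset)."""
        if self.n_significant == 0:
            n = len(rows) if rows is not None else self.n_bits
            return np.zeros(n, dtype=np.int64)
        out = np.zeros(self.n_bits, dtype=np.int64)
        votes = self.votes.astype(np.int64)
        chunk = max(1, (1 << 24) // max(1, self.n_bits))
        for start in range(0, self.n_significant, chunk):
            bits = unpack_masks(self.masks[start : start + chunk], self.n_bits)
            out += votes[start : start + chunk] @ bits
        if rows is not None:
            return out[np.asarray(rows)]
        return out


class RuleScanner:
    """Reusable scan engine over a fixed evaluation dataset.

    The evaluation dataset fixes the bit positions; per-(site, residue)
    membership masks are precomputed once.  Each call to :meth:`scan` may use
    a different training subset, residue universe, order list, level cap and
    threshold — which is exactly what cross-validation needs.
    """

    def __init__(self, dataset):
        self.dataset = dataset
        self.scaffold = dataset.scaffold
        self.n = dataset.L
        codes = dataset.codes()
        self.residue_masks: list[dict[str, np.ndarray]] = []
        for k in range(self.scaffold.n_sites):
            site_masks = {}
            for tok in self.scaffold.sites[k].alphabet:
                col = np.fromiter((c[k] == tok for c in codes), bool, count=self.n)
                if col.any():
                    site_masks[tok] = pack_rows(col)
            self.residue_masks.append(site_masks)
        self.nb = (self.n + 7) // 8
        self._zero = np.zeros(self.nb, dtype=np.uint8)

    def observed_alphabets(self, rows: np.ndarray) -> tuple[tuple[str, ...], ...]:
        """Residues present among the given rows, per site, in alphabet order."""
        rows = np.asarray(rows)
        words = pack_rows(np.isin(np.arange(self.n), rows)) if rows.dtype != bool else pack_rows(rows)
        out = []
        for k in range(self.scaffold.n_sites):
            present = tuple(
                tok
                for tok in self.scaffold.sites[k].alphabet
                if tok in self.residue_masks[k] and (self.residue_masks[k][tok] & words).any()
            )
            out.append(present)
        return tuple(out)

    def _term_masks(self, k: int, alphabet: Sequence[str], max_level: Optional[int]):
        """Term subsets and stacked packed masks for one site."""
        m = len(alphabet)
        top = m - 1 if max_level is None else min(max_level, m - 1)
        subsets, masks = [], []
        for level in range(1, top + 1):
            for sub in itertools.combinations(alphabet, level):
                w = self._zero
                for tok in sub:
                    tok_mask = self.residue_masks[k].get(tok)
                    if tok_mask is not None:
                        w = w | tok_mask
                subsets.append(sub)
                masks.append(w)
        if masks:
            return subsets, np.stack(masks)
        return subsets, np.zeros((0, self.nb), dtype=np.uint8)

    def scan(
        self,
        train_rows: np.ndarray,
        theta: float,
        orders: Sequence[int],
        max_level: Optional[int],
        universe_alphabets: Optional[Sequence[Sequence[str]]] = None,
        negatives: bool = True,
        collect_rules: bool = False,
        max_block: int = 1 << 21,
    ) -> ScanResult:
        """Enumerate every rule, keep the statistically significant voters.

        ``train_rows`` is a boolean vector over the evaluation dataset marking
        the training compounds; ``s``/``i`` and the p-value are computed on
        that subset only, while the returned masks span the whole evaluation
        dataset.  Rules embracing no training compound, or all of them, are
        discarded before significance assessment.

        Vote criteria (both inclusive, theta in percent): +1 when the upper
        tail ``p(i+, s) <= theta`` (enrichment), -1 when the lower tail
        ``P(j <= i) = 100 - p((i+1)+, s) <= theta`` (depletion).  With
        ``theta < 50`` no rule can satisfy both.
        """
        train_rows = np.asarray(train_rows, dtype=bool)
        labels = np.fromiter(
            (bool(c.label) for c in self.dataset.compounds), bool, count=self.n
        )
        train_words = pack_rows(train_rows)
        interest_words = pack_rows(train_rows & labels)
        L = int(train_rows.sum())
        I = int((train_rows & labels).sum())
        if I == 0 or I == L:
            raise ValueError(f"degenerate training set: I={I}, L={L}")
        if not 0 < theta < 50:
            raise ValueError("p-value threshold must lie in (0, 50) percent")
        if universe_alphabets is None:
            universe_alphabets = self.observed_alphabets(train_rows)
        Ptab = pvalue_table(I, L)

        n_sites = self.scaffold.n_sites
        site_terms = [
            self._term_masks(k, universe_alphabets[k], max_level) for k in range(n_sites)
        ]
        n_generated = 0
        n_matchable = 0
        sel_masks, sel_votes, sel_s, sel_i, sel_p, sel_pl = [], [], [], [], [], []
        rule_ids: list = [] if collect_rules else None

        for r in sorted(set(orders)):
            if not 1 <= r <= n_sites:
                raise ValueError(f"rule order {r} outside 1..{n_sites}")
            for combo in itertools.combinations(range(n_sites), r):
                pools = [site_terms[k] for k in combo]
                sizes = [len(p[0]) for p in pools]
                block_total = math.prod(sizes)
                if block_total == 0:
                    continue
                n_generated += block_total
                stride0 = math.prod(sizes[1:])
                chunk0 = max(1, max_block // max(1, stride0))
                for start in range(0, sizes[0], chunk0):
                    cur = pools[0][1][start : start + chunk0]
                    for _, A in pools[1:]:
                        cur = (cur[:, None, :] & A[None, :, :]).reshape(-1, self.nb)
                    s_arr = np.bitwise_count(cur & train_words).sum(axis=1, dtype=np.int64)
                    i_arr = np.bitwise_count(cur & interest_words).sum(axis=1, dtype=np.int64)
                    valid = (s_arr > 0) & (s_arr < L)
                    n_matchable += int(valid.sum())
                    pv = Ptab[s_arr, i_arr]
                    # lower tail P(j <= i) = 100 - p((i+1)+); 100 when i = I
                    pl = np.where(
                        i_arr < I, 100.0 - Ptab[s_arr, np.minimum(i_arr + 1, I)], 100.0
                    )
                    votes = np.where(pv <= theta, 1, 0).astype(np.int8)
                    if negatives:
                        votes = np.where(pl <= theta, -1, votes).astype(np.int8)
                    votes = np.where(valid, votes, 0).astype(np.int8)
                    sel = np.nonzero(votes)[0]
                    if sel.size:
                        sel_masks.append(cur[sel])
                        sel_votes.append(votes[sel])
                        sel_s.append(s_arr[sel])
                        sel_i.append(i_arr[sel])
                        sel_p.append(pv[sel])
                        sel_pl.append(pl[sel])
                        if collect_rules:
                            flat = sel + start * stride0
                            idx = np.unravel_index(flat, sizes)
                            sites = tuple(k + 1 for k in combo)
                            for row in zip(*idx):
                                rule_ids.append(
                                    (sites, tuple(pools[j][0][t] for j, t in enumerate(row)))
                                )
        if sel_masks:
            masks = np.concatenate(sel_masks)
            votes = np.concatenate(sel_votes)
            s_out = np.concatenate(sel_s)
            i_out = np.concatenate(sel_i)
            p_out = np.concatenate(sel_p)
            pl_out = np.concatenate(sel_pl)
        else:
            masks = np.zeros((0, self.nb), dtype=np.uint8)
            votes = np.zeros(0, dtype=np.int8)
            s_out = i_out = np.zeros(0, dtype=np.int64)
            p_out = pl_out = np.zeros(0, dtype=np.float64)
        return ScanResult(
            n_generated=n_generated,
            n_matchable=n_matchable,
            masks=masks,
            votes=votes,
            s=s_out,
            i=i_out,
            p_percent=p_out,
            p_lower_percent=pl_out,
            rule_ids=rule_ids,
            n_bits=self.n,
        )
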