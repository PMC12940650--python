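"""Cross-validation with leakage-free per-fold rule re-selection.

Every fold rebuilds the entire voting system from scratch on its training
split (rule enumeration over the residues observed in that split, fresh
hypergeometric significance against the split's own I and L) and only then
scores its held-out compounds.  Three schemes are provided:

* leave-one-out (L1O): one compound out per fold;
* repeated stratified 10-fold: each class is shuffled and dealt round-robin
  into k folds, so class proportions per fold are as even as arithmetic
  allows; the AUC of a repetition is computed on the pooled held-out scores;
* balanced leave-two-out (BL2O): every (active, inactive) pair is held out
  once; each compound accumulates its held-out votes over all its pairs and
  the accumulated votes are balanced by the compound's own class size before
  ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._scan import RuleScanner
from .metrics import roc_auc
from .scaffold import Dataset
from .significance import SelectionConfig

__all__ = ["CvConfig", "CvResult", "loo_cv", "repeated_stratified_kfold", "bl2o"]


@dataclass(frozen=True)
class CvConfig:
    scheme: str = "kfold"  # "L1O" | "kfold" | "BL2O"
    k: int = 10
    repetitions: int = 1
    seed: int = 0
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    pooled: bool = True  # kfold AUC per repetition from pooled held-out scores

    def __post_init__(self):
        if self.scheme == "kfold" and self.k < 2:
            raise ValueError("k-fold needs k >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class CvResult:
    scheme: str
    scores: pd.DataFrame  # per-compound held-out scores (kfold: one column per repetition)
    aucs: list[float]
    n_runs: int
    seed: Optional[int] = None

    @property
    def auc(self) -> float:
        return self.aucs[0] if len(self.aucs) == 1 else self.mean

    @property
    def mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd(self) -> float:
        """Sample standard deviation of the per-repetition AUCs."""
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "scheme": self.scheme,
            "n_runs": self.n_runs,
            "repetitions": len(self.aucs),
            "seed": self.seed,
            "auc_mean": self.mean,
            "auc_sd": self.sd,
        }


def _fold_scan(scanner: RuleScanner, train_rows: np.ndarray, sel: SelectionConfig):
    """Re-run the full training block on one fold's training rows."""
    universe = (
        scanner.observed_alphabets(train_rows)
        if sel.universe == "observed"
        else scanner.scaffold.alphabets()
    )
    return scanner.scan(
        train_rows,
        theta=sel.theta,
        orders=sel.orders,
        max_level=sel.max_level,
        universe_alphabets=universe,
        negatives=sel.allow_negative_votes,
    )


def _base_frame(dataset: Dataset) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [c.id for c in dataset.compounds],
            "label": [bool(c.label) for c in dataset.compounds],
        }
    )


def loo_cv(dataset: Dataset, selection: SelectionConfig) -> CvResult:
    """Leave-one-out: each compound is scored by a system trained without it."""
    if dataset.L < 3:
        raise ValueError("leave-one-out needs at least 3 compounds")
    if dataset.I == 0 or dataset.I == dataset.L:
        raise ValueError("both classes must be present")
    scanner = RuleScanner(dataset)
    held_scores = np.zeros(dataset.L, dtype=np.int64)
    for j in range(dataset.L):
        train_rows = np.ones(dataset.L, dtype=bool)
        train_rows[j] = False
        res = _fold_scan(scanner, train_rows, selection)
        held_scores[j] = res.scores(rows=[j])[0]
    frame = _base_frame(dataset)
    frame["score"] = held_scores
    auc = roc_auc(held_scores, frame["label"].to_numpy()).auc
    return CvResult(scheme="L1O", scores=frame, aucs=[auc], n_runs=dataset.L)


def stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffle each class and deal round-robin into k folds.

    For 21 actives / 40 inactives and k = 10 this yields nine folds of
    2 active + 4 inactive and one fold of 3 active + 4 inactive.
    """
    labels = np.asarray(labels, dtype=bool)
    fold_of = np.empty(len(labels), dtype=int)
    for cls in (True, False):
        idx = np.nonzero(labels == cls)[0]
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % k
    folds = [np.nonzero(fold_of == f)[0] for f in range(k)]
    if any(len(f) == 0 for f in folds):
        raise ValueError(
            f"infeasible stratification: {len(labels)} compounds into {k} folds "
            f"({int(labels.sum())} of interest)"
        )
    return folds


def repeated_stratified_kfold(dataset: Dataset, cfg: CvConfig) -> CvResult:
    """Repeated randomised stratified k-fold CV; one AUC per repetition."""
    labels = np.fromiter((bool(c.label) for c in dataset.compounds), bool, count=dataset.L)
    rng = np.random.default_rng(cfg.seed)
    scanner = RuleScanner(dataset)
    aucs: list[float] = []
    frame = _base_frame(dataset)
    n_runs = 0
    for rep in range(cfg.repetitions):
        folds = stratified_folds(labels, cfg.k, rng)
        held_scores = np.zeros(dataset.L, dtype=np.int64)
        fold_aucs = []
        for fold in folds:
            train_rows = np.ones(dataset.L, dtype=bool)
            train_rows[fold] = False
            res = _fold_scan(scanner, train_rows, cfg.selection)
            held_scores[fold] = res.scores(rows=fold)
            n_runs += 1
            if not cfg.pooled:
                fl = labels[fold]
                if fl.any() and (~fl).any():
                    fold_aucs.append(roc_auc(held_scores[fold], fl).auc)
        if cfg.pooled:
            aucs.append(roc_auc(held_scores, labels).auc)
        else:
            aucs.append(float(np.mean(fold_aucs)))
        frame[f"score_rep{rep + 1}"] = held_scores
    return CvResult(scheme="kfold", scores=frame, aucs=aucs, n_runs=n_runs, seed=cfg.seed)


def bl2o(dataset: Dataset, selection: SelectionConfig) -> CvResult:
    """Balanced leave-two-out over all I x (L - I) active/inactive pairs.

    Each active compound is scored L - I times and each inactive I times;
    accumulated votes are multiplied by the compound's own class size so both
    classes weigh equally in the final ranking.
    """
    labels = np.fromiter((bool(c.label) for c in dataset.compounds), bool, count=dataset.L)
    actives = np.nonzero(labels)[0]
    inactives = np.nonzero(~labels)[0]
    if len(actives) == 0 or len(inactives) == 0:
        raise ValueError("BL2O needs at least one compound of each class")
    scanner = RuleScanner(dataset)
    accumulated = np.zeros(dataset.L, dtype=np.int64)
    n_runs = 0
    for a in actives:
        for b in inactives:
            train_rows = np.ones(dataset.L, dtype=bool)
            train_rows[[a, b]] = False
            res = _fold_scan(scanner, train_rows, selection)
            pair_scores = res.scores(rows=[a, b])
            accumulated[a] += pair_scores[0]
            accumulated[b] += pair_scores[1]
            n_runs += 1
    balanced = accumulated.copy()
    balanced[actives] *= len(actives)
    balanced[inactives] *= len(inactives)
    frame = _base_frame(dataset)
    frame["accumulated"] = accumulated
    frame["score"] = balanced
    auc = roc_auc(balanced, labels).auc
    return CvResult(scheme="BL2O", scores=frame, aucs=[auc], n_runs=n_runs)
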