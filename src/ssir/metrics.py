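"""Vote scoring of compounds and evaluation of the resulting rankings.

Every compound collects the sum of the votes of the rules that match it; the
scores define a ranking whose quality is measured by the tie-corrected AU-ROC
(Mann-Whitney statistic), and a hard classification is obtained by a *voting
frontier*: a compound is predicted of interest when its score is at or above
the frontier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import _scan
from .scaffold import Compound, Dataset
from .significance import VotingSystem

__all__ = [
    "ScoreTable",
    "RocResult",
    "ConfusionSummary",
    "score",
    "roc_auc",
    "confusion_at",
    "optimal_frontier",
]


@dataclass
class ScoreTable:
    """Per-compound summed votes: the substrate for ROC analysis and screening."""

    frame: pd.DataFrame  # columns: id, code, score, label
    voting_system: Optional[VotingSystem] = None

    @property
    def scores(self) -> np.ndarray:
        return self.frame["score"].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class RocResult:
    """AU-ROC and the (FPR, TPR) curve vertices, from (0,0) to (1,1)."""

    auc: float
    curve: np.ndarray


@dataclass(frozen=True)
class ConfusionSummary:
    frontier: float
    TP: int
    FP: int
    TN: int
    FN: int
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f1: float

    def as_dict(self) -> dict:
        return {
            "frontier": self.frontier,
            "TP": self.TP,
            "FP": self.FP,
            "TN": self.TN,
            "FN": self.FN,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "f1": self.f1,
        }


def _compounds_of(data: Union[Dataset, Sequence[Compound]]):
    return list(data.compounds) if isinstance(data, Dataset) else list(data)


def score(vs: VotingSystem, data: Union[Dataset, Sequence[Compound]]) -> ScoreTable:
    """Sum the votes of the matching rules for every compound.

    A voter whose term mentions a residue absent from the scored compounds
    simply never matches (test compounds with residues unseen in training are
    legal but under-described).  Matching is vectorised through packed
    membership bitsets over the scored set.
    """
    compounds = _compounds_of(data)
    n = len(compounds)
    scaffold = vs.scaffold
    nb = (n + 7) // 8
    residue_masks: list[dict[str, np.ndarray]] = []
    for k in range(scaffold.n_sites):
        site: dict[str, np.ndarray] = {}
        for j, c in enumerate(compounds):
            site.setdefault(c.code[k], np.zeros(n, dtype=bool))[j] = True
        residue_masks.append({tok: _scan.pack_rows(v) for tok, v in site.items()})
    zero = np.zeros(nb, dtype=np.uint8)
    scores = np.zeros(n, dtype=np.int64)
    mask_rows, votes = [], []
    for v in vs.voters:
        w = None
        for t in v.rule.terms:
            tw = zero
            for tok in t.subset:
                tok_mask = residue_masks[t.site_index - 1].get(tok)
                if tok_mask is not None:
                    tw = tw | tok_mask
            w = tw if w is None else (w & tw)
            if not w.any():
                break
        if w is not None and w.any():
            mask_rows.append(w)
            votes.append(v.vote)
    if mask_rows:
        masks = np.stack(mask_rows)
        votes_arr = np.asarray(votes, dtype=np.int64)
        chunk = max(1, (1 << 24) // max(1, n))
        for start in range(0, len(votes_arr), chunk):
            bits = _scan.unpack_masks(masks[start : start + chunk], n)
            scores += votes_arr[start : start + chunk] @ bits
    frame = pd.DataFrame(
        {
            "id": [c.id for c in compounds],
            "code": [scaffold.render_code(c.code) for c in compounds],
            "score": scores,
            "label": [c.label for c in compounds],
        }
    )
    return ScoreTable(frame=frame, voting_system=vs)


def _scores_labels(scores, labels=None):
    if isinstance(scores, ScoreTable):
        labels = scores.labels if labels is None else labels
        scores = scores.scores
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    return scores, labels


def roc_auc(scores, labels=None) -> RocResult:
    """Tie-corrected AU-ROC of the score ranking and the ROC curve vertices.

    The AUC is the Mann-Whitney statistic: over all (positive, negative)
    pairs, credit 1 when the positive outranks the negative and 1/2 on ties —
    identical to the trapezoidal area under the threshold-sweep ROC curve.
    """
    y, lab = _scores_labels(scores, labels)
    n_pos = int(lab.sum())
    n_neg = int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative label")
    from scipy.stats import rankdata

    ranks = rankdata(y)  # average ranks handle ties as half-credit
    auc = (ranks[lab].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # curve: sweep thresholds from above the max score downwards
    order = np.argsort(-y, kind="stable")
    y_sorted, lab_sorted = y[order], lab[order]
    tps = np.cumsum(lab_sorted)
    fps = np.cumsum(~lab_sorted)
    # keep only the last point of each tied-score run
    last = np.r_[np.nonzero(np.diff(y_sorted))[0], len(y_sorted) - 1]
    curve = np.vstack(
        [
            np.r_[0.0, fps[last] / n_neg],
            np.r_[0.0, tps[last] / n_pos],
        ]
    ).T
    return RocResult(auc=float(auc), curve=curve)


def confusion_at(scores, labels=None, frontier: float = 0) -> ConfusionSummary:
    """Confusion matrix at a voting frontier (predicted positive iff score >= frontier)."""
    y, lab = _scores_labels(scores, labels)
    pred = y >= frontier
    TP = int((pred & lab).sum())
    FP = int((pred & ~lab).sum())
    TN = int((~pred & ~lab).sum())
    FN = int((~pred & lab).sum())
    n = len(y)
    sens = 100.0 * TP / (TP + FN) if TP + FN else 0.0
    spec = 100.0 * TN / (TN + FP) if TN + FP else 0.0
    acc = 100.0 * (TP + TN) / n if n else 0.0
    prec = 100.0 * TP / (TP + FP) if TP + FP else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    return ConfusionSummary(
        frontier=frontier,
        TP=TP,
        FP=FP,
        TN=TN,
        FN=FN,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        precision=prec,
        f1=f1,
    )


def optimal_frontier(scores, labels=None, criterion: str = "accuracy"):
    """Frontier maximising accuracy (default) or Youden's J; ties break toward
    the smallest frontier, favouring sensitivity.

    For integer scores, candidate frontiers are the smallest integers that
    realise each distinct classification, so the returned frontier is the
    smallest integer achieving the optimum.
    """
    y, lab = _scores_labels(scores, labels)
    us = np.unique(y)
    integral = np.allclose(us, np.round(us))
    if integral:
        us_int = np.round(us).astype(int)
        candidates = [us_int[0]] + [int(us_int[k - 1]) + 1 for k in range(1, len(us_int))]
        candidates.append(int(us_int[-1]) + 1)
    else:
        candidates = list(us) + [float(us[-1]) + 1.0]

    def crit(cs: ConfusionSummary) -> float:
        if criterion == "accuracy":
            return cs.accuracy
        if criterion == "youden":
            return cs.sensitivity + cs.specificity - 100.0
        raise ValueError(f"unknown criterion {criterion!r}")

    best_f, best_v = None, -np.inf
    for f in candidates:
        v = crit(confusion_at(y, lab, f))
        if v > best_v or (v == best_v and best_f is not None and f < best_f):
            best_f, best_v = f, v
    return best_f
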