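"""Model/results front end for the SSIR method.

``SSIRModel`` holds a labelled training set and the selection configuration;
``fit()`` runs the training block (exhaustive rule enumeration, hypergeometric
significance, voter selection) and returns an ``SSIRResults`` carrying the
voting system, training diagnostics, and methods to score and evaluate new
compounds, cross-validate, and screen virtual candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd

from . import crossval, metrics, screening as screen_mod
from .scaffold import Compound, Dataset, Scaffold, load_dataset
from .significance import SelectionConfig, VotingSystem, build_voting_system

__all__ = ["SSIRModel", "SSIRResults", "EvalReport"]


class SSIRModel:
    """Superposing Significant Interaction Rules model for one training set.

    Parameters
    ----------
    train
        Labelled training dataset (both classes must be present).
    orders
        Rule orders to enumerate; an int or a sequence of ints.
    max_level
        Largest term level. ``1`` is the classical single-residue method;
        ``None`` enumerates every proper subset (level up to ``m - 1``).
    theta
        Significance threshold, percent, in (0, 50).
    universe
        ``"observed"`` (default) restricts terms to training residues.
    negative_votes
        Include depletion rules as -1 voters.

    Examples
    --------
    >>> from ssir import SSIRModel, load_antihiv
    >>> trn = load_antihiv().subset("TRN")
    >>> res = SSIRModel(trn, orders=3, max_level=2, theta=15).fit()
    >>> round(res.train_auc, 3) >= 0.9
    True
    """

    def __init__(
        self,
        train: Dataset,
        orders: Union[int, Sequence[int]] = 3,
        max_level: Optional[int] = 2,
        theta: float = 15.0,
        universe: str = "observed",
        negative_votes: bool = True,
    ):
        self.train = train
        self.config = SelectionConfig(
            theta=theta,
            orders=(orders,) if isinstance(orders, int) else tuple(orders),
            max_level=max_level,
            universe=universe,
            allow_negative_votes=negative_votes,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, scaffold: Scaffold, **kwargs) -> "SSIRModel":
        """Build from a DataFrame with columns id, code, label[, subset]."""
        return cls(load_dataset(df, scaffold), **kwargs)

    def fit(self) -> "SSIRResults":
        vs = build_voting_system(self.train, self.config)
        return SSIRResults(model=self, voting_system=vs)


@dataclass(frozen=True)
class EvalReport:
    """Evaluation of one scored compound set."""

    score_table: metrics.ScoreTable
    roc: metrics.RocResult
    confusion: metrics.ConfusionSummary

    @property
    def auc(self) -> float:
        return self.roc.auc


class SSIRResults:
    """Fitted SSIR voting system with diagnostics and prediction methods."""

    def __init__(self, model: SSIRModel, voting_system: VotingSystem):
        self.model = model
        self.voting_system = voting_system
        self._train_scores: Optional[metrics.ScoreTable] = None

    # -- diagnostics ------------------------------------------------------
    @property
    def n_generated(self) -> int:
        return self.voting_system.n_generated

    @property
    def n_voters(self) -> int:
        return len(self.voting_system)

    @property
    def train_scores(self) -> metrics.ScoreTable:
        if self._train_scores is None:
            self._train_scores = metrics.score(self.voting_system, self.model.train)
        return self._train_scores

    @property
    def train_auc(self) -> float:
        return metrics.roc_auc(self.train_scores).auc

    # -- prediction -------------------------------------------------------
    def score(self, data: Union[Dataset, Sequence[Compound]]) -> metrics.ScoreTable:
        """Summed votes for new compounds."""
        return metrics.score(self.voting_system, data)

    def evaluate(
        self,
        data: Union[Dataset, Sequence[Compound]],
        frontier: Optional[float] = None,
        criterion: str = "accuracy",
    ) -> EvalReport:
        """Score a labelled set; AUC plus the confusion summary at ``frontier``
        (the criterion-optimal frontier when not given)."""
        table = self.score(data)
        roc = metrics.roc_auc(table)
        if frontier is None:
            frontier = metrics.optimal_frontier(table, criterion=criterion)
        return EvalReport(
            score_table=table, roc=roc, confusion=metrics.confusion_at(table, frontier=frontier)
        )

    # -- cross-validation -------------------------------------------------
    def loo(self) -> crossval.CvResult:
        return crossval.loo_cv(self.model.train, self.model.config)

    def kfold(self, k: int = 10, repetitions: int = 1, seed: int = 0, pooled: bool = True):
        cfg = crossval.CvConfig(
            scheme="kfold",
            k=k,
            repetitions=repetitions,
            seed=seed,
            selection=self.model.config,
            pooled=pooled,
        )
        return crossval.repeated_stratified_kfold(self.model.train, cfg)

    def bl2o(self) -> crossval.CvResult:
        return crossval.bl2o(self.model.train, self.model.config)

    # -- virtual screening --------------------------------------------------
    def screen(
        self,
        max_diff: int = 2,
        min_support: int = 3,
        universe: str = "observed",
        exclude: str = "train",
        known: Optional[Dataset] = None,
    ) -> pd.DataFrame:
        """Generate similarity-restricted candidates and rank them by votes."""
        cfg = screen_mod.ScreenConfig(
            max_diff=max_diff, min_support=min_support, universe=universe, exclude=exclude
        )
        candidates = screen_mod.enumerate_candidates(self.model.train, cfg, known=known)
        return screen_mod.screen(
            candidates, self.voting_system, training=self.model.train, max_diff=max_diff
        )

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        vs = self.voting_system
        cfg = self.model.config
        lines = [
            "SSIR voting system",
            "=" * 54,
            f"training compounds      {vs.train_L:>10d}  (of interest: {vs.train_I})",
            f"rule orders             {str(cfg.orders):>10s}",
            f"max term level          {str(cfg.max_level):>10s}",
            f"p-value threshold       {cfg.theta:>9.3g}%",
            f"residue universe        {cfg.universe:>10s}",
            f"rules generated         {vs.n_generated:>10d}",
            f"rules matchable         {vs.n_matchable:>10d}",
            f"voters (+1 / -1)        {vs.n_positive:>10d} / {vs.n_negative}",
            f"training AU-ROC         {self.train_auc:>10.3f}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<SSIRResults: {self.n_voters} voters "
            f"({self.voting_system.n_positive}+/{self.voting_system.n_negative}-) "
            f"from {self.n_generated} rules>"
        )
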