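"""Core-panel identification and repeated-split panel evaluation.

The core panel is the set intersection of the random-forest and t-test
top-k lists; the severity-correlation top-k contributes candidates only.
Every candidate is then added to the core one at a time and scored by
repeated-split logistic regression: each of ``n_splits`` iterations draws
a simple random 80/20 subject split, fits an unpenalized logistic
regression of group on the panel's normalized columns on the training
side, and records the test-side AUC (rank-based Mann-Whitney area) plus
sensitivity and specificity at a 0.5 probability threshold with case as
the positive class.  Candidates whose mean AUC strictly exceeds the core
baseline — compared over an identical split sequence, removing
split-lottery noise — join the final panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .preprocess import NormalizedMatrix

__all__ = [
    "PanelEvaluation",
    "PanelResult",
    "auc_mann_whitney",
    "evaluate_panel",
    "find_core",
    "additive_search",
]

logger = logging.getLogger(__name__)


def auc_mann_whitney(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based ROC area: P(score_case > score_control) + 0.5 P(tie).

    ``y_true`` holds 1 for cases (positive class) and 0 for controls.
    Equivalent to the Mann-Whitney U statistic normalized by the number
    of (case, control) pairs; ties contribute half credit.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


@dataclass
class PanelEvaluation:
    """Distribution of (AUC, sensitivity, specificity) over repeated splits."""

    proteins: list[str]
    n_splits: int
    per_split: np.ndarray  # (n_splits, 3): auc, sensitivity, specificity

    def __post_init__(self) -> None:
        self.per_split = np.asarray(self.per_split, dtype=float)
        if self.per_split.shape != (self.n_splits, 3):
            raise ValueError("per_split shape must be (n_splits, 3)")

    @property
    def auc_mean(self) -> float:
        return float(self.per_split[:, 0].mean())

    @property
    def auc_sd(self) -> float:
        return float(self.per_split[:, 0].std(ddof=1)) if self.n_splits > 1 else 0.0

    @property
    def sensitivity_mean(self) -> float:
        return float(self.per_split[:, 1].mean())

    @property
    def sensitivity_sd(self) -> float:
        return float(self.per_split[:, 1].std(ddof=1)) if self.n_splits > 1 else 0.0

    @property
    def specificity_mean(self) -> float:
        return float(self.per_split[:, 2].mean())

    @property
    def specificity_sd(self) -> float:
        return float(self.per_split[:, 2].std(ddof=1)) if self.n_splits > 1 else 0.0

    def summary(self) -> dict:
        return {
            "proteins": list(self.proteins),
            "n_splits": self.n_splits,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "sensitivity_mean": self.sensitivity_mean,
            "sensitivity_sd": self.sensitivity_sd,
            "specificity_mean": self.specificity_mean,
            "specificity_sd": self.specificity_sd,
        }

    def per_split_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_split, columns=["auc", "sensitivity", "specificity"]
        ).assign(split=np.arange(self.n_splits))


@dataclass
class PanelResult:
    """Outcome of the core + additive panel search."""

    core: list[str]
    candidates: list[str]
    additive: list[str]
    final_panel: list[str]
    core_eval: PanelEvaluation | None
    final_eval: PanelEvaluation
    per_candidate_eval: dict[str, PanelEvaluation] = field(default_factory=dict)

    def validate(self) -> None:
        if set(self.additive) - set(self.candidates):
            raise ValueError("additive proteins must be a subset of the candidates")
        if set(self.final_panel) != set(self.core) | set(self.additive):
            raise ValueError("final panel must equal core union additive")
        if set(self.candidates) & set(self.core):
            raise ValueError("candidates must be disjoint from the core")


def find_core(rf, tt, corr=None) -> tuple[list[str], list[str]]:
    """Core = RF top-k ∩ t-test top-k; candidates = the union of all
    supplied top-k lists minus the core.

    The severity-correlation list (``corr``), when given, contributes
    candidates only — by construction its proteins are selected within
    the case group and never define the core.  Both outputs are ordered
    deterministically by each protein's best rank across the lists, ties
    by analyte id.
    """
    lists = [lst for lst in (rf, tt, corr) if lst is not None]
    if not rf.entries or not tt.entries:
        raise ValueError("both the rf and ttest rankings must be nonempty")
    best_rank: dict[str, int] = {}
    for lst in lists:
        for analyte, _, rank in lst.entries:
            best_rank[analyte] = min(rank, best_rank.get(analyte, np.inf))

    def _ordered(ids):
        return sorted(ids, key=lambda a: (best_rank[a], a))

    core_set = set(rf.analytes) & set(tt.analytes)
    if not core_set:
        warnings.warn(
            "RF and t-test top lists share no proteins; proceeding with an "
            "empty core and candidates-only search",
            stacklevel=2,
        )
    union = set().union(*(lst.analytes for lst in lists))
    return _ordered(core_set), _ordered(union - core_set)


def _fit_logistic(x_train: np.ndarray, y_train: np.ndarray):
    """Unpenalized logistic fit; ridge 1e-6 fallback on separation."""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=500)
        model.fit(x_train, y_train)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            logger.debug("separation in training split; refitting with ridge 1e-6")
            model = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000)
            model.fit(x_train, y_train)
    return model


def evaluate_panel(
    z: NormalizedMatrix,
    group: np.ndarray,
    proteins: list[str],
    n_splits: int = 1000,
    train_frac: float = 0.8,
    seed: int = 0,
    stratified: bool = False,
) -> PanelEvaluation:
    """Repeated-split logistic-regression evaluation of a fixed panel.

    Each split assigns ``train_frac`` of subjects to training uniformly at
    random (redrawn whenever either side lacks both classes; or
    stratified within class when ``stratified=True``).  Identical seeds
    reproduce identical split sequences, so two panels evaluated with the
    same seed see exactly the same splits.
    """
    if not proteins:
        raise ValueError("panel must contain at least one protein")
    x = z.columns(list(proteins))
    group = np.asarray(group, dtype=object)
    y = np.where(group == "case", 1, 0)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    n = len(y)
    n_train = int(round(train_frac * n))
    if not 0 < n_train < n:
        raise ValueError(f"train_frac={train_frac} leaves an empty train or test side")
    rng = np.random.default_rng(seed)
    per_split = np.empty((n_splits, 3))
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    for s in range(n_splits):
        if stratified:
            n_case_train = int(round(train_frac * len(case_idx)))
            train = np.concatenate(
                [
                    rng.permutation(case_idx)[:n_case_train],
                    rng.permutation(ctrl_idx)[: n_train - n_case_train],
                ]
            )
            mask = np.zeros(n, dtype=bool)
            mask[train] = True
        else:
            while True:
                mask = np.zeros(n, dtype=bool)
                mask[rng.permutation(n)[:n_train]] = True
                if 0 < y[mask].sum() < mask.sum() and 0 < y[~mask].sum() < (~mask).sum():
                    break
        model = _fit_logistic(x[mask], y[mask])
        prob = model.predict_proba(x[~mask])[:, 1]
        y_test = y[~mask]
        pred = prob >= 0.5
        pos = y_test == 1
        per_split[s, 0] = auc_mann_whitney(y_test, prob)
        per_split[s, 1] = pred[pos].mean()
        per_split[s, 2] = (~pred[~pos]).mean()
    return PanelEvaluation(proteins=list(proteins), n_splits=n_splits, per_split=per_split)


def additive_search(
    z: NormalizedMatrix,
    group: np.ndarray,
    core: list[str],
    candidates: list[str],
    n_splits: int = 1000,
    seed: int = 0,
    train_frac: float = 0.8,
    margin: float = 0.0,
    stratified: bool = False,
) -> PanelResult:
    """One-at-a-time additive search over candidates against the core.

    Every evaluation reuses the seed, hence the split sequence, of the
    core baseline, so AUC differences reflect the added protein rather
    than split luck.  A candidate is additive when its mean AUC exceeds
    the baseline by more than ``margin`` (default 0: strictly greater).
    With an empty core the baseline is the chance level 0.5.
    """

    def _eval(proteins):
        return evaluate_panel(
            z, group, proteins, n_splits=n_splits, train_frac=train_frac,
            seed=seed, stratified=stratified,
        )

    core = list(core)
    candidates = list(candidates)
    core_eval = _eval(core) if core else None
    baseline = core_eval.auc_mean if core_eval is not None else 0.5
    per_candidate: dict[str, PanelEvaluation] = {}
    additive: list[str] = []
    for c in candidates:
        ev = _eval(core + [c])
        per_candidate[c] = ev
        if ev.auc_mean > baseline + margin:
            additive.append(c)
    final_panel = core + additive
    if final_panel:
        final_eval = _eval(final_panel)
    elif core_eval is not None:
        final_eval = core_eval
    else:
        raise ValueError("no core and no additive candidates: nothing to evaluate")
    result = PanelResult(
        core=core,
        candidates=candidates,
        additive=additive,
        final_panel=final_panel,
        core_eval=core_eval,
        final_eval=final_eval,
        per_candidate_eval=per_candidate,
    )
    result.validate()
    return result
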