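"""The three protein-ranking methods feeding panel discovery.

1. Repeated random-forest Gini importance: fit a random-forest classifier
   of group on all analytes ``n_repeats`` times with different seeds,
   average each analyte's mean decrease in Gini impurity, and keep the
   top *k*.  Importances are reported on the classic ``MeanDecreaseGini``
   scale (total weighted impurity decrease per tree, not normalized to
   sum to one).
2. Two-group differential abundance: per-analyte Welch t-test on the
   normalized values with Benjamini-Hochberg FDR across all analytes;
   log2 fold changes are computed from raw RFU group means.  The top *k*
   by ascending p-value form the t-test ranking.
3. Case-only severity correlation: per-analyte Pearson (or Spearman)
   correlation with the ADOS total score over case samples only; top *k*
   by absolute coefficient.  Controls never enter this computation — ADOS
   is not administered to them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .dataio import ProteomicDataset
from .preprocess import NormalizedMatrix

__all__ = [
    "RankedList",
    "DifferentialResult",
    "rf_importance_ranking",
    "differential_abundance",
    "ttest_ranking",
    "severity_correlation_ranking",
]

logger = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Top-k analytes of one ranking method plus the full score table."""

    method: str  # {"rf", "ttest", "correlation"}
    entries: list[tuple[str, float, int]]  # (analyte_id, score, 1-based rank)
    k: int
    table: pd.DataFrame = field(repr=False, default=None)

    @property
    def analytes(self) -> list[str]:
        return [a for a, _, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["analyte_id", "score", "rank"])


@dataclass
class DifferentialResult:
    """Per-analyte Welch test + BH FDR + raw-scale log2 fold change."""

    table: pd.DataFrame  # analyte_id, log2_fold_change, t_statistic, p_value, fdr_q, direction
    alpha: float = 0.05

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())


def _group_masks(group: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    group = np.asarray(group, dtype=object)
    case = group == "case"
    ctrl = group == "control"
    if case.sum() < 2 or ctrl.sum() < 2:
        raise ValueError("need at least two samples in each group")
    return case, ctrl


def rf_importance_ranking(
    z: NormalizedMatrix,
    group: np.ndarray,
    n_repeats: int = 100,
    k: int = 10,
    seed: int = 0,
    n_trees: int = 500,
) -> RankedList:
    """Average Gini importance over ``n_repeats`` seeded forests.

    Each repeat fits a forest of ``n_trees`` trees (``mtry`` =
    floor(sqrt(#analytes)), unlimited depth, no class weights) with
    random state ``seed + repeat``.  Scores are the mean over repeats of
    the unnormalized mean decrease in Gini impurity, rescaled by the
    sample count to match the conventional MeanDecreaseGini units.  Ties
    in the ranking break lexicographically by analyte id.
    """
    case, ctrl = _group_masks(np.asarray(group, dtype=object))
    y = np.where(case, 1, 0)
    n, m = z.z.shape
    total = np.zeros(m)
    for r in range(n_repeats):
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            criterion="gini",
            max_features="sqrt",
            random_state=seed + r,
            n_jobs=1,
        )
        rf.fit(z.z, y)
        # unnormalized impurity decrease averaged over trees, on the
        # "total samples routed" scale used by MeanDecreaseGini
        imp = np.zeros(m)
        for tree in rf.estimators_:
            imp += tree.tree_.compute_feature_importances(normalize=False)
        total += imp / n_trees * n
    score = total / n_repeats
    order = sorted(range(m), key=lambda j: (-score[j], z.analyte_ids[j]))
    table = pd.DataFrame(
        {
            "analyte_id": [z.analyte_ids[j] for j in order],
            "mean_gini_importance": score[order],
        }
    )
    entries = [
        (z.analyte_ids[j], float(score[j]), rank + 1)
        for rank, j in enumerate(order[: min(k, m)])
    ]
    return RankedList(method="rf", entries=entries, k=k, table=table)


def differential_abundance(
    z: NormalizedMatrix,
    raw: ProteomicDataset,
    group: np.ndarray,
    alpha: float = 0.05,
) -> DifferentialResult:
    """Welch t-test per analyte (case vs control, normalized scale) with
    BH step-up FDR; fold changes from raw RFU group means.

    ``log2_fold_change = log2(mean case RFU) - log2(mean control RFU)``.
    Analytes with zero variance in both groups get p = 1 when the group
    means agree (the comparison is then decided exactly and logged).
    """
    case, ctrl = _group_masks(group)
    zx = z.z
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # degenerate (zero-variance) columns are decided exactly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p_val = stats.ttest_ind(zx[case], zx[ctrl], axis=0, equal_var=False)
    degenerate = ~np.isfinite(t_stat)
    if degenerate.any():
        mean_diff = zx[case].mean(axis=0) - zx[ctrl].mean(axis=0)
        equal = np.abs(mean_diff) < 1e-12
        fallback_t = np.where(equal, 0.0, np.where(mean_diff > 0, np.inf, -np.inf))
        t_stat = np.where(degenerate, fallback_t, t_stat)
        p_val = np.where(degenerate, np.where(equal, 1.0, 0.0), p_val)
        logger.info("%d zero-variance analyte(s) decided by exact mean comparison", degenerate.sum())
    _, fdr_q, _, _ = multipletests(p_val, method="fdr_bh")
    lfc = np.log2(raw.rfu[case].mean(axis=0)) - np.log2(raw.rfu[ctrl].mean(axis=0))
    direction = np.where(
        fdr_q < alpha, np.where(lfc > 0, "up", np.where(lfc < 0, "down", "ns")), "ns"
    )
    table = pd.DataFrame(
        {
            "analyte_id": z.analyte_ids,
            "log2_fold_change": lfc,
            "t_statistic": t_stat,
            "p_value": p_val,
            "fdr_q": fdr_q,
            "direction": direction,
        }
    )
    return DifferentialResult(table=table, alpha=alpha)


def ttest_ranking(diff: DifferentialResult, k: int = 10) -> RankedList:
    """Top-k analytes by ascending p; ties by larger |t|, then id."""
    t = diff.table
    if t.empty:
        raise ValueError("differential result is empty")
    if k > len(t):
        warnings.warn(
            f"k={k} exceeds the {len(t)} available analytes; returning the full ordering",
            stacklevel=2,
        )
    order = t.assign(_abs_t=t["t_statistic"].abs()).sort_values(
        ["p_value", "_abs_t", "analyte_id"], ascending=[True, False, True], kind="mergesort"
    )
    top = order.head(min(k, len(t)))
    entries = [
        (row.analyte_id, float(row.p_value), rank + 1)
        for rank, row in enumerate(top.itertuples(index=False))
    ]
    return RankedList(
        method="ttest", entries=entries, k=k, table=order.drop(columns="_abs_t")
    )


def severity_correlation_ranking(
    z: NormalizedMatrix,
    severity: np.ndarray,
    k: int = 10,
    method: str = "pearson",
) -> RankedList:
    """Per-analyte correlation with the ADOS total over scored cases only.

    Samples without a severity score — all controls, structurally — are
    excluded before anything is computed, encoding the case-only rule.
    Ranking is by absolute coefficient, descending, ties by analyte id;
    signed coefficients and p-values are retained in the score table.
    """
    severity = np.asarray(severity, dtype=float)
    has = ~np.isnan(severity)
    if has.sum() == 0:
        raise ValueError(
            "no samples carry a severity score; the severity ranking uses case "
            "samples only (ADOS is not administered to controls) and cannot run"
        )
    if has.sum() < 3:
        raise ValueError("need at least 3 severity-scored case samples")
    x = z.z[has]
    s = severity[has]
    n = len(s)
    if method == "spearman":
        x = stats.rankdata(x, axis=0)
        s = stats.rankdata(s)
    s_c = s - s.mean()
    x_c = x - x.mean(axis=0)
    denom = np.sqrt((x_c**2).sum(axis=0) * (s_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (x_c * s_c[:, None]).sum(axis=0) / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r * r, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    m = len(z.analyte_ids)
    order = sorted(range(m), key=lambda j: (-abs(r[j]), z.analyte_ids[j]))
    table = pd.DataFrame(
        {
            "analyte_id": [z.analyte_ids[j] for j in order],
            "coefficient": r[order],
            "p_value": p[order],
        }
    )
    entries = [
        (z.analyte_ids[j], float(r[j]), rank + 1)
        for rank, j in enumerate(order[: min(k, m)])
    ]
    return RankedList(method="correlation", entries=entries, k=k, table=table)
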