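"""Confounder battery for a discovered panel, plus duplicate variability.

Four checks mirror the standard post-hoc battery for a serum panel:
binary strata comparisons (ethnicity as white vs non-white, allergy as
yes/no) by Welch t-test per panel protein; Spearman rank correlation of
each panel protein with age; a medication sensitivity analysis that
re-evaluates the fixed panel after removing subjects reporting
psychiatric medication; and per-protein percent coefficient of variation
between blinded technical duplicate assay pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ProteomicDataset
from .preprocess import NormalizedMatrix
from .panel import PanelEvaluation, evaluate_panel

__all__ = [
    "CovariateReport",
    "binary_covariate_test",
    "age_correlation",
    "medication_sensitivity",
    "duplicate_variability",
]


@dataclass
class CovariateReport:
    """Per-protein covariate statistics (one row per protein)."""

    covariate: str
    table: pd.DataFrame  # analyte_id, statistic, p_value, note


def _coerce_binary(split: np.ndarray) -> np.ndarray:
    """Object array of {True, False, None} -> float {1, 0, nan}."""
    out = np.full(len(split), np.nan)
    for i, v in enumerate(split):
        if v is None:
            continue
        if isinstance(v, float) and np.isnan(v):
            continue
        out[i] = 1.0 if bool(v) else 0.0
    return out


def binary_covariate_test(
    z: NormalizedMatrix,
    split: np.ndarray,
    proteins: list[str],
    covariate: str = "binary",
) -> CovariateReport:
    """Welch t-test of each panel protein between two covariate strata.

    ``split`` is a per-sample boolean with None/NaN for unreported values;
    those samples are dropped before testing.  A stratum smaller than two
    samples marks every protein row untestable rather than erroring the
    whole battery — unless a stratum is entirely empty, which is a usage
    error.
    """
    flags = _coerce_binary(np.asarray(split, dtype=object))
    known = ~np.isnan(flags)
    a_mask = known & (flags == 1.0)
    b_mask = known & (flags == 0.0)
    if a_mask.sum() == 0 or b_mask.sum() == 0:
        raise ValueError(f"covariate {covariate!r}: one stratum is empty")
    x = z.columns(list(proteins))
    rows = []
    testable = a_mask.sum() >= 2 and b_mask.sum() >= 2
    for j, prot in enumerate(proteins):
        if not testable:
            rows.append((prot, np.nan, np.nan, "untestable: stratum of size < 2"))
            continue
        t, p = stats.ttest_ind(x[a_mask, j], x[b_mask, j], equal_var=False)
        diff = x[a_mask, j].mean() - x[b_mask, j].mean()
        note = f"{'higher' if diff > 0 else 'lower'} with {covariate}"
        rows.append((prot, float(t), float(p), note))
    return CovariateReport(
        covariate=covariate,
        table=pd.DataFrame(rows, columns=["analyte_id", "statistic", "p_value", "note"]),
    )


def age_correlation(
    z: NormalizedMatrix, age: np.ndarray, proteins: list[str]
) -> CovariateReport:
    """Spearman rank correlation of each panel protein with age.

    Uses every sample with a reported age; requires at least three.
    Constant age yields untestable rows.
    """
    age = np.asarray(age, dtype=float)
    known = ~np.isnan(age)
    if known.sum() < 3:
        raise ValueError("age correlation requires at least 3 samples with age")
    x = z.columns(list(proteins))[known]
    a = age[known]
    rows = []
    constant = np.ptp(a) == 0
    for j, prot in enumerate(proteins):
        if constant or np.ptp(x[:, j]) == 0:
            rows.append((prot, np.nan, np.nan, "untestable: constant values"))
            continue
        rho, p = stats.spearmanr(x[:, j], a)
        rows.append((prot, float(rho), float(p), ""))
    return CovariateReport(
        covariate="age",
        table=pd.DataFrame(rows, columns=["analyte_id", "statistic", "p_value", "note"]),
    )


def medication_sensitivity(
    z: NormalizedMatrix,
    group: np.ndarray,
    proteins: list[str],
    medication: np.ndarray,
    n_splits: int = 1000,
    train_frac: float = 0.8,
    seed: int = 0,
    stratified: bool = False,
) -> tuple[PanelEvaluation, PanelEvaluation]:
    """Re-evaluate a fixed panel with medicated subjects removed.

    Returns ``(full_eval, reduced_eval)``.  The panel is *not*
    re-selected: only the evaluation cohort changes.  Subjects with
    unreported medication status are retained in both evaluations.
    """
    full = evaluate_panel(
        z, group, proteins, n_splits=n_splits, train_frac=train_frac,
        seed=seed, stratified=stratified,
    )
    flags = _coerce_binary(np.asarray(medication, dtype=object))
    keep = ~(flags == 1.0)
    if keep.all():
        return full, full
    sub = NormalizedMatrix(
        sample_ids=[s for s, k in zip(z.sample_ids, keep) if k],
        analyte_ids=list(z.analyte_ids),
        z=z.z[keep],
    )
    reduced = evaluate_panel(
        sub, np.asarray(group, dtype=object)[keep], proteins,
        n_splits=n_splits, train_frac=train_frac, seed=seed, stratified=stratified,
    )
    return full, reduced


def duplicate_variability(ds: ProteomicDataset, proteins: list[str] | None = None) -> pd.DataFrame:
    """Percent CV between blinded duplicate pairs, per protein.

    For each (original, duplicate) raw-RFU pair the two-point CV is
    ``sd / mean * 100`` with the sample-SD convention (``sd =
    |a - b| / sqrt(2)``); the reported value per protein is the mean over
    pairs.  Scale-invariant: rescaling a protein's RFU leaves it
    unchanged.
    """
    if ds.duplicate_of is None or all(d is None for d in ds.duplicate_of):
        raise ValueError("dataset contains no duplicate pairs")
    index = {s: i for i, s in enumerate(ds.sample_ids)}
    pairs = [
        (index[ref], i)
        for i, ref in enumerate(ds.duplicate_of)
        if ref is not None
    ]
    cols = list(proteins) if proteins is not None else list(ds.analyte_ids)
    aindex = {a: j for j, a in enumerate(ds.analyte_ids)}
    missing = [c for c in cols if c not in aindex]
    if missing:
        raise KeyError(f"proteins not in dataset: {missing}")
    jidx = [aindex[c] for c in cols]
    orig = ds.rfu[np.array([i for i, _ in pairs])][:, jidx]
    dup = ds.rfu[np.array([j for _, j in pairs])][:, jidx]
    sd = np.abs(orig - dup) / np.sqrt(2.0)
    mean = (orig + dup) / 2.0
    cv = sd / mean * 100.0
    return pd.DataFrame(
        {"analyte_id": cols, "mean_pct_cv": cv.mean(axis=0), "n_pairs": len(pairs)}
    )
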