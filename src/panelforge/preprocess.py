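"""QC filtering and normalization of the RFU matrix.

Normalization follows the discovery pipeline convention for aptamer
panels: log10-transform the strictly positive RFU values, z-transform
each analyte across all retained samples (both groups pooled), and clip
the result to [-3, 3] to bound outlier influence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dataio import ProteomicDataset

__all__ = ["NormalizedMatrix", "qc_filter", "normalize"]

logger = logging.getLogger(__name__)

CLIP = 3.0


@dataclass
class NormalizedMatrix:
    """log10 + per-analyte z-scored matrix, clipped to [-3, 3]."""

    sample_ids: list[str]
    analyte_ids: list[str]
    z: np.ndarray  # (n_samples, n_analytes)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (len(self.sample_ids), len(self.analyte_ids)):
            raise ValueError("z shape does not match sample/analyte ids")

    def columns(self, analyte_ids: list[str]) -> np.ndarray:
        """Sub-matrix of the named analytes, raising on unknown names."""
        index = {a: j for j, a in enumerate(self.analyte_ids)}
        missing = [a for a in analyte_ids if a not in index]
        if missing:
            raise KeyError(f"analytes not in matrix: {missing}")
        return self.z[:, [index[a] for a in analyte_ids]]


def qc_filter(ds: ProteomicDataset) -> ProteomicDataset:
    """Restrict to QC-passing analytes and unique subjects.

    Blinded duplicate re-measurements (samples with ``duplicate_of`` set)
    are removed here as well, so discovery statistics are computed on
    unique subjects only; duplicates remain available on the unfiltered
    dataset for variability assessment.
    """
    keep_analytes = ds.qc_pass
    if not keep_analytes.any():
        raise ValueError("no analytes survive QC filtering")
    out = ds.select_analytes(keep_analytes)
    if ds.duplicate_of is not None:
        primary = np.array([d is None for d in ds.duplicate_of], dtype=bool)
        if not primary.all():
            out = out.select_samples(primary)
    return out


def normalize(ds: ProteomicDataset, ddof: int = 0) -> NormalizedMatrix:
    """log10 -> per-analyte z-score (pooled over all samples) -> clip ±3.

    ``ddof=0`` (population SD) is the default; pass ``ddof=1`` for the
    sample-SD convention.  Zero-variance analytes produce an all-zero
    column and a logged warning rather than being dropped, keeping column
    indices stable; they are inert in every downstream ranker.
    """
    if np.any(ds.rfu <= 0):
        raise ValueError("RFU values must be strictly positive for log10 transform")
    logx = np.log10(ds.rfu)
    mean = logx.mean(axis=0)
    sd = logx.std(axis=0, ddof=ddof)
    degenerate = sd == 0
    if degenerate.any():
        names = [a for a, d in zip(ds.analyte_ids, degenerate) if d]
        logger.warning(
            "%d zero-variance analyte(s) set to all-zero z-scores: %s",
            len(names),
            ", ".join(names[:5]) + ("..." if len(names) > 5 else ""),
        )
    safe_sd = np.where(degenerate, 1.0, sd)
    z = (logx - mean) / safe_sd
    z[:, degenerate] = 0.0
    np.clip(z, -CLIP, CLIP, out=z)
    return NormalizedMatrix(
        sample_ids=list(ds.sample_ids), analyte_ids=list(ds.analyte_ids), z=z
    )
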