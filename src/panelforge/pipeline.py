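"""End-to-end discovery orchestration: ingest -> QC -> normalize ->
rank -> panel -> covariate battery, with a run manifest for provenance.

A single master seed fans out to stage-specific seeds by fixed offsets,
so the random-forest ranking and the repeated-split evaluations are
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .covariates import (
    age_correlation,
    binary_covariate_test,
    duplicate_variability,
    medication_sensitivity,
)
from .dataio import LayoutConfig, ProteomicDataset, read_dataset, write_table
from .panel import PanelResult, additive_search, find_core
from .preprocess import normalize, qc_filter
from .rankers import (
    differential_abundance,
    rf_importance_ranking,
    severity_correlation_ranking,
    ttest_ranking,
)

__all__ = ["PipelineConfig", "run_discovery"]

logger = logging.getLogger(__name__)

# fixed fan-out offsets from the master seed
_SEED_RF = 101
_SEED_SPLITS = 211

_ETHNICITY_WHITE = {"white", "caucasian"}


@dataclass
class PipelineConfig:
    """Tunable parameters of one discovery run."""

    layout: LayoutConfig = field(default_factory=LayoutConfig)
    top_k: int = 10
    rf_repeats: int = 100
    rf_trees: int = 500
    n_splits: int = 1000
    train_frac: float = 0.8
    alpha: float = 0.05
    seed: int = 0
    correlation_kind: str = "pearson"
    stratified_splits: bool = False
    additive_margin: float = 0.0
    normalize_ddof: int = 0

    def validate(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError(f"train_frac must lie in (0, 1), got {self.train_frac}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        for name in ("top_k", "rf_repeats", "rf_trees", "n_splits"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.correlation_kind not in {"pearson", "spearman"}:
            raise ValueError(f"unknown correlation_kind {self.correlation_kind!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat key/value YAML config; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        layout_raw = raw.pop("layout", None)
        raw.update(overrides)
        cfg = cls(**raw)
        if layout_raw:
            cfg.layout = LayoutConfig(**layout_raw)
        cfg.validate()
        return cfg

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["layout"] = {
            "columns": dict(self.layout.columns),
            "analyte_columns": list(self.layout.analyte_columns)
            if self.layout.analyte_columns
            else None,
            "qc_table": str(self.layout.qc_table) if self.layout.qc_table else None,
            "sheet": self.layout.sheet,
        }
        return d


def run_discovery(
    config: PipelineConfig,
    input: str | Path | ProteomicDataset,
    outdir: str | Path,
) -> PanelResult:
    """Run the full discovery pipeline and write all result tables.

    Outputs under ``outdir``: ranked lists per method, the differential
    table, panel summary and per-candidate/per-split metrics, the
    covariate report, duplicate %CV (when duplicate pairs exist), and a
    ``manifest.json`` recording config, seed and software version.  When
    the input carries no severity scores the correlation ranking is
    skipped and the skip is recorded in the manifest.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": "panelforge",
        "version": __version__,
        "config": config.to_manifest(),
        "skipped": [],
    }

    ds = input if isinstance(input, ProteomicDataset) else read_dataset(
        Path(input), layout=config.layout
    )
    manifest["input"] = {
        "n_samples": ds.n_samples,
        "n_analytes": ds.n_analytes,
        "n_qc_fail": int((~ds.qc_pass).sum()),
    }

    filtered = qc_filter(ds)
    z = normalize(filtered, ddof=config.normalize_ddof)
    group = filtered.group

    rf = rf_importance_ranking(
        z, group, n_repeats=config.rf_repeats, k=config.top_k,
        seed=config.seed + _SEED_RF, n_trees=config.rf_trees,
    )
    diff = differential_abundance(z, filtered, group, alpha=config.alpha)
    tt = ttest_ranking(diff, k=config.top_k)

    corr = None
    have_severity = filtered.severity is not None and bool(
        (~np.isnan(filtered.severity)).sum()
    )
    if have_severity:
        corr = severity_correlation_ranking(
            z, filtered.severity, k=config.top_k, method=config.correlation_kind
        )
    else:
        manifest["skipped"].append(
            "severity_correlation_ranking: no severity scores in input"
        )

    core, candidates = find_core(rf, tt, corr)
    result = additive_search(
        z, group, core, candidates,
        n_splits=config.n_splits, seed=config.seed + _SEED_SPLITS,
        train_frac=config.train_frac, margin=config.additive_margin,
        stratified=config.stratified_splits,
    )

    # ---- exports -------------------------------------------------------
    write_table(rf.table, outdir / "rf_ranking.csv")
    write_table(tt.to_frame(), outdir / "ttest_ranking.csv")
    write_table(diff.table, outdir / "differential_abundance.csv")
    if corr is not None:
        write_table(corr.table, outdir / "correlation_ranking.csv")

    summary_rows = [
        {
            "analyte_id": p,
            "in_core": p in set(result.core),
            "in_additive": p in set(result.additive),
            "candidate_auc_mean": result.per_candidate_eval[p].auc_mean
            if p in result.per_candidate_eval
            else np.nan,
        }
        for p in result.final_panel + [c for c in result.candidates if c not in set(result.additive)]
    ]
    write_table(summary_rows, outdir / "panel_summary.csv")
    write_table(
        [
            {"analyte_id": c, "auc_mean": ev.auc_mean, "auc_sd": ev.auc_sd}
            for c, ev in result.per_candidate_eval.items()
        ],
        outdir / "per_candidate_auc.csv",
    )
    write_table(result.final_eval.per_split_frame(), outdir / "per_split_metrics.csv")
    manifest["panel"] = {
        "core": result.core,
        "additive": result.additive,
        "final_panel": result.final_panel,
        "core_auc_mean": result.core_eval.auc_mean if result.core_eval else None,
        "final": result.final_eval.summary(),
    }

    # ---- covariate battery --------------------------------------------
    cov_frames = []
    panel = result.final_panel
    if filtered.ethnicity is not None and panel:
        known = np.array([e is not None for e in filtered.ethnicity])
        if known.any():
            white = np.array(
                [
                    None if e is None else str(e).strip().lower() in _ETHNICITY_WHITE
                    for e in filtered.ethnicity
                ],
                dtype=object,
            )
            try:
                rep = binary_covariate_test(z, white, panel, covariate="ethnicity")
                cov_frames.append(rep.table.assign(covariate="ethnicity"))
            except ValueError as exc:
                manifest["skipped"].append(f"ethnicity: {exc}")
    if filtered.allergy is not None and panel:
        try:
            rep = binary_covariate_test(z, filtered.allergy, panel, covariate="allergy")
            cov_frames.append(rep.table.assign(covariate="allergy"))
        except ValueError as exc:
            manifest["skipped"].append(f"allergy: {exc}")
    if filtered.age_years is not None and panel:
        try:
            rep = age_correlation(z, filtered.age_years, panel)
            cov_frames.append(rep.table.assign(covariate="age"))
        except ValueError as exc:
            manifest["skipped"].append(f"age: {exc}")
    if cov_frames:
        import pandas as pd

        write_table(pd.concat(cov_frames, ignore_index=True), outdir / "covariate_report.csv")

    if filtered.medication is not None and panel:
        full_ev, red_ev = medication_sensitivity(
            z, group, panel, filtered.medication,
            n_splits=config.n_splits, train_frac=config.train_frac,
            seed=config.seed + _SEED_SPLITS, stratified=config.stratified_splits,
        )
        from .covariates import _coerce_binary

        flags = _coerce_binary(np.asarray(filtered.medication, dtype=object))
        manifest["medication_sensitivity"] = {
            "full_auc_mean": full_ev.auc_mean,
            "reduced_auc_mean": red_ev.auc_mean,
            "n_removed": int((flags == 1.0).sum()),
        }

    if ds.duplicate_of is not None and any(d is not None for d in ds.duplicate_of):
        cv = duplicate_variability(ds, panel if panel else None)
        write_table(cv, outdir / "duplicate_cv.csv")
        manifest["duplicate_cv_mean_pct"] = float(cv["mean_pct_cv"].mean())

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result
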