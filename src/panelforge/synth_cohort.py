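"""Synthetic serum-proteomic cohorts with planted, recoverable structure.

The generator emulates the statistical design of a two-arm aptamer-panel
discovery study: ~150 boys split into balanced case/control groups, ~1,300
analytes of which a fixed number fail QC, strictly positive log-normal
abundances, a small set of analytes carrying group log2-fold-change
effects, a distinct set correlated with a case-only integer severity score
(ADOS total), and blinded technical duplicate pairs with a controlled
percent coefficient of variation.  The planted truth travels alongside the
dataset so recovery can be tested end to end.

Model
-----
For analyte *a* the log10 abundance of sample *s* is

    x[s, a] = mu_a + e[s, a],   mu_a ~ U(baseline_log10_mean_range),
                                e[s, a] ~ N(0, baseline_log10_sd^2)

A planted group effect ``(a, d)`` shifts case samples by ``d * log10(2)``,
so the case/control ratio of expected RFU means is exactly ``2**d``.  A
planted severity effect ``(a, r)`` replaces the case-sample noise of
analyte *a* by a Gaussian copula with the latent severity trait:
``e = sd * (r*t + sqrt(1-r^2)*eps)`` where ``t ~ N(0,1)`` is the trait
later discretized to an integer ADOS-like total, giving a case-only
Pearson correlation of approximately *r* (mildly attenuated by the
discretization).  Duplicate re-measurements multiply the original RFU by
``exp(sigma*Z)`` with ``sigma = sqrt(pi) * duplicate_cv``, which makes the
expected two-point %CV of an (original, duplicate) pair equal to
``duplicate_cv``.

Demographic covariates (age, ethnicity, allergy, medication) are drawn
independently of all protein values with marginals resembling a pediatric
autism cohort, so they act as true null confounders for the covariate
battery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataio import ProteomicDataset, ValidationError, write_dataset

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "attach_duplicates",
    "study_cohort_spec",
    "write_cohort",
]

LOG10_2 = np.log10(2.0)


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort; a pure function of ``seed``.

    ``planted_group_effects`` lists ``(analyte_index, log2_fold_change)``
    pairs; ``planted_severity_effects`` lists ``(analyte_index,
    target_pearson_r)`` pairs applied to case samples only.
    ``duplicate_cv`` is the expected two-point %CV/100 between a sample
    and its blinded duplicate.
    """

    n_case: int = 76
    n_control: int = 78
    n_analytes: int = 1317
    n_qc_fail: int = 192
    planted_group_effects: Sequence[tuple[int, float]] = field(default_factory=tuple)
    planted_severity_effects: Sequence[tuple[int, float]] = field(default_factory=tuple)
    severity_range: tuple[int, int] = (6, 26)
    baseline_log10_mean_range: tuple[float, float] = (2.0, 4.5)
    baseline_log10_sd: float = 0.05
    duplicate_pairs: int = 7
    duplicate_cv: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_case", "n_control", "n_analytes"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0 <= self.n_qc_fail < self.n_analytes:
            raise ValidationError(
                f"n_qc_fail must lie in [0, n_analytes), got {self.n_qc_fail}"
            )
        for name, effects in (
            ("planted_group_effects", self.planted_group_effects),
            ("planted_severity_effects", self.planted_severity_effects),
        ):
            idx = [i for i, _ in effects]
            if len(set(idx)) != len(idx):
                raise ValidationError(f"{name}: planted analyte indices must be distinct")
            if any(i < 0 or i >= self.n_analytes for i in idx):
                raise ValidationError(f"{name}: analyte index out of range [0, n_analytes)")
        for _, r in self.planted_severity_effects:
            if not -1.0 < r < 1.0:
                raise ValidationError(
                    f"planted_severity_effects: target correlation {r} outside (-1, 1)"
                )
        if not 0.0 <= self.duplicate_cv < 1.0:
            raise ValidationError(f"duplicate_cv must lie in [0, 1), got {self.duplicate_cv}")
        lo, hi = self.severity_range
        if lo >= hi:
            raise ValidationError(f"severity_range low must be < high, got {self.severity_range}")
        lo, hi = self.baseline_log10_mean_range
        if lo > hi:
            raise ValidationError("baseline_log10_mean_range low must be <= high")
        if self.baseline_log10_sd <= 0:
            raise ValidationError(f"baseline_log10_sd must be > 0, got {self.baseline_log10_sd}")
        if self.duplicate_pairs < 0 or self.duplicate_pairs > min(self.n_case, self.n_control):
            raise ValidationError(
                "duplicate_pairs must lie in [0, min(n_case, n_control)], got "
                f"{self.duplicate_pairs}"
            )


@dataclass
class SyntheticCohort:
    """A generated dataset plus the planted truth for recovery tests."""

    dataset: ProteomicDataset
    truth: dict

    @property
    def planted_group_analytes(self) -> list[str]:
        return [a for a, _ in self.truth["group_effects"]]

    @property
    def planted_severity_analytes(self) -> list[str]:
        return [a for a, _ in self.truth["severity_effects"]]


def _analyte_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"PROT_{i:0{width}d}" for i in range(n)]


def _demographics(rng: np.random.Generator, n: int):
    """Null covariates with marginals like a pediatric two-arm serum study."""
    age = rng.uniform(2.0, 10.0, size=n)
    eth = np.array(
        [None if rng.random() < 4 / 154 else ("white" if rng.random() < 0.5 else "non-white") for _ in range(n)],
        dtype=object,
    )
    allergy = np.array(
        [None if rng.random() < 5 / 154 else bool(rng.random() < 44 / 149) for _ in range(n)],
        dtype=object,
    )
    medication = np.array(
        [None if rng.random() < 2 / 154 else bool(rng.random() < 8 / 152) for _ in range(n)],
        dtype=object,
    )
    return age, eth, allergy, medication


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate one cohort; identical specs yield bit-identical cohorts."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EED]))
    n = spec.n_case + spec.n_control
    m = spec.n_analytes
    analytes = _analyte_ids(m)
    sample_ids = [f"CASE_{i:03d}" for i in range(spec.n_case)] + [
        f"CTRL_{i:03d}" for i in range(spec.n_control)
    ]
    group = np.array(["case"] * spec.n_case + ["control"] * spec.n_control, dtype=object)

    mu = rng.uniform(*spec.baseline_log10_mean_range, size=m)
    noise = rng.standard_normal((n, m)) * spec.baseline_log10_sd

    # latent severity trait for cases, shared by copula-planted analytes
    trait = rng.standard_normal(spec.n_case)
    case_rows = slice(0, spec.n_case)
    for j, r in spec.planted_severity_effects:
        eps = rng.standard_normal(spec.n_case)
        noise[case_rows, j] = spec.baseline_log10_sd * (r * trait + np.sqrt(1 - r * r) * eps)

    log10x = mu[None, :] + noise
    for j, d in spec.planted_group_effects:
        log10x[case_rows, j] += d * LOG10_2

    # integer ADOS-like totals: linear map of the trait spanning ~3 SD to
    # each bound, rounded and clipped; keeps Pearson near the copula target
    lo, hi = spec.severity_range
    mid, scale = (lo + hi) / 2.0, (hi - lo) / 6.0
    sev_case = np.clip(np.rint(mid + scale * trait), lo, hi).astype(int)
    severity = np.full(n, np.nan)
    severity[case_rows] = sev_case

    # QC failures drawn outside the planted sets so planted signal survives QC
    planted = {j for j, _ in spec.planted_group_effects} | {
        j for j, _ in spec.planted_severity_effects
    }
    eligible = np.array(sorted(set(range(m)) - planted))
    qc_pass = np.ones(m, dtype=bool)
    if spec.n_qc_fail:
        if len(eligible) < spec.n_qc_fail:
            raise ValidationError("n_qc_fail exceeds the number of non-planted analytes")
        fail = rng.choice(eligible, size=spec.n_qc_fail, replace=False)
        qc_pass[fail] = False

    age, eth, allergy, medication = _demographics(rng, n)

    dataset = ProteomicDataset(
        sample_ids=sample_ids,
        group=group,
        analyte_ids=analytes,
        rfu=np.power(10.0, log10x),
        qc_pass=qc_pass,
        age_years=age,
        ethnicity=eth,
        allergy=allergy,
        medication=medication,
        severity=severity,
        duplicate_of=np.array([None] * n, dtype=object),
    )
    truth = {
        "group_effects": [(analytes[j], float(d)) for j, d in spec.planted_group_effects],
        "severity_effects": [(analytes[j], float(r)) for j, r in spec.planted_severity_effects],
        "qc_fail_analytes": [a for a, ok in zip(analytes, qc_pass) if not ok],
    }
    return SyntheticCohort(dataset=dataset, truth=truth)


def attach_duplicates(cohort: SyntheticCohort, spec: CohortSpec) -> SyntheticCohort:
    """Append blinded duplicate re-measurements of the first
    ``duplicate_pairs`` case and control samples.

    The duplicate of sample *s* equals ``rfu[s] * exp(sigma * Z)`` with
    ``sigma = sqrt(pi) * duplicate_cv`` per analyte, so the expected
    two-point %CV (sample-SD convention) of each pair is
    ``100 * duplicate_cv``.  With ``duplicate_cv = 0`` duplicates are
    bit-identical to their originals.
    """
    spec.validate()
    if spec.duplicate_pairs == 0:
        return cohort
    ds = cohort.dataset
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xD0B1]))
    case_idx = np.flatnonzero(ds.group == "case")[: spec.duplicate_pairs]
    ctrl_idx = np.flatnonzero(ds.group == "control")[: spec.duplicate_pairs]
    originals = np.concatenate([case_idx, ctrl_idx])

    sigma = np.sqrt(np.pi) * spec.duplicate_cv
    factor = (
        np.exp(sigma * rng.standard_normal((len(originals), ds.n_analytes)))
        if sigma > 0
        else np.ones((len(originals), ds.n_analytes))
    )
    dup_rfu = ds.rfu[originals] * factor
    dup_ids = [f"DUP_{ds.sample_ids[i]}" for i in originals]

    def _cat(a, b):
        return None if a is None else np.concatenate([a, b])

    new = ProteomicDataset(
        sample_ids=list(ds.sample_ids) + dup_ids,
        group=np.concatenate([ds.group, ds.group[originals]]),
        analyte_ids=list(ds.analyte_ids),
        rfu=np.vstack([ds.rfu, dup_rfu]),
        qc_pass=ds.qc_pass.copy(),
        age_years=_cat(ds.age_years, ds.age_years[originals] if ds.age_years is not None else None),
        ethnicity=_cat(ds.ethnicity, ds.ethnicity[originals] if ds.ethnicity is not None else None),
        allergy=_cat(ds.allergy, ds.allergy[originals] if ds.allergy is not None else None),
        medication=_cat(
            ds.medication, ds.medication[originals] if ds.medication is not None else None
        ),
        severity=_cat(ds.severity, ds.severity[originals] if ds.severity is not None else None),
        duplicate_of=np.concatenate(
            [
                ds.duplicate_of
                if ds.duplicate_of is not None
                else np.array([None] * ds.n_samples, dtype=object),
                np.array([ds.sample_ids[i] for i in originals], dtype=object),
            ]
        ),
    )
    return SyntheticCohort(dataset=new, truth=dict(cohort.truth))


def study_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The default study-scale cohort: 76 cases vs 78 controls, 1,317
    analytes with 192 QC failures, six group-discriminative analytes with
    fold changes on the scale reported for serum panels (log2 FC from
    roughly -0.9 to +0.1), four severity-correlated analytes
    (|r| ~ 0.30-0.41), and 7 + 7 blinded duplicate pairs at 10% CV.
    """
    spec = CohortSpec(
        planted_group_effects=(
            (10, -0.1505),
            (20, 0.1000),
            (30, -0.1274),
            (40, -0.0916),
            (50, -0.0788),
            (60, -0.8843),
        ),
        planted_severity_effects=(
            (100, -0.4058),
            (110, -0.3898),
            (120, -0.3895),
            (130, -0.3008),
        ),
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


def write_cohort(cohort: SyntheticCohort, path: str | Path, format: str | None = None) -> None:
    """Write the dataset via :mod:`panelforge.dataio` plus a JSON truth
    sidecar (``<stem>.truth.json``) for recovery tests."""
    path = Path(path)
    write_dataset(cohort.dataset, path, format=format)
    sidecar = path.with_suffix(".truth.json")
    sidecar.write_text(json.dumps(cohort.truth, indent=2))
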