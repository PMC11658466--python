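"""Reading, validating and writing wide protein-abundance datasets.

The canonical on-disk layout is a single wide table: one metadata block
(sample_id, group, age, ethnicity, allergy, medication, severity,
duplicate_of) followed by one numeric column per analyte (relative
fluorescence units, RFU).  Per-analyte QC flags travel in a small sidecar
table (``analyte_id, qc_pass``); analytes absent from the sidecar default
to pass.  A :class:`LayoutConfig` maps dialect column names onto the
canonical ones so externally produced files (CSV/TSV/XLSX) can be ingested
without editing them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProteomicDataset",
    "LayoutConfig",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "write_table",
]

#: Accepted spellings for the two study arms, compared case-insensitively.
_CASE_LABELS = {"asd", "case", "1"}
_CONTROL_LABELS = {"td", "control", "0"}

_METADATA_FIELDS = (
    "sample_id",
    "group",
    "age",
    "ethnicity",
    "allergy",
    "medication",
    "severity",
    "duplicate_of",
)


class ValidationError(ValueError):
    """A dataset violated a structural invariant."""


@dataclass
class LayoutConfig:
    """Column-name mapping absorbing file-dialect differences.

    ``columns`` maps canonical metadata names (see ``_METADATA_FIELDS``) to
    the column names used in the file; names absent from the file are
    treated as absent metadata.  ``analyte_columns`` optionally restricts
    which columns are analytes (default: every non-metadata column).
    ``qc_table`` names a sidecar CSV with columns ``analyte_id, qc_pass``;
    ``sheet`` selects the XLSX worksheet (default first).
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    analyte_columns: Sequence[str] | None = None
    qc_table: str | Path | None = None
    sheet: int | str = 0

    def column_for(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


@dataclass
class ProteomicDataset:
    """A samples x analytes RFU matrix with per-sample metadata.

    ``severity`` (ADOS total = SA + RRB) is defined for case samples only;
    controls carry NaN, never a numeric placeholder.  ``duplicate_of``
    links a blinded technical duplicate to its original sample id (None
    for primary samples).
    """

    sample_ids: list[str]
    group: np.ndarray  # of {"case", "control"}
    analyte_ids: list[str]
    rfu: np.ndarray  # (n_samples, n_analytes), positive floats
    qc_pass: np.ndarray  # bool per analyte
    age_years: np.ndarray | None = None  # float, NaN = absent
    ethnicity: np.ndarray | None = None  # object, None = absent
    allergy: np.ndarray | None = None  # object bool, None = absent
    medication: np.ndarray | None = None  # object bool, None = absent
    severity: np.ndarray | None = None  # float, NaN = absent; integer-valued
    duplicate_of: np.ndarray | None = None  # object str, None = primary

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=object)
        self.rfu = np.asarray(self.rfu, dtype=float)
        self.qc_pass = np.asarray(self.qc_pass, dtype=bool)
        if self.severity is not None:
            self.severity = np.asarray(self.severity, dtype=float)
        if self.age_years is not None:
            self.age_years = np.asarray(self.age_years, dtype=float)
        self.validate()

    # -- structural invariants -------------------------------------------
    def validate(self) -> None:
        n, m = self.rfu.shape
        if n != len(self.sample_ids) or m != len(self.analyte_ids):
            raise ValidationError(
                f"matrix shape {self.rfu.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.analyte_ids)} analytes"
            )
        for name, ids in (("sample", self.sample_ids), ("analyte", self.analyte_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValidationError(f"duplicated {name} ID: {i!r}")
                seen.add(i)
        bad = set(self.group) - {"case", "control"}
        if bad:
            raise ValidationError(f"unrecognized group labels: {sorted(bad)}")
        if len(self.qc_pass) != m:
            raise ValidationError("qc_pass length does not match analyte count")
        if not np.all(np.isfinite(self.rfu)):
            i, j = np.argwhere(~np.isfinite(self.rfu))[0]
            raise ValidationError(
                f"non-finite RFU at sample {self.sample_ids[i]!r}, "
                f"analyte {self.analyte_ids[j]!r}"
            )
        if np.any(self.rfu <= 0):
            i, j = np.argwhere(self.rfu <= 0)[0]
            raise ValidationError(
                f"non-positive RFU at sample {self.sample_ids[i]!r}, "
                f"analyte {self.analyte_ids[j]!r}"
            )
        if self.severity is not None:
            has_sev = ~np.isnan(self.severity)
            on_control = has_sev & (self.group == "control")
            if np.any(on_control):
                sid = self.sample_ids[int(np.argmax(on_control))]
                raise ValidationError(
                    f"severity score present on control sample {sid!r}: ADOS is "
                    "administered to the case group only, so controls must carry "
                    "no severity score"
                )
        if self.duplicate_of is not None:
            known = set(self.sample_ids)
            for i, ref in enumerate(self.duplicate_of):
                if ref is not None and ref not in known:
                    raise ValidationError(
                        f"duplicate_of of sample {self.sample_ids[i]!r} refers to "
                        f"unknown sample {ref!r}"
                    )

    # -- convenience -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_analytes(self) -> int:
        return len(self.analyte_ids)

    @property
    def case_mask(self) -> np.ndarray:
        return self.group == "case"

    def select_samples(self, mask: np.ndarray) -> "ProteomicDataset":
        mask = np.asarray(mask, dtype=bool)

        def _take(a):
            return None if a is None else np.asarray(a, dtype=object)[mask] if a.dtype == object else a[mask]

        kept = set(np.asarray(self.sample_ids, dtype=object)[mask])
        dup = None
        if self.duplicate_of is not None:
            dup = np.array(
                [d if d in kept else None for d in np.asarray(self.duplicate_of, dtype=object)[mask]],
                dtype=object,
            )
        return ProteomicDataset(
            sample_ids=[s for s, keep in zip(self.sample_ids, mask) if keep],
            group=self.group[mask],
            analyte_ids=list(self.analyte_ids),
            rfu=self.rfu[mask],
            qc_pass=self.qc_pass.copy(),
            age_years=None if self.age_years is None else self.age_years[mask],
            ethnicity=_take(self.ethnicity),
            allergy=_take(self.allergy),
            medication=_take(self.medication),
            severity=None if self.severity is None else self.severity[mask],
            duplicate_of=dup,
        )

    def select_analytes(self, mask: np.ndarray) -> "ProteomicDataset":
        mask = np.asarray(mask, dtype=bool)
        return dataclasses.replace(
            self,
            analyte_ids=[a for a, keep in zip(self.analyte_ids, mask) if keep],
            rfu=self.rfu[:, mask],
            qc_pass=self.qc_pass[mask],
        )


def _normalize_group(value: object, where: str) -> str:
    text = str(value).strip().lower()
    if text in _CASE_LABELS:
        return "case"
    if text in _CONTROL_LABELS:
        return "control"
    raise ValidationError(f"unrecognized group label {value!r} for {where}")


def _optional_bool(value: object) -> object:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "1", "yes", "y", "1.0"}:
        return True
    if text in {"false", "0", "no", "n", "0.0"}:
        return False
    raise ValidationError(f"cannot interpret {value!r} as boolean")


def _optional_str(value: object) -> object:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return str(value)


def _read_frame(path: Path, format: str | None, layout: LayoutConfig) -> pd.DataFrame:
    fmt = format or {".csv": "csv", ".tsv": "tsv", ".xlsx": "xlsx"}.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"cannot infer format of {path}; pass format=")
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t")
    if fmt == "xlsx":
        return pd.read_excel(path, sheet_name=layout.sheet, engine="openpyxl")
    raise ValueError(f"unsupported format {fmt!r}")


def read_dataset(
    path: str | Path,
    format: str | None = None,
    layout: LayoutConfig | None = None,
) -> ProteomicDataset:
    """Read and validate a wide RFU table.

    Metadata columns missing from the file become "absent" (None/NaN);
    analytes missing from the QC sidecar default to pass.  Non-numeric or
    non-positive RFU cells raise with the offending row/column address.
    """
    layout = layout or LayoutConfig()
    path = Path(path)
    frame = _read_frame(path, format, layout)

    colmap = {f: layout.column_for(f) for f in _METADATA_FIELDS}
    meta_cols = [c for c in colmap.values() if c in frame.columns]
    if colmap["sample_id"] not in frame.columns:
        raise ValidationError(f"missing sample_id column {colmap['sample_id']!r}")
    if colmap["group"] not in frame.columns:
        raise ValidationError(f"missing group column {colmap['group']!r}")

    if layout.analyte_columns is not None:
        analyte_cols = list(layout.analyte_columns)
    else:
        analyte_cols = [c for c in frame.columns if c not in meta_cols]
    if not analyte_cols:
        raise ValidationError("no analyte columns found")

    sample_ids = [str(s) for s in frame[colmap["sample_id"]]]
    group = np.array(
        [_normalize_group(g, f"sample {s!r}") for s, g in zip(sample_ids, frame[colmap["group"]])],
        dtype=object,
    )

    raw = frame[analyte_cols]
    rfu = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(analyte_cols):
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() & raw[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValidationError(
                f"non-numeric RFU {raw[col].iloc[i]!r} at sample "
                f"{sample_ids[i]!r}, analyte {col!r}"
            )
        rfu[:, j] = numeric.to_numpy(dtype=float)

    def _series(field_name: str):
        col = colmap[field_name]
        return frame[col] if col in frame.columns else None

    age_s = _series("age")
    sev_s = _series("severity")
    eth_s = _series("ethnicity")
    alg_s = _series("allergy")
    med_s = _series("medication")
    dup_s = _series("duplicate_of")

    n = len(sample_ids)
    fmt = format or {".csv": "csv", ".tsv": "tsv", ".xlsx": "xlsx"}.get(path.suffix.lower())
    qc_pass = np.ones(len(analyte_cols), dtype=bool)
    qc: pd.Series | None = None
    if layout.qc_table:
        qc = pd.read_csv(layout.qc_table).set_index("analyte_id")["qc_pass"]
    elif fmt == "xlsx":
        try:
            qc = pd.read_excel(path, sheet_name="analytes", engine="openpyxl").set_index(
                "analyte_id"
            )["qc_pass"]
        except ValueError:  # no such worksheet: all-pass default
            qc = None
    elif path.with_suffix(".analytes.csv").exists():
        qc = pd.read_csv(path.with_suffix(".analytes.csv")).set_index("analyte_id")["qc_pass"]
    if qc is not None:
        for j, a in enumerate(analyte_cols):
            if a in qc.index:
                qc_pass[j] = bool(qc.loc[a])

    return ProteomicDataset(
        sample_ids=sample_ids,
        group=group,
        analyte_ids=list(analyte_cols),
        rfu=rfu,
        qc_pass=qc_pass,
        age_years=None if age_s is None else pd.to_numeric(age_s, errors="coerce").to_numpy(float),
        ethnicity=None if eth_s is None else np.array([_optional_str(v) for v in eth_s], dtype=object),
        allergy=None if alg_s is None else np.array([_optional_bool(v) for v in alg_s], dtype=object),
        medication=None if med_s is None else np.array([_optional_bool(v) for v in med_s], dtype=object),
        severity=None if sev_s is None else pd.to_numeric(sev_s, errors="coerce").to_numpy(float),
        duplicate_of=None
        if dup_s is None
        else np.array([_optional_str(v) for v in dup_s], dtype=object),
    ) if n else _empty_error()


def _empty_error():
    raise ValidationError("dataset contains no samples")


def _metadata_frame(ds: ProteomicDataset) -> pd.DataFrame:
    def _obj(a, fill=None):
        if a is None:
            return [fill] * ds.n_samples
        return list(a)

    return pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "group": list(ds.group),
            "age": _obj(ds.age_years),
            "ethnicity": _obj(ds.ethnicity),
            "allergy": _obj(ds.allergy),
            "medication": _obj(ds.medication),
            "severity": _obj(ds.severity),
            "duplicate_of": _obj(ds.duplicate_of),
        }
    )


def write_dataset(ds: ProteomicDataset, path: str | Path, format: str | None = None) -> None:
    """Write the canonical wide layout plus the QC sidecar table.

    CSV/TSV write ``<path>`` and ``<stem>.analytes.csv``; XLSX writes two
    worksheets (``data``, ``analytes``).  ``read_dataset`` round-trips the
    result.
    """
    path = Path(path)
    fmt = format or {".csv": "csv", ".tsv": "tsv", ".xlsx": "xlsx"}.get(path.suffix.lower())
    meta = _metadata_frame(ds)
    data = pd.concat(
        [meta, pd.DataFrame(ds.rfu, columns=ds.analyte_ids, index=meta.index)], axis=1
    )
    qc = pd.DataFrame({"analyte_id": ds.analyte_ids, "qc_pass": ds.qc_pass})
    if fmt == "xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as xl:
            data.to_excel(xl, sheet_name="data", index=False)
            qc.to_excel(xl, sheet_name="analytes", index=False)
        return
    sep = "\t" if fmt == "tsv" else ","
    data.to_csv(path, sep=sep, index=False, float_format="%.10g")
    qc.to_csv(path.with_suffix(".analytes.csv"), index=False)


def write_table(rows: pd.DataFrame | Iterable[Mapping[str, object]], path: str | Path) -> None:
    """Write tabular records as CSV with deterministic column and row order.

    Floats are rendered with 10 significant digits so a read-back agrees to
    well below 1e-9 relative error.
    """
    frame = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    frame.to_csv(path, index=False, float_format="%.10g")
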