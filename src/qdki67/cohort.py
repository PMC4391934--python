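"""Per-patient cohort table: typed records, validated reading and writing.

The table is shaped like the tumour-bank export that accompanies a TMA
study: one row per patient with clinico-pathological covariates (age,
menopausal status, T/N stage, histological grade, ER, HER2), the imaging
quantification (Ki67 sum, CK sum, Ki67/CK ratio) and, when follow-up is
available, disease-free-survival time in months and an event flag.
CSV is the canonical dialect; XLS/XLSX are accepted with a user-supplied
column map since deposited spreadsheets rarely share header conventions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field, fields
from typing import Iterable, Mapping

import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["PatientRecord", "CohortTable", "read_cohort_table", "write_cohort_table"]

#: columns a cohort table must provide (after applying the column map)
MANDATORY_COLUMNS = ("ki67_sum", "ck_sum")

_CATEGORICAL_DOMAINS = {
    "menopausal": {"pre", "post"},
    "t_stage": {1, 2, 3},
    "n_stage": {0, 1, 2, 3},
    "histo_grade": {1, 2, 3},
    "er": {0, 1},
    "her2": {0, 1},
    "event": {0, 1},
}


@dataclass
class PatientRecord:
    """One patient: covariates, imaging quantification and optional outcome.

    ``er``/``her2``/``event`` are 0/1 flags (positive / amplified /
    recurrence = 1); ``ratio`` is Ki67 sum divided by CK sum.
    """

    patient_id: str
    ki67_sum: float
    ck_sum: float
    ratio: float
    age: float | None = None
    menopausal: str | None = None  # "pre" | "post"
    t_stage: int | None = None  # 1..3
    n_stage: int | None = None  # 0..3
    histo_grade: int | None = None  # 1..3
    er: int | None = None
    her2: int | None = None
    dfs_months: float | None = None
    event: int | None = None


@dataclass
class CohortTable:
    """A validated list of patient records plus parse provenance."""

    records: list[PatientRecord]
    source: str = "<memory>"
    n_read: int = 0
    n_rejected: int = 0
    parse_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("patient ids are not unique")
        if self.n_read == 0:
            self.n_read = len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f.name for f in fields(PatientRecord)]
        return pd.DataFrame([asdict(r) for r in self.records], columns=cols)


def _validate_row(row: Mapping, row_no: int) -> PatientRecord:
    ki67 = float(row["ki67_sum"])
    ck = float(row["ck_sum"])
    if not (math.isfinite(ki67) and math.isfinite(ck)):
        raise ValidationError(f"row {row_no}: non-finite signal sums")
    if ki67 < 0 or ck <= 0:
        raise ValidationError(f"row {row_no}: ki67_sum must be >= 0 and ck_sum > 0")
    ratio = ki67 / ck
    stored = row.get("ratio")
    if stored is not None and not pd.isna(stored):
        stored = float(stored)
        # stored ratio only cross-validates parsing; recomputation is canonical
        if stored > 0 and abs(stored - ratio) > 0.01 * max(stored, ratio):
            raise ValidationError(
                f"row {row_no}: stored ratio {stored:g} inconsistent with "
                f"ki67_sum/ck_sum = {ratio:g}"
            )

    def opt(name, cast):
        value = row.get(name)
        if value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value):
            return None
        value = cast(value)
        domain = _CATEGORICAL_DOMAINS.get(name)
        if domain is not None and value not in domain:
            raise ValidationError(f"row {row_no}: {name}={value!r} outside {sorted(domain)}")
        return value

    dfs = opt("dfs_months", float)
    if dfs is not None and dfs <= 0:
        raise ValidationError(f"row {row_no}: dfs_months must be positive")
    return PatientRecord(
        patient_id=str(row.get("patient_id", f"P{row_no:04d}")),
        ki67_sum=ki67,
        ck_sum=ck,
        ratio=ratio,
        age=opt("age", float),
        menopausal=opt("menopausal", lambda v: str(v).strip().lower()),
        t_stage=opt("t_stage", int),
        n_stage=opt("n_stage", int),
        histo_grade=opt("histo_grade", int),
        er=opt("er", int),
        her2=opt("her2", int),
        dfs_months=dfs,
        event=opt("event", int),
    )


def read_cohort_table(path, column_map: Mapping[str, str] | None = None) -> CohortTable:
    """Read and validate a per-patient cohort table (CSV, XLS or XLSX).

    ``column_map`` maps file headers to canonical field names, e.g.
    ``{"Ki67 quantificational value": "ki67_sum"}``.  Rows that fail
    validation are rejected individually with a logged reason; a missing
    mandatory column aborts with :class:`SchemaError`.
    """
    path = str(path)
    if path.endswith((".xls", ".xlsx")):
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")

    records: list[PatientRecord] = []
    parse_log: list[str] = []
    n_rejected = 0
    seen_ids: set[str] = set()
    for row_no, row in enumerate(frame.to_dict(orient="records")):
        try:
            record = _validate_row(row, row_no)
            if record.patient_id in seen_ids:
                raise ValidationError(f"row {row_no}: duplicate patient_id {record.patient_id}")
        except (ValidationError, ValueError, TypeError) as exc:
            n_rejected += 1
            message = f"rejected row {row_no}: {exc}"
            parse_log.append(message)
            logger.warning("%s: %s", path, message)
            continue
        seen_ids.add(record.patient_id)
        records.append(record)
    parse_log.append(f"read {len(frame)} rows, accepted {len(records)}, rejected {n_rejected}")
    return CohortTable(
        records=records,
        source=path,
        n_read=len(frame),
        n_rejected=n_rejected,
        parse_log=parse_log,
    )


def write_cohort_table(cohort: CohortTable | Iterable[PatientRecord], path) -> None:
    """Write records to CSV (canonical) or XLSX, one row per patient."""
    path = str(path)
    if isinstance(cohort, CohortTable):
        frame = cohort.to_dataframe()
    else:
        frame = CohortTable(records=list(cohort)).to_dataframe()
    if path.endswith(".xlsx"):
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)
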