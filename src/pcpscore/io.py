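"""Cohort CSV reading/writing with validation.

Schema: header ``id,age,diagnosis,tpsa,fpsa,cpsa``; diagnosis in
{PCa, BPH}; decimal point, UTF-8.  A missing cPSA value is filled with
tPSA - fPSA and the row flagged as derived; rows violating the record
invariants are rejected with a line-numbered log entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cohort import Cohort, CohortError, DEFAULT_STRATA, GROUPS, PatientRecord
from .scores import derive_cpsa

__all__ = ["read_cohort", "write_cohort", "ReadReport"]

log = logging.getLogger(__name__)

COLUMNS = ["id", "age", "diagnosis", "tpsa", "fpsa", "cpsa"]


@dataclass(frozen=True)
class ReadReport:
    n_read: int
    n_rejected: int
    n_derived_cpsa: int
    rejected_rows: tuple[int, ...]  # 1-based data row numbers
    derived_rows: tuple[int, ...]


def read_cohort(
    path: str | Path,
    strata: Sequence[tuple[float, float]] = DEFAULT_STRATA,
    with_report: bool = False,
) -> Cohort | tuple[Cohort, ReadReport]:
    """Load and validate a cohort CSV.

    Rows failing the record invariants (e.g. fPSA >= tPSA, tPSA outside
    the strata) are rejected and logged with their row number.  Malformed
    headers, non-numeric fields, or unknown diagnosis labels raise a
    parse error naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str})
    if list(df.columns) != COLUMNS:
        raise CohortError(
            f"{path}: expected header {','.join(COLUMNS)}, got "
            f"{','.join(map(str, df.columns))}"
        )
    records: list[PatientRecord] = []
    rejected: list[int] = []
    derived: list[int] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.diagnosis not in GROUPS:
            raise CohortError(f"{path} row {i}: unknown diagnosis {row.diagnosis!r}")
        try:
            age = float(row.age)
            tpsa = float(row.tpsa)
            fpsa = float(row.fpsa)
        except (TypeError, ValueError) as exc:
            raise CohortError(f"{path} row {i}: non-numeric field ({exc})") from exc
        cpsa_raw = row.cpsa
        try:
            if pd.isna(cpsa_raw):
                cpsa = derive_cpsa(tpsa, fpsa)
                derived.append(i)
            else:
                cpsa = float(cpsa_raw)
        except ValueError:
            log.warning("%s row %d rejected: cannot derive cpsa", path, i)
            rejected.append(i)
            continue
        try:
            rec = PatientRecord(
                id=str(row.id), age=age, diagnosis=row.diagnosis,
                tpsa=tpsa, fpsa=fpsa, cpsa=cpsa,
            )
            if not any(lo <= rec.tpsa < hi for lo, hi in strata):
                raise CohortError("tpsa outside strata")
        except CohortError as exc:
            log.warning("%s row %d rejected: %s", path, i, exc)
            rejected.append(i)
            continue
        records.append(rec)
    if rejected:
        log.warning("%s: rejected %d of %d rows", path, len(rejected), len(df))
    cohort = Cohort(records, strata)
    if with_report:
        report = ReadReport(
            n_read=len(records),
            n_rejected=len(rejected),
            n_derived_cpsa=len(derived),
            rejected_rows=tuple(rejected),
            derived_rows=tuple(derived),
        )
        return cohort, report
    return cohort


def write_cohort(cohort: Cohort, path: str | Path, float_fmt: str = "%.6g") -> None:
    """Write the cohort CSV (UTF-8, newline-terminated rows)."""
    cohort.to_dataframe().to_csv(
        Path(path), index=False, float_format=float_fmt, lineterminator="\n"
    )
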