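"""Reading, writing and inclusion filtering of CT-report tables.

A corpus is a flat table with one row per brain-CT study, mirroring a
radiology-information-system export: an opaque study identifier, patient
age and sex, study date, the reporting facility, and the two free-text
fields every report carries — the descriptive *body* and the radiologist's
*conclusion*.  Text fields are stored verbatim; no normalization happens
at rest.

Record-level inclusion filtering removes studies that cannot be used for
text classification: blank report text, patients under 18, missing age,
implausible age (data-entry artifacts such as 976 or 1000 years), and
complete line duplicates.  Every input record receives exactly one
disposition, so the kept and excluded sets always partition the input.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import SchemaError

log = logging.getLogger(__name__)

#: Column order of the corpus table.
SCHEMA = ("study_id", "age", "sex", "study_date", "facility", "body", "conclusion")

SEXES = ("female", "male", "unknown")

#: Reasons a record can be excluded, in the order the rules are applied
#: (duplicate detection runs last, over otherwise-valid records only).
EXCLUSION_REASONS = ("empty_text", "missing_age", "underage", "abnormal_age", "duplicate")

#: Inclusive age bounds for a plausible adult patient.
DEFAULT_MIN_AGE = 18
DEFAULT_MAX_AGE = 120

_DIALECT_SEP = {"csv": ",", "tsv": "\t"}


@dataclass(frozen=True)
class ReportRecord:
    """One CT study: metadata plus the two verbatim report text fields."""

    study_id: str
    age: int | None
    sex: str
    study_date: str
    facility: str
    body: str
    conclusion: str

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be non-empty")

    def row(self) -> tuple[str, ...]:
        """The record as a tuple of strings in :data:`SCHEMA` order."""
        return (
            self.study_id,
            "" if self.age is None else str(self.age),
            self.sex,
            self.study_date,
            self.facility,
            self.body,
            self.conclusion,
        )


@dataclass(frozen=True)
class Disposition:
    study_id: str
    kept: bool
    reason: str | None  # one of EXCLUSION_REASONS when not kept


@dataclass
class ExclusionLog:
    """Per-record outcome of :func:`apply_exclusions`."""

    dispositions: list[Disposition]

    @property
    def n_kept(self) -> int:
        return sum(d.kept for d in self.dispositions)

    @property
    def n_excluded(self) -> int:
        return len(self.dispositions) - self.n_kept

    def reason_counts(self) -> dict[str, int]:
        return dict(Counter(d.reason for d in self.dispositions if not d.kept))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "study_id": [d.study_id for d in self.dispositions],
                "disposition": ["kept" if d.kept else "excluded" for d in self.dispositions],
                "reason": [d.reason or "" for d in self.dispositions],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _parse_age(raw: str, study_id: str) -> int | None:
    raw = raw.strip()
    if not raw:
        return None
    try:
        return int(raw)
    except ValueError:
        log.warning("study %s: unparseable age %r treated as missing", study_id, raw)
        return None


def _parse_sex(raw: str) -> str:
    s = raw.strip().lower()
    return s if s in ("female", "male") else "unknown"


def read_corpus(path, dialect: str = "csv") -> list[ReportRecord]:
    """Read a corpus table into a list of :class:`ReportRecord`.

    Blank ages parse as missing; a non-numeric, non-blank age is kept as
    missing with a logged warning.  Row order is preserved.  A header that
    does not match :data:`SCHEMA` raises :class:`SchemaError`.
    """
    if dialect not in _DIALECT_SEP:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")
    df = pd.read_csv(
        path,
        sep=_DIALECT_SEP[dialect],
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
    )
    if tuple(df.columns) != SCHEMA:
        raise SchemaError(
            f"header {tuple(df.columns)} does not match expected schema {SCHEMA}"
        )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ReportRecord(
                study_id=row.study_id,
                age=_parse_age(row.age, row.study_id),
                sex=_parse_sex(row.sex),
                study_date=row.study_date,
                facility=row.facility,
                body=row.body,
                conclusion=row.conclusion,
            )
        )
    return records


def write_corpus(records: Iterable[ReportRecord], path, dialect: str = "csv") -> None:
    """Write records as a corpus table (RFC-4180 quoting via pandas)."""
    if dialect not in _DIALECT_SEP:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")
    df = pd.DataFrame([r.row() for r in records], columns=list(SCHEMA))
    df.to_csv(path, index=False, sep=_DIALECT_SEP[dialect])


def _blank(text: str) -> bool:
    return not text.strip()


def _dup_key(record: ReportRecord) -> tuple[str, ...]:
    # complete line duplicate = all seven fields equal after trimming
    return tuple(f.strip() for f in record.row())


def apply_exclusions(
    records: Sequence[ReportRecord],
    min_age: int = DEFAULT_MIN_AGE,
    max_age: int = DEFAULT_MAX_AGE,
) -> tuple[list[ReportRecord], ExclusionLog]:
    """Apply the record-level inclusion criteria.

    A record is kept iff body and conclusion are both non-blank, age is
    present and within ``[min_age, max_age]`` (age exactly ``min_age`` is
    included), and the record is not a complete duplicate of an
    earlier-kept record.  The first occurrence of a duplicate group is
    kept; duplicate detection runs after the per-record checks.
    """
    kept: list[ReportRecord] = []
    dispositions: list[Disposition] = []
    seen: set[tuple[str, ...]] = set()
    for record in records:
        reason = None
        if _blank(record.body) or _blank(record.conclusion):
            reason = "empty_text"
        elif record.age is None:
            reason = "missing_age"
        elif record.age < min_age:
            reason = "underage"
        elif record.age > max_age:
            reason = "abnormal_age"
        else:
            key = _dup_key(record)
            if key in seen:
                reason = "duplicate"
            else:
                seen.add(key)
        if reason is None:
            kept.append(record)
            dispositions.append(Disposition(record.study_id, True, None))
        else:
            dispositions.append(Disposition(record.study_id, False, reason))
    return kept, ExclusionLog(dispositions)
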