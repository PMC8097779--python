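"""Longitudinal PK dataset containers and NONMEM-style CSV I/O.

One row per event: ``ID, TIME, AMT, DUR, DV, EVID`` plus one column per
covariate.  ``EVID = 1`` marks a dose (AMT mg infused over DUR h), ``EVID =
0`` an observation (DV mg/L).  ``RATE`` (mg/h) is accepted in place of
``DUR`` with DUR = AMT/RATE.  Times are hours from each subject's first
event; covariates are constant within a subject (the first value wins and a
conflict is logged).

Observations at or below the assay quantification limit (2.00 mg/L for the
chemiluminescence/FPIA vancomycin assays this dialect was designed around)
are kept in the dataset but flagged ``below_loq``; estimation excludes them
by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectRecord",
    "Event",
    "PKDataset",
    "Issue",
    "read_dataset",
    "validate_dataset",
    "write_dataset",
    "DEFAULT_LLOQ",
]

DEFAULT_LLOQ = 2.0  # mg/L, assay sensitivity limit

COTHERAPY_FLAGS = (
    "ceftriaxone",
    "meropenem",
    "gentamicin",
    "furosemide",
    "ibuprofen",
    "dexamethasone",
)

#: CSV column -> SubjectRecord field
_COVARIATE_COLUMNS = {
    "WT": "weight",
    "AGE": "age",
    "HT": "height",
    "GA": "gestational_age",
    "SCR": "scr",
    "SEX": "sex",
    "CEF": "ceftriaxone",
    "MER": "meropenem",
    "GEN": "gentamicin",
    "FUR": "furosemide",
    "IBU": "ibuprofen",
    "DEX": "dexamethasone",
    "ALT": "alt",
    "AST": "ast",
    "BUN": "bun",
    "TP": "total_protein",
    "ALB": "albumin",
}
_FIELD_TO_COLUMN = {v: k for k, v in _COVARIATE_COLUMNS.items()}


@dataclass
class SubjectRecord:
    """Time-constant covariates for one infant.

    Units: weight kg, age days, height cm, gestational_age weeks,
    scr umol/L, ALT/AST U/L, BUN mmol/L, total protein and albumin g/L.
    Co-therapy flags are 0/1.
    """

    subject_id: str
    weight: float
    scr: float
    age: float = 0.0
    height: float | None = None
    gestational_age: float | None = None
    sex: str | None = None  # "male" / "female"
    ceftriaxone: int = 0
    meropenem: int = 0
    gentamicin: int = 0
    furosemide: int = 0
    ibuprofen: int = 0
    dexamethasone: int = 0
    alt: float | None = None
    ast: float | None = None
    bun: float | None = None
    total_protein: float | None = None
    albumin: float | None = None

    def covariate(self, name: str) -> float:
        """Numeric value of a covariate by field name (sex -> 1 if male)."""
        val = getattr(self, name)
        if name == "sex":
            if val is None:
                raise ValueError(f"subject {self.subject_id}: sex missing")
            return 1.0 if val == "male" else 0.0
        if val is None:
            raise ValueError(f"subject {self.subject_id}: covariate {name!r} missing")
        return float(val)


@dataclass
class Event:
    """A dose or an observation, ordered by (subject, time, dose-first)."""

    subject_id: str
    time: float  # h from the subject's first event
    kind: str  # "dose" | "observation"
    amount: float | None = None  # mg, dose only
    infusion_duration: float | None = None  # h, dose only
    concentration: float | None = None  # mg/L, observation only
    observation_label: str | None = None  # "trough" | "peak" | "other"
    below_loq: bool = False


@dataclass
class PKDataset:
    """A cohort: subject records plus the ordered event stream."""

    subjects: dict[str, SubjectRecord] = field(default_factory=dict)
    events: list[Event] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(1 for e in self.events if e.kind == "observation")

    def observations(self, include_bql: bool = True) -> list[Event]:
        return [
            e
            for e in self.events
            if e.kind == "observation" and (include_bql or not e.below_loq)
        ]

    def subject_events(self, subject_id: str) -> list[Event]:
        return [e for e in self.events if e.subject_id == subject_id]

    def sorted(self) -> "PKDataset":
        """Deterministically ordered copy: (subject, time, doses first).

        Subjects sort numerically when their ids parse as numbers, else
        lexicographically, so the ordering is invariant to row permutation.
        """

        def sid_key(sid: str):
            try:
                return (0, float(sid), sid)
            except ValueError:
                return (1, 0.0, sid)

        subjects = {sid: self.subjects[sid] for sid in sorted(self.subjects, key=sid_key)}
        ev = sorted(
            self.events,
            key=lambda e: (sid_key(e.subject_id), e.time, 0 if e.kind == "dose" else 1),
        )
        return PKDataset(subjects=subjects, events=ev)


@dataclass(frozen=True)
class Issue:
    """One validation finding; issues are data, not exceptions."""

    subject_id: str | None
    event_index: int | None
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"subject {self.subject_id}" if self.subject_id else "dataset"
        if self.event_index is not None:
            where += f", event {self.event_index}"
        return f"{where}: {self.rule}"


def _required_columns(cols: set[str]) -> None:
    needed = {"ID", "TIME", "AMT", "DV", "EVID"}
    missing = needed - cols
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")
    if "DUR" not in cols and "RATE" not in cols:
        raise ValueError("missing required column: DUR (or RATE)")


def _to_float(val, col: str, row: int) -> float | None:
    if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
        return None
    try:
        return float(val)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"unparseable numeric in column {col}, row {row}: {val!r}") from exc


def read_dataset(
    path,
    column_map: Mapping[str, str] | None = None,
    lloq: float = DEFAULT_LLOQ,
) -> PKDataset:
    """Read a NONMEM-style CSV into a validated :class:`PKDataset`.

    ``column_map`` maps canonical names (``ID``, ``TIME`` ...) to the file's
    actual headers.  Observations with DV <= ``lloq`` are flagged
    ``below_loq`` (set ``lloq=0`` to disable).  Raises on missing required
    columns and unparseable numerics; row order is canonicalised by sorting
    on (subject, time, doses-first).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    _required_columns(set(df.columns))

    subjects: dict[str, SubjectRecord] = {}
    events: list[Event] = []
    cov_cols = [c for c in df.columns if c in _COVARIATE_COLUMNS]

    for row_idx, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        sid = str(rec["ID"])
        time = _to_float(rec["TIME"], "TIME", row_idx)
        evid = _to_float(rec["EVID"], "EVID", row_idx)
        if time is None or evid is None:
            raise ValueError(f"row {row_idx}: TIME and EVID are required")
        if sid not in subjects:
            cov: dict[str, object] = {}
            for col in cov_cols:
                fld = _COVARIATE_COLUMNS[col]
                if fld == "sex":
                    raw = rec.get(col)
                    if raw is not None and isinstance(raw, str) and raw.strip():
                        cov[fld] = raw.strip().lower()
                    continue
                val = _to_float(rec.get(col), col, row_idx)
                if val is not None:
                    cov[fld] = int(val) if fld in COTHERAPY_FLAGS else val
            subjects[sid] = SubjectRecord(
                subject_id=sid,
                weight=cov.pop("weight", float("nan")),
                scr=cov.pop("scr", float("nan")),
                **cov,
            )
        else:
            # covariates are time-constant: first value wins, conflicts logged
            existing = subjects[sid]
            for col in cov_cols:
                fld = _COVARIATE_COLUMNS[col]
                if fld == "sex":
                    continue
                val = _to_float(rec.get(col), col, row_idx)
                old = getattr(existing, fld)
                if val is not None and old is not None and not math.isnan(float(old)) and float(old) != val:
                    logger.warning(
                        "subject %s: covariate %s changes from %s to %s at row %d; keeping first",
                        sid, fld, old, val, row_idx,
                    )
        if int(evid) == 1:
            amt = _to_float(rec["AMT"], "AMT", row_idx)
            dur = _to_float(rec.get("DUR"), "DUR", row_idx)
            if dur is None:
                rate = _to_float(rec.get("RATE"), "RATE", row_idx)
                if rate is None or rate <= 0:
                    raise ValueError(f"row {row_idx}: dose needs DUR or RATE")
                dur = amt / rate
            events.append(Event(sid, time, "dose", amount=amt, infusion_duration=dur))
        else:
            dv = _to_float(rec["DV"], "DV", row_idx)
            label = rec.get("LABEL")
            label = label if isinstance(label, str) and label.strip() else None
            events.append(
                Event(
                    sid,
                    time,
                    "observation",
                    concentration=dv,
                    observation_label=label,
                    below_loq=bool(dv is not None and lloq > 0 and dv <= lloq),
                )
            )

    # event order is canonicalised by sorting, so any row permutation of the
    # same file reads to the identical dataset
    return PKDataset(subjects=subjects, events=events).sorted()


def validate_dataset(ds: PKDataset) -> list[Issue]:
    """Check every container invariant; returns one :class:`Issue` per violation."""
    issues: list[Issue] = []
    for sid, s in ds.subjects.items():
        if not (s.weight > 0):
            issues.append(Issue(sid, None, "weight must be > 0"))
        if not (s.scr > 0):
            issues.append(Issue(sid, None, "scr must be > 0"))
        if s.age is not None and s.age < 0:
            issues.append(Issue(sid, None, "age must be >= 0"))
        for flag in COTHERAPY_FLAGS:
            if getattr(s, flag) not in (0, 1):
                issues.append(Issue(sid, None, f"co-therapy flag {flag} must be 0/1"))
    seen_dose: dict[str, bool] = {}
    for i, e in enumerate(ds.events):
        if e.subject_id not in ds.subjects:
            issues.append(Issue(e.subject_id, i, "event references unknown subject"))
            continue
        if e.time < 0:
            issues.append(Issue(e.subject_id, i, "event time must be >= 0"))
        if e.kind == "dose":
            if e.amount is None or e.amount <= 0:
                issues.append(Issue(e.subject_id, i, "dose amount must be > 0"))
            if e.infusion_duration is None or e.infusion_duration < 0:
                issues.append(Issue(e.subject_id, i, "infusion duration must be >= 0"))
            seen_dose[e.subject_id] = True
        elif e.kind == "observation":
            if e.concentration is None or e.concentration <= 0:
                issues.append(Issue(e.subject_id, i, "observed concentration must be > 0"))
            if not seen_dose.get(e.subject_id):
                issues.append(Issue(e.subject_id, i, "observation precedes any dose"))
        else:
            issues.append(Issue(e.subject_id, i, f"unknown event kind {e.kind!r}"))
    return issues


def write_dataset(ds: PKDataset, path) -> None:
    """Write the CSV dialect read by :func:`read_dataset`.

    Numeric fields are written at full ``repr`` precision so a read/write
    round trip is bit-exact.  Covariate columns that are absent for every
    subject are omitted.
    """
    ds = ds.sorted()
    present_cov = [
        fld
        for fld in _FIELD_TO_COLUMN
        if any(getattr(s, fld) is not None for s in ds.subjects.values())
    ]
    has_label = any(e.observation_label for e in ds.events)
    cols = ["ID", "TIME", "AMT", "DUR", "DV", "EVID"]
    cols += [_FIELD_TO_COLUMN[f] for f in present_cov]
    if has_label:
        cols.append("LABEL")

    def fmt(x) -> str:
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return ""
        if isinstance(x, float):
            return repr(x)
        return str(x)

    lines = [",".join(cols)]
    for e in ds.events:
        s = ds.subjects[e.subject_id]
        row = [
            e.subject_id,
            fmt(float(e.time)),
            fmt(float(e.amount) if e.amount is not None else None),
            fmt(float(e.infusion_duration) if e.infusion_duration is not None else None),
            fmt(float(e.concentration) if e.concentration is not None else None),
            "1" if e.kind == "dose" else "0",
        ]
        for fld in present_cov:
            val = getattr(s, fld)
            if val is None:
                row.append("")
            elif fld == "sex":
                row.append(str(val))
            elif fld in COTHERAPY_FLAGS:
                row.append(str(int(val)))
            else:
                row.append(fmt(float(val)))
        if has_label:
            row.append(e.observation_label or "")
        lines.append(",".join(row))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
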