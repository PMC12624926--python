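"""Loaders and validators for the standardized metadata templates.

Seven templates feed the pipeline besides the operant files: Cohort
Information (one row per animal; the entry point of an RFID into the
system), Daily Issues (session-level experimenter observations with a
keep/discard decision), Exit (animals leaving the study, with the last good
session to retain), the three non-operant behavioral tests (Von Frey
nociception, tail-immersion analgesia, bottle-brush irritability) and the
Corrections Record (session workbooks needing reprocessing).

Templates are accepted as CSV or XLSX. Columns are located by header name
through the bundled manifests (case-insensitive, order-free); validation is
total — every cell either maps to a typed field or raises/logs a named
schema deviation. keep/discard decisions are stored as recorded; exclusion
is applied later, in :func:`operantdb.store.combine`, so the raw database
preserves everything.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, TemplateError
from .medpc_io import parse_session_token

logger = logging.getLogger(__name__)

ISSUE_CODES = ("disconnected", "tangled", "empty_syringe", "sick", "other")
EXIT_CODES = ("death", "brevital_fail", "other")
EXPERIMENT_GROUPS = ("drug", "saline", "sham", "naive")
DRUG_GROUPS = ("oxycodone", "cocaine")
DECISION_TYPES = ("objective", "subjective")

#: Numerical tolerance for re-checking stored averages/differences in the
#: behavioral-test templates.
CONSISTENCY_TOL = 1e-6


def _load_manifests() -> dict:
    with resources.files("operantdb").joinpath("manifests.yaml").open() as fh:
        return yaml.safe_load(fh)


_MANIFESTS = _load_manifests()


def _norm_header(h: str) -> str:
    return re.sub(r"[\s\-/]+", "_", str(h).strip().lower())


def _norm_enum(value: str) -> str:
    return re.sub(r"[\s\-]+", "_", str(value).strip().lower())


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df = pd.read_excel(path, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    df.columns = [_norm_header(c) for c in df.columns]
    return df


def _map_columns(df: pd.DataFrame, template: str,
                 mandatory: tuple[str, ...]) -> dict[str, str]:
    """Resolve canonical field → actual column using the header manifest."""
    manifest = _MANIFESTS[template]
    mapping: dict[str, str] = {}
    for fieldname, aliases in manifest.items():
        for alias in aliases:
            if _norm_header(alias) in df.columns:
                mapping[fieldname] = _norm_header(alias)
                break
    missing = [f for f in mandatory if f not in mapping]
    if missing:
        raise SchemaError(f"template {template!r}: missing mandatory "
                          f"column(s) {missing}")
    return mapping


def _parse_date(value, template, row, col) -> dt.date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) \
            or str(value).strip() == "":
        return None
    s = str(value).strip().split()[0]
    for fmt in ("%Y-%m-%d", "%m/%d/%Y", "%m/%d/%y"):
        try:
            return dt.datetime.strptime(s, fmt).date()
        except ValueError:
            continue
    raise TemplateError(f"{template} row {row} col {col!r}: unparseable date {value!r}")


def _enum(value, allowed, template, row, col):
    v = _norm_enum(value)
    if v not in allowed:
        raise TemplateError(f"{template} row {row} col {col!r}: {value!r} "
                            f"not in {allowed}")
    return v


def _blank(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) \
        or str(value).strip() in ("", "nan", "None")


# ---------------------------------------------------------------------------
# Cohort Information
# ---------------------------------------------------------------------------

@dataclass
class CohortInfoRow:
    """One animal's row of the Cohort Information template."""

    subject_id: str
    rfid: str
    sex: str
    cohort: str
    experiment_group: str
    drug_group: str
    date_of_birth: dt.date | None = None
    coat_color: str | None = None
    ear_marks: str | None = None
    parentage: str | None = None
    dissection_group: str | None = None
    technician_ids: str | None = None
    experiment_dates: dict[str, dt.date] = field(default_factory=dict)
    weekly_weights: list[tuple[dt.date, float]] = field(default_factory=list)
    patency_outcomes: list[tuple[dt.date, str]] = field(default_factory=list)


_COHORT_MANDATORY = ("subject_id", "rfid", "sex", "cohort",
                     "experiment_group", "drug_group")


def load_cohort_info(path) -> list[CohortInfoRow]:
    """Load and validate a Cohort Information file (CSV or XLSX).

    Experiment-stage dates are read from ``date_<stage>`` columns, weekly
    weights from ``weight_<i>_date`` / ``weight_<i>_g`` pairs and catheter
    patency outcomes from ``patency_<i>_date`` / ``patency_<i>_result``
    pairs. Duplicate RFIDs and unknown enum values raise.
    """
    df = _read_table(path)
    mapping = _map_columns(df, "cohort_info", _COHORT_MANDATORY)
    date_cols = [c for c in df.columns if c.startswith("date_")
                 and c != "date_of_birth"]
    weight_idx = sorted({m.group(1) for c in df.columns
                         for m in [re.match(r"weight_(\d+)_date$", c)] if m}, key=int)
    patency_idx = sorted({m.group(1) for c in df.columns
                          for m in [re.match(r"patency_(\d+)_date$", c)] if m}, key=int)

    rows: list[CohortInfoRow] = []
    seen_rfid: set[str] = set()
    for i, raw in df.iterrows():
        rownum = i + 2  # 1-based plus header
        rfid = str(raw[mapping["rfid"]]).strip()
        if _blank(rfid):
            raise TemplateError(f"cohort_info row {rownum}: empty RFID")
        if rfid in seen_rfid:
            raise TemplateError(f"cohort_info row {rownum}: duplicated RFID {rfid}")
        seen_rfid.add(rfid)
        row = CohortInfoRow(
            subject_id=str(raw[mapping["subject_id"]]).strip(),
            rfid=rfid,
            sex=_enum(raw[mapping["sex"]], ("m", "f"), "cohort_info", rownum,
                      "sex").upper(),
            cohort=str(raw[mapping["cohort"]]).strip(),
            experiment_group=_enum(raw[mapping["experiment_group"]],
                                   EXPERIMENT_GROUPS, "cohort_info", rownum,
                                   "experiment_group"),
            drug_group=_enum(raw[mapping["drug_group"]], DRUG_GROUPS,
                             "cohort_info", rownum, "drug_group"),
        )
        for attr in ("date_of_birth",):
            if attr in mapping and not _blank(raw[mapping[attr]]):
                row.date_of_birth = _parse_date(raw[mapping[attr]],
                                                "cohort_info", rownum, attr)
        for attr in ("coat_color", "ear_marks", "parentage",
                     "dissection_group", "technician_ids"):
            if attr in mapping and not _blank(raw[mapping[attr]]):
                setattr(row, attr, str(raw[mapping[attr]]).strip())
        for c in date_cols:
            if not _blank(raw[c]):
                row.experiment_dates[c.removeprefix("date_")] = \
                    _parse_date(raw[c], "cohort_info", rownum, c)
        for k in weight_idx:
            dcol, gcol = f"weight_{k}_date", f"weight_{k}_g"
            if gcol in df.columns and not _blank(raw[dcol]) and not _blank(raw[gcol]):
                grams = float(raw[gcol])
                if grams <= 0:
                    raise TemplateError(
                        f"cohort_info row {rownum} col {gcol!r}: weight must be positive")
                row.weekly_weights.append(
                    (_parse_date(raw[dcol], "cohort_info", rownum, dcol), grams))
        for k in patency_idx:
            dcol, rcol = f"patency_{k}_date", f"patency_{k}_result"
            if rcol in df.columns and not _blank(raw[dcol]) and not _blank(raw[rcol]):
                row.patency_outcomes.append(
                    (_parse_date(raw[dcol], "cohort_info", rownum, dcol),
                     _enum(raw[rcol], ("pass", "fail"), "cohort_info", rownum, rcol)))
        rows.append(row)
    return rows


def split_cohort_info(rows: list[CohortInfoRow]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split cohort rows into a subject table (one row per RFID, static
    fields) and a long-format measurement table (rfid, measurement_type,
    date, value, technician). The union of both reconstructs the input."""
    subj_records = []
    meas_records = []
    for r in rows:
        rec = {
            "rfid": r.rfid, "subject_id": r.subject_id, "sex": r.sex,
            "cohort": r.cohort, "experiment_group": r.experiment_group,
            "drug_group": r.drug_group,
            "date_of_birth": r.date_of_birth.isoformat() if r.date_of_birth else None,
            "coat_color": r.coat_color, "ear_marks": r.ear_marks,
            "parentage": r.parentage, "dissection_group": r.dissection_group,
            "technician_ids": r.technician_ids,
        }
        for stage, date in r.experiment_dates.items():
            rec[f"date_{stage}"] = date.isoformat()
        subj_records.append(rec)
        for date, grams in r.weekly_weights:
            meas_records.append({"rfid": r.rfid, "measurement_type": "weight",
                                 "date": date.isoformat(), "value": grams,
                                 "technician": r.technician_ids})
        for date, outcome in r.patency_outcomes:
            meas_records.append({"rfid": r.rfid, "measurement_type": "patency",
                                 "date": date.isoformat(), "value": outcome,
                                 "technician": r.technician_ids})
    subject = pd.DataFrame(subj_records)
    measurement = pd.DataFrame(
        meas_records, columns=["rfid", "measurement_type", "date", "value",
                               "technician"])
    return subject, measurement


# ---------------------------------------------------------------------------
# Daily Issues / Exit
# ---------------------------------------------------------------------------

@dataclass
class IssueRow:
    subject_id: str
    rfid: str
    date: dt.date | None
    session_id: str | None
    issue_code: str
    keep: bool
    decision_type: str
    notes: str | None = None


@dataclass
class ExitRow:
    subject_id: str
    rfid: str
    cohort: str
    exit_date: dt.date
    last_good_session: str | None
    exit_code: str
    decision_type: str
    behavioral_testing_status: str | None = None
    tissue_collection_status: str | None = None
    notes: str | None = None
    replaced: bool = False


_TRUTHY = {"true", "1", "yes", "y", "keep", "t"}
_FALSY = {"false", "0", "no", "n", "discard", "f"}


def _parse_bool(value, template, row, col) -> bool:
    v = _norm_enum(value)
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise TemplateError(f"{template} row {row} col {col!r}: {value!r} is not "
                        "a keep/discard or true/false value")


def load_issues(path) -> list[IssueRow]:
    """Load the Daily Issues template; issue codes come from the closed
    vocabulary {disconnected, tangled, empty_syringe, sick, other}."""
    df = _read_table(path)
    mapping = _map_columns(df, "issues",
                           ("rfid", "date", "issue_code", "keep", "decision_type"))
    rows = []
    for i, raw in df.iterrows():
        rownum = i + 2
        session_id = None
        if "session_id" in mapping and not _blank(raw[mapping["session_id"]]):
            token = str(raw[mapping["session_id"]]).strip()
            parse_session_token(token)  # raises FilenameError if malformed
            session_id = token.upper()
        rows.append(IssueRow(
            subject_id=str(raw[mapping["subject_id"]]).strip()
            if "subject_id" in mapping else "",
            rfid=str(raw[mapping["rfid"]]).strip(),
            date=_parse_date(raw[mapping["date"]], "issues", rownum, "date"),
            session_id=session_id,
            issue_code=_enum(raw[mapping["issue_code"]], ISSUE_CODES,
                             "issues", rownum, "issue_code"),
            keep=_parse_bool(raw[mapping["keep"]], "issues", rownum, "keep"),
            decision_type=_enum(raw[mapping["decision_type"]], DECISION_TYPES,
                                "issues", rownum, "decision_type"),
            notes=None if "notes" not in mapping or _blank(raw[mapping["notes"]])
            else str(raw[mapping["notes"]]).strip(),
        ))
    return rows


def load_exits(path) -> list[ExitRow]:
    """Load the Exit template; exit codes from {Death, Brevital_Fail, Other}."""
    df = _read_table(path)
    mapping = _map_columns(df, "exit",
                           ("rfid", "exit_date", "exit_code", "decision_type"))
    rows = []
    for i, raw in df.iterrows():
        rownum = i + 2
        last_good = None
        if "last_good_session" in mapping and not _blank(raw[mapping["last_good_session"]]):
            token = str(raw[mapping["last_good_session"]]).strip()
            parse_session_token(token)
            last_good = token.upper()
        rows.append(ExitRow(
            subject_id=str(raw[mapping["subject_id"]]).strip()
            if "subject_id" in mapping else "",
            rfid=str(raw[mapping["rfid"]]).strip(),
            cohort=str(raw[mapping["cohort"]]).strip() if "cohort" in mapping else "",
            exit_date=_parse_date(raw[mapping["exit_date"]], "exit", rownum,
                                  "exit_date"),
            last_good_session=last_good,
            exit_code=_enum(raw[mapping["exit_code"]], EXIT_CODES, "exit",
                            rownum, "exit_code"),
            decision_type=_enum(raw[mapping["decision_type"]], DECISION_TYPES,
                                "exit", rownum, "decision_type"),
            behavioral_testing_status=None
            if "behavioral_testing_status" not in mapping
            or _blank(raw[mapping["behavioral_testing_status"]])
            else str(raw[mapping["behavioral_testing_status"]]).strip(),
            tissue_collection_status=None
            if "tissue_collection_status" not in mapping
            or _blank(raw[mapping["tissue_collection_status"]])
            else str(raw[mapping["tissue_collection_status"]]).strip(),
            notes=None if "notes" not in mapping or _blank(raw[mapping["notes"]])
            else str(raw[mapping["notes"]]).strip(),
            replaced=_parse_bool(raw[mapping["replaced"]], "exit", rownum,
                                 "replaced")
            if "replaced" in mapping and not _blank(raw[mapping["replaced"]])
            else False,
        ))
    return rows


# ---------------------------------------------------------------------------
# Behavioral tests (Von Frey, tail immersion, irritability)
# ---------------------------------------------------------------------------

#: (inputs, stored aggregate) pairs recomputed and checked per test kind.
_VF_TIMEPOINTS = ("pre", "post")
_IRR_TIMEPOINTS = ("pre", "post")


def load_behavior_test(path, kind: str) -> pd.DataFrame:
    """Load a behavioral-test template and verify its stored aggregates.

    ``kind`` ∈ {"vonfrey", "tail_immersion", "irritability"}. Stored
    per-timepoint averages and timepoint differences are recomputed from
    their inputs; mismatches beyond 1e-6 are logged as validation warnings
    (both values reported) but the stored value is kept, since the template
    is the recorded source.
    """
    if kind not in ("vonfrey", "tail_immersion", "irritability"):
        raise ValueError(f"unknown behavior test kind {kind!r}")
    df = _read_table(path)
    if "rfid" not in df.columns:
        raise SchemaError(f"template {kind!r}: missing mandatory column ['rfid']")
    num_cols = [c for c in df.columns
                if c not in ("rfid", "subject_id", "cohort")]
    for c in num_cols:
        df[c] = pd.to_numeric(df[c], errors="raise")
    checks = _consistency_checks(kind, df.columns)
    for stored, inputs, op in checks:
        recomputed = _recompute(df, inputs, op)
        bad = (df[stored] - recomputed).abs() > CONSISTENCY_TOL
        for i in df.index[bad.fillna(False)]:
            logger.warning(
                "%s row %d: stored %s=%s but recomputed %s from %s",
                kind, i + 2, stored, df.at[i, stored], recomputed[i], inputs)
    measure_cols = [c for c in num_cols if "diff" not in c]
    if kind != "irritability":
        neg = df[measure_cols].lt(0).any(axis=None)
        if neg:
            raise TemplateError(f"{kind}: negative latency/force measurement")
    return df


def _recompute(df, inputs, op):
    if op == "mean":
        return df[list(inputs)].mean(axis=1)
    a, b = inputs
    return df[a] - df[b]


def _consistency_checks(kind, columns):
    checks = []
    if kind == "vonfrey":
        for tp in _VF_TIMEPOINTS:
            for meas in ("force", "latency"):
                stored = f"{meas}_avg_{tp}"
                inputs = (f"{meas}_left_{tp}", f"{meas}_right_{tp}")
                if stored in columns and all(c in columns for c in inputs):
                    checks.append((stored, inputs, "mean"))
        for meas in ("force", "latency"):
            stored = f"{meas}_diff"
            inputs = (f"{meas}_avg_post", f"{meas}_avg_pre")
            if stored in columns and all(c in columns for c in inputs):
                checks.append((stored, inputs, "diff"))
    elif kind == "tail_immersion":
        if {"latency_diff", "latency_postlga_drug", "latency_presha_drug"} <= set(columns):
            checks.append(("latency_diff",
                           ("latency_postlga_drug", "latency_presha_drug"), "diff"))
    else:  # irritability
        for tp in _IRR_TIMEPOINTS:
            for meas in ("aggressive", "defensive"):
                stored = f"{meas}_avg_{tp}"
                inputs = (f"{meas}_obs1_{tp}", f"{meas}_obs2_{tp}")
                if stored in columns and all(c in columns for c in inputs):
                    checks.append((stored, inputs, "mean"))
        for meas in ("aggressive", "defensive"):
            stored = f"{meas}_diff"
            inputs = (f"{meas}_avg_post", f"{meas}_avg_pre")
            if stored in columns and all(c in columns for c in inputs):
                checks.append((stored, inputs, "diff"))
    return checks


# ---------------------------------------------------------------------------
# Corrections Record
# ---------------------------------------------------------------------------

class CorrectionRecord:
    """CSV of session-workbook filenames needing reprocessing, one per line.

    The convert stage rereads every listed file and clears the record only
    after all succeed; a partial failure leaves the record intact.
    """

    def __init__(self, path):
        self.path = Path(path)

    def load(self) -> list[str]:
        if not self.path.exists():
            return []
        return [ln.strip() for ln in self.path.read_text().splitlines()
                if ln.strip()]

    def append(self, filename: str) -> None:
        entries = self.load()
        if filename not in entries:
            entries.append(filename)
        self.path.write_text("\n".join(entries) + ("\n" if entries else ""))

    def clear(self) -> None:
        self.path.write_text("")


__all__ = [
    "CohortInfoRow", "IssueRow", "ExitRow", "CorrectionRecord",
    "ISSUE_CODES", "EXIT_CODES", "EXPERIMENT_GROUPS", "DRUG_GROUPS",
    "load_cohort_info", "split_cohort_info", "load_issues", "load_exits",
    "load_behavior_test",
]
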