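"""Embedded relational store: raw tables, the exclusion-joined combined
table, and CSV backups.

The store is a single SQLite file (or ``:memory:``) holding one operant
table per session type (SHA, LGA, PR, SHOCK; one row per rat-session — the
transposed form of the session workbook), the subject and measurement tables
split out of the Cohort Information template, the issue/exit tables, and the
three behavioral-test tables. RFID is the primary key connecting everything.

Ingest is idempotent: operant rows are keyed by their source filename, so
re-ingesting a (possibly corrected) workbook replaces its rows instead of
duplicating them. Exclusions are applied only at :func:`combine` time —
the raw database preserves every recorded observation.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import sqlite3
from pathlib import Path

import pandas as pd

from .errors import StoreError
from .medpc_io import (SESSION_TYPES, SessionMeta, SessionRecord,
                       session_sort_key, session_token)
from .templates_io import (CohortInfoRow, ExitRow, IssueRow,
                           split_cohort_info)

logger = logging.getLogger(__name__)

_OPERANT_COLUMNS = [
    "rfid", "subject_id", "cohort", "drug", "location", "computer",
    "session_type", "session_index", "session_token", "session_date",
    "start_time", "end_time", "box", "program",
    "total_infusions", "total_active", "total_inactive",
    "breakpoint", "total_shocks", "infusions_after_shock",
    "infusion_ts", "active_ts", "inactive_ts", "timeout_ts",
    "source_file",
]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS subject (
    rfid TEXT PRIMARY KEY, subject_id TEXT, sex TEXT, cohort TEXT,
    experiment_group TEXT, drug_group TEXT, date_of_birth TEXT,
    coat_color TEXT, ear_marks TEXT, parentage TEXT, dissection_group TEXT,
    technician_ids TEXT, experiment_dates TEXT);
CREATE TABLE IF NOT EXISTS measurement (
    rfid TEXT, measurement_type TEXT, date TEXT, value TEXT, technician TEXT);
CREATE TABLE IF NOT EXISTS issue (
    rfid TEXT, subject_id TEXT, date TEXT, session_id TEXT, issue_code TEXT,
    keep INTEGER, decision_type TEXT, notes TEXT);
CREATE TABLE IF NOT EXISTS exit (
    rfid TEXT, subject_id TEXT, cohort TEXT, exit_date TEXT,
    last_good_session TEXT, exit_code TEXT, decision_type TEXT,
    behavioral_testing_status TEXT, tissue_collection_status TEXT,
    notes TEXT, replaced INTEGER);
CREATE TABLE IF NOT EXISTS quarantine (
    subject_id TEXT, session_token TEXT, source_file TEXT, reason TEXT,
    payload TEXT);
CREATE TABLE IF NOT EXISTS exclusion_log (
    rfid TEXT, session_type TEXT, session_token TEXT, reason TEXT,
    detail TEXT);
"""

_BEHAVIOR_TABLES = {"vonfrey": "vonfrey", "tail_immersion": "tail_immersion",
                    "irritability": "irritability"}


def serialize_list(values) -> str:
    """Space-delimited numeral serialization used for timestamp-array cells."""
    return " ".join(f"{v:.3f}" for v in values)


def deserialize_list(cell) -> list[float]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return []
    return [float(v) for v in str(cell).split()]


class RawDatabase:
    """The raw relational store (local stand-in for the cloud SQL tier)."""

    def __init__(self, path=":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.executescript(_SCHEMA)
        for stype in SESSION_TYPES:
            cols = ", ".join(f'"{c}"' for c in _OPERANT_COLUMNS)
            self.conn.execute(
                f'CREATE TABLE IF NOT EXISTS operant_{stype.lower()} '
                f'({cols}, UNIQUE (rfid, session_token))')
        self.conn.commit()

    def close(self):
        self.conn.close()

    # -- template ingest ----------------------------------------------------

    def ingest_cohort_info(self, rows: list[CohortInfoRow]) -> None:
        subject, measurement = split_cohort_info(rows)
        # experiment dates fold into one JSON column; the long-format
        # measurement table carries weights and patency outcomes
        date_cols = [c for c in subject.columns if c.startswith("date_")
                     and c != "date_of_birth"]
        base_cols = [c for c in subject.columns if c not in date_cols]
        folded = subject[base_cols].copy()
        folded["experiment_dates"] = [
            json.dumps({c.removeprefix("date_"): subject.at[i, c]
                        for c in date_cols if pd.notna(subject.at[i, c])})
            for i in subject.index]
        for _, row in folded.iterrows():
            self.conn.execute(
                "INSERT OR REPLACE INTO subject VALUES "
                "(:rfid, :subject_id, :sex, :cohort, :experiment_group, "
                ":drug_group, :date_of_birth, :coat_color, :ear_marks, "
                ":parentage, :dissection_group, :technician_ids, "
                ":experiment_dates)", row.to_dict())
        rfids = tuple(folded["rfid"])
        self.conn.execute(
            f"DELETE FROM measurement WHERE rfid IN "
            f"({','.join('?' * len(rfids))})", rfids)
        measurement.to_sql("measurement", self.conn, if_exists="append",
                           index=False)
        self.conn.commit()

    def ingest_issues(self, rows: list[IssueRow]) -> None:
        self.conn.execute("DELETE FROM issue")
        self.conn.executemany(
            "INSERT INTO issue VALUES (?,?,?,?,?,?,?,?)",
            [(r.rfid, r.subject_id, r.date.isoformat() if r.date else None,
              r.session_id, r.issue_code, int(r.keep), r.decision_type,
              r.notes) for r in rows])
        self.conn.commit()

    def ingest_exits(self, rows: list[ExitRow]) -> None:
        self.conn.execute("DELETE FROM exit")
        self.conn.executemany(
            "INSERT INTO exit VALUES (?,?,?,?,?,?,?,?,?,?,?)",
            [(r.rfid, r.subject_id, r.cohort,
              r.exit_date.isoformat() if r.exit_date else None,
              r.last_good_session, r.exit_code, r.decision_type,
              r.behavioral_testing_status, r.tissue_collection_status,
              r.notes, int(r.replaced)) for r in rows])
        self.conn.commit()

    def ingest_behavior_test(self, df: pd.DataFrame, kind: str) -> None:
        table = _BEHAVIOR_TABLES[kind]
        df.to_sql(table, self.conn, if_exists="replace", index=False)
        self.conn.commit()

    # -- operant ingest -----------------------------------------------------

    def ingest_session(self, records: list[SessionRecord],
                       meta: SessionMeta) -> int:
        """Ingest one converted session (one computer's records).

        Rows are keyed by source file: previously ingested rows from the
        same file are replaced, making re-ingest after a correction
        idempotent. Records whose subject has no RFID in the subject table
        are quarantined with a referential warning. Returns the number of
        rows stored.
        """
        table = f"operant_{meta.session_type.lower()}"
        # subject_id -> rfid lookup scoped to the cohort
        lookup = {sid: rfid for sid, rfid in self.conn.execute(
            "SELECT subject_id, rfid FROM subject WHERE cohort = ?",
            (meta.cohort,))}
        source = records[0].source_file if records else None
        if source:
            self.conn.execute(f"DELETE FROM {table} WHERE source_file = ?",
                              (source,))
            self.conn.execute("DELETE FROM quarantine WHERE source_file = ?",
                              (source,))
        stored = 0
        for rec in records:
            rfid = lookup.get(rec.subject_id)
            if rfid is None:
                logger.warning("referential orphan: subject %r (%s) has no "
                               "RFID in cohort %s; quarantined",
                               rec.subject_id, rec.source_file, meta.cohort)
                self.conn.execute(
                    "INSERT INTO quarantine VALUES (?,?,?,?,?)",
                    (rec.subject_id, meta.session_token, rec.source_file,
                     "no subject with this ID in cohort",
                     json.dumps({"total_infusions": rec.total_infusions})))
                continue
            row = {
                "rfid": rfid, "subject_id": rec.subject_id,
                "cohort": meta.cohort, "drug": meta.drug,
                "location": meta.location, "computer": meta.computer,
                "session_type": meta.session_type,
                "session_index": meta.session_index,
                "session_token": meta.session_token,
                "session_date": rec.start_datetime.date().isoformat(),
                "start_time": rec.start_datetime.time().isoformat(),
                "end_time": rec.end_datetime.time().isoformat(),
                "box": rec.box, "program": rec.program,
                "total_infusions": rec.total_infusions,
                "total_active": rec.total_active,
                "total_inactive": rec.total_inactive,
                "breakpoint": rec.breakpoint,
                "total_shocks": rec.total_shocks,
                "infusions_after_shock": rec.infusions_after_shock,
                "infusion_ts": serialize_list(rec.infusion_ts),
                "active_ts": serialize_list(rec.active_ts),
                "inactive_ts": serialize_list(rec.inactive_ts),
                "timeout_ts": serialize_list(rec.timeout_ts),
                "source_file": rec.source_file,
            }
            placeholders = ", ".join(f":{c}" for c in _OPERANT_COLUMNS)
            self.conn.execute(
                f"INSERT OR REPLACE INTO {table} VALUES ({placeholders})", row)
            stored += 1
        self.conn.commit()
        return stored

    # -- table access -------------------------------------------------------

    def table(self, name: str) -> pd.DataFrame:
        return pd.read_sql_query(f"SELECT * FROM {name}", self.conn)

    def operant(self, session_type: str | None = None) -> pd.DataFrame:
        """All operant rows (optionally one session type) as one frame."""
        types = [session_type] if session_type else SESSION_TYPES
        frames = [self.table(f"operant_{t.lower()}") for t in types]
        return pd.concat(frames, ignore_index=True)

    def table_names(self) -> list[str]:
        rows = self.conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table'").fetchall()
        return sorted(r[0] for r in rows)


# ---------------------------------------------------------------------------
# Combination (exclusion join)
# ---------------------------------------------------------------------------

def _order_key(row) -> tuple:
    """Chronology by recorded session date when available, token order as
    tie-break/fallback — dates are ground truth."""
    date = row["session_date"] if isinstance(row, dict) else row.session_date
    token = row["session_token"] if isinstance(row, dict) else row.session_token
    tok = session_sort_key(token)
    if date:
        return (0, str(date), tok)
    return (1, "", tok)


def combine(db: RawDatabase) -> pd.DataFrame:
    """Join operant rows with subject fields on RFID into the single unified
    table, excluding rows discarded in the Daily Issues file and rows after
    the animal's last good session in the Exit file.

    Removals are written to the ``exclusion_log`` table with their reason.
    """
    operant = db.operant()
    subject = db.table("subject")
    issues = db.table("issue")
    exits = db.table("exit")

    combined = operant.merge(
        subject[["rfid", "sex", "cohort", "drug_group", "experiment_group"]],
        on="rfid", how="inner", suffixes=("", "_subject"))

    discard = issues[issues["keep"] == 0]
    exclusions: list[dict] = []
    keep_mask = []
    exit_by_rfid = {r.rfid: r for r in exits.itertuples()}
    for row in combined.itertuples():
        reason = None
        for iss in discard.itertuples():
            if iss.rfid != row.rfid:
                continue
            # session token precedence; date is the fallback key
            if iss.session_id:
                if iss.session_id == row.session_token:
                    reason = f"issue:{iss.issue_code}"
                    break
            elif iss.date and iss.date == row.session_date:
                reason = f"issue:{iss.issue_code}"
                break
        if reason is None and row.rfid in exit_by_rfid:
            ex = exit_by_rfid[row.rfid]
            if ex.last_good_session:
                last_row = combined[(combined["rfid"] == row.rfid) &
                                    (combined["session_token"] == ex.last_good_session)]
                if len(last_row):
                    last_key = _order_key(last_row.iloc[0].to_dict())
                else:  # last good session has no stored row; token order only
                    last_key = (1, "", session_sort_key(ex.last_good_session))
                if _order_key(row) > last_key:
                    reason = f"exit:{ex.exit_code}:after {ex.last_good_session}"
            elif ex.exit_date and str(row.session_date) > str(ex.exit_date):
                reason = f"exit:{ex.exit_code}:after exit date {ex.exit_date}"
        if reason is None:
            keep_mask.append(True)
        else:
            keep_mask.append(False)
            exclusions.append({"rfid": row.rfid,
                               "session_type": row.session_type,
                               "session_token": row.session_token,
                               "reason": reason.split(":")[0],
                               "detail": reason})
            logger.info("excluded %s %s: %s", row.rfid, row.session_token,
                        reason)

    db.conn.execute("DELETE FROM exclusion_log")
    if exclusions:
        pd.DataFrame(exclusions).to_sql("exclusion_log", db.conn,
                                        if_exists="append", index=False)
    db.conn.commit()

    kept = combined[pd.Series(keep_mask, index=combined.index)].copy()
    # annotate kept rows that carry a keep=True issue note
    notes = {}
    for iss in issues[issues["keep"] == 1].itertuples():
        key = (iss.rfid, iss.session_id)
        notes[key] = iss.issue_code
    kept["issue_annotation"] = [
        notes.get((r.rfid, r.session_token)) for r in kept.itertuples()]
    kept["excluded_reason"] = None
    return kept.reset_index(drop=True)


# ---------------------------------------------------------------------------
# CSV backup
# ---------------------------------------------------------------------------

def export_backup(db: RawDatabase, outdir, *,
                  combined: pd.DataFrame | None = None) -> list[Path]:
    """Write every table (and optionally the combined table) as CSV.

    UTF-8, comma-separated, RFC-4180 quoting; timestamp-array cells stay in
    their space-delimited serialization, so re-import reproduces tables
    exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in db.table_names():
        path = outdir / f"{name}.csv"
        db.table(name).to_csv(path, index=False)
        written.append(path)
    if combined is not None:
        path = outdir / "combined.csv"
        combined.to_csv(path, index=False)
        written.append(path)
    return written


def import_backup(backup_dir, path=":memory:") -> RawDatabase:
    """Rebuild a :class:`RawDatabase` from an :func:`export_backup` tree."""
    backup_dir = Path(backup_dir)
    db = RawDatabase(path)
    for csv_path in sorted(backup_dir.glob("*.csv")):
        name = csv_path.stem
        if name == "combined":
            continue
        df = pd.read_csv(csv_path, dtype=_backup_dtypes(db, name))
        if name in db.table_names():
            db.conn.execute(f"DELETE FROM {name}")
            if len(df):
                df.to_sql(name, db.conn, if_exists="append", index=False)
        else:  # behavior-test tables exist only once ingested
            df.to_sql(name, db.conn, if_exists="replace", index=False)
    db.conn.commit()
    return db


def _backup_dtypes(db: RawDatabase, name: str) -> dict:
    info = db.conn.execute(f"PRAGMA table_info({name})").fetchall()
    return {row[1]: str for row in info if row[2] == "TEXT"}


__all__ = ["RawDatabase", "combine", "export_backup", "import_backup",
           "serialize_list", "deserialize_list", "session_token"]
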