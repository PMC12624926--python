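"""MedPC raw-file and session-workbook I/O.

MedPC (Med Associates) writes one TXT file per computer per session, holding
up to 16 box blocks. Each block is a header (subject, box, dates, times, MSN
program) followed by letter-coded variables: scalars such as total counts and
fixed-size zero-padded arrays such as event timestamps. The letter→meaning
assignment is program-specific, so it is supplied as a :class:`VariableMap`.

This module also owns the session filename grammar
(``<LOCATION><COMPUTER>_<COHORT>_<DRUG>_<SESSIONID>.txt``, e.g.
``MTF134A_C01_OXY_LGA10.txt``) and the per-computer session workbook: one
column per rat, fixed variable rows, written as XLSX with an identical CSV
twin.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import openpyxl

from .errors import FilenameError, MedPCParseError, SchemaError

logger = logging.getLogger(__name__)

SESSION_TYPES = ("SHA", "LGA", "PR", "SHOCK")
#: Phase order used when session dates are unavailable: short access, long
#: access, then progressive ratio / shock testing.
PHASE_ORDER = {t: i for i, t in enumerate(SESSION_TYPES)}
DRUGS = ("OXY", "COC")
COMPUTERS = "ABCDE"

SCALAR_ROLES = (
    "total_infusions",
    "total_active",
    "total_inactive",
    "breakpoint",
    "total_shocks",
    "infusions_after_shock",
)
ARRAY_ROLES = (
    "infusion_timestamps",
    "active_timestamps",
    "inactive_timestamps",
    "timeout_timestamps",
    "infusion_bins_5min",
)

#: Which count scalar is the source of truth for each timestamp array's
#: length (used to undo MedPC's trailing-zero padding).
_COUNT_FOR_ARRAY = {
    "infusion_timestamps": "total_infusions",
    "active_timestamps": "total_active",
    "inactive_timestamps": "total_inactive",
}


@dataclass(frozen=True)
class VariableMap:
    """Letter→role assignment for one MedPC program family.

    ``timestamp_unit`` is seconds per array tick (1.0 for programs that log
    real seconds; 0.01 for centisecond-tick dialects).
    """

    scalar_roles: dict[str, str] = field(default_factory=dict)
    array_roles: dict[str, str] = field(default_factory=dict)
    timestamp_unit: float = 1.0

    def __post_init__(self):
        if self.timestamp_unit <= 0:
            raise ValueError("timestamp_unit must be > 0")
        letters = list(self.scalar_roles) + list(self.array_roles)
        if len(letters) != len(set(letters)):
            raise ValueError("a letter maps to two roles in the VariableMap")
        for roles, allowed in ((self.scalar_roles, SCALAR_ROLES),
                               (self.array_roles, ARRAY_ROLES)):
            seen = set()
            for letter, role in roles.items():
                if role not in allowed:
                    raise ValueError(f"unknown role {role!r} for letter {letter!r}")
                if role in seen:
                    raise ValueError(f"role {role!r} mapped to two letters")
                seen.add(role)

    @property
    def letters(self) -> set[str]:
        return set(self.scalar_roles) | set(self.array_roles)


#: Default assignment: B counts active lever presses, W holds drug infusions
#: per 5-min bin, Y holds active-press timestamps; the remaining letters are
#: this package's canonical choices and can be overridden per MSN in config.
DEFAULT_VARIABLE_MAP = VariableMap(
    scalar_roles={
        "F": "total_infusions",
        "B": "total_active",
        "N": "total_inactive",
        "K": "breakpoint",
        "H": "total_shocks",
        "I": "infusions_after_shock",
    },
    array_roles={
        "G": "infusion_timestamps",
        "Y": "active_timestamps",
        "Z": "inactive_timestamps",
        "U": "timeout_timestamps",
        "W": "infusion_bins_5min",
    },
    timestamp_unit=1.0,
)


# ---------------------------------------------------------------------------
# Session metadata / filename grammar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionMeta:
    """Metadata encoded in a raw/output filename."""

    location: str
    computer: str
    cohort: str
    drug: str
    session_type: str
    session_index: int

    def __post_init__(self):
        if self.computer not in COMPUTERS:
            raise FilenameError(self.computer, "computer", "must be a single letter A-E")
        if not re.fullmatch(r"C\d{2}", self.cohort):
            raise FilenameError(self.cohort, "cohort", "must match C01-C50 pattern (C + 2 digits)")
        if self.drug not in DRUGS:
            raise FilenameError(self.drug, "drug", f"must be one of {DRUGS}")
        if self.session_type not in SESSION_TYPES:
            raise FilenameError(self.session_type, "session_type", f"must be one of {SESSION_TYPES}")
        if not 1 <= self.session_index <= 99:
            raise FilenameError(str(self.session_index), "session_index", "must be in 1..99")

    @property
    def session_token(self) -> str:
        return session_token(self.session_type, self.session_index)


def session_token(session_type: str, session_index: int) -> str:
    """Compose a session ID token, e.g. ``('LGA', 10) -> 'LGA10'``."""
    if session_type not in SESSION_TYPES:
        raise ValueError(f"unknown session type {session_type!r}")
    if not 1 <= session_index <= 99:
        raise ValueError("session index must be in 1..99")
    return f"{session_type}{session_index:02d}"


_TOKEN_RE = re.compile(r"(?P<type>SHA|LGA|PR|SHOCK)(?P<index>\d{2})$")


def parse_session_token(token: str) -> tuple[str, int]:
    """Split ``'LGA10'`` into ``('LGA', 10)``; raises FilenameError."""
    m = _TOKEN_RE.fullmatch(token.strip().upper())
    if not m:
        raise FilenameError(token, "session_id",
                            "expected type token SHA|LGA|PR|SHOCK + 2-digit index")
    idx = int(m.group("index"))
    if idx < 1:
        raise FilenameError(token, "session_index", "index must be >= 1")
    return m.group("type"), idx


def session_sort_key(token: str) -> tuple[int, int]:
    """Total order on session tokens: phase order SHA→LGA→PR→SHOCK, then index."""
    stype, idx = parse_session_token(token)
    return (PHASE_ORDER[stype], idx)


_EXTENSIONS = (".txt", ".xlsx", ".csv")


def parse_session_filename(name: str) -> SessionMeta:
    """Parse a session filename into :class:`SessionMeta`.

    Accepts the bare stem or any of the pipeline extensions (.txt, .xlsx,
    .csv). On failure raises :class:`FilenameError` naming the grammar
    element that failed, which feeds the gap diagnostics.
    """
    stem = name
    for ext in _EXTENSIONS:
        if stem.lower().endswith(ext):
            stem = stem[: -len(ext)]
            break
    parts = stem.split("_")
    if len(parts) != 4:
        raise FilenameError(name, "structure",
                            "expected 4 underscore-separated fields "
                            "<LOCATION><COMPUTER>_<COHORT>_<DRUG>_<SESSIONID>")
    loccomp, cohort, drug, sessid = parts
    if len(loccomp) < 2:
        raise FilenameError(name, "location", "location+computer field too short")
    location, computer = loccomp[:-1], loccomp[-1]
    if computer not in COMPUTERS:
        raise FilenameError(name, "computer", f"{computer!r} is not one of A-E")
    if not re.fullmatch(r"C\d{2}", cohort):
        raise FilenameError(name, "cohort", f"{cohort!r} does not match C + 2-digit index")
    if drug not in DRUGS:
        raise FilenameError(name, "drug", f"{drug!r} is not one of {DRUGS}")
    try:
        stype, idx = parse_session_token(sessid)
    except FilenameError as exc:
        raise FilenameError(name, exc.element, str(exc)) from None
    return SessionMeta(location=location, computer=computer, cohort=cohort,
                       drug=drug, session_type=stype, session_index=idx)


def compose_session_filename(meta: SessionMeta, ext: str = ".txt") -> str:
    """Inverse of :func:`parse_session_filename`."""
    return (f"{meta.location}{meta.computer}_{meta.cohort}_{meta.drug}_"
            f"{meta.session_token}{ext}")


# ---------------------------------------------------------------------------
# Session records
# ---------------------------------------------------------------------------

@dataclass
class SessionRecord:
    """One animal × one operant session, as extracted from a raw file."""

    subject_id: str
    box: int
    program: str
    start_datetime: dt.datetime
    end_datetime: dt.datetime
    total_infusions: int = 0
    total_active: int = 0
    total_inactive: int = 0
    infusion_ts: list[float] = field(default_factory=list)
    active_ts: list[float] = field(default_factory=list)
    inactive_ts: list[float] = field(default_factory=list)
    timeout_ts: list[float] = field(default_factory=list)
    infusion_bins_5min: list[int] | None = None
    breakpoint: int | None = None
    total_shocks: int | None = None
    infusions_after_shock: int | None = None
    source_file: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return (self.end_datetime - self.start_datetime).total_seconds()

    def validate(self, *, check_counts: bool = True, tolerance: float = 1.0) -> None:
        if self.box < 1:
            raise ValueError(f"{self.subject_id}: box must be positive")
        for name in ("infusion_ts", "active_ts", "inactive_ts", "timeout_ts"):
            ts = getattr(self, name)
            if any(b < a for a, b in zip(ts, ts[1:])):
                raise ValueError(f"{self.subject_id}: {name} not non-decreasing")
            if ts and (ts[0] < 0 or ts[-1] > self.duration_s + tolerance):
                raise ValueError(
                    f"{self.subject_id}: {name} outside [0, session duration]")
        if check_counts:
            for count, arr in (("total_infusions", self.infusion_ts),
                               ("total_active", self.active_ts),
                               ("total_inactive", self.inactive_ts)):
                n = getattr(self, count)
                if n < 0:
                    raise ValueError(f"{self.subject_id}: {count} negative")
                if arr and n != len(arr):
                    raise ValueError(
                        f"{self.subject_id}: {count}={n} != len({len(arr)}) of its array")
        if self.infusion_bins_5min is not None and self.infusion_ts:
            if sum(self.infusion_bins_5min) != self.total_infusions:
                raise ValueError(
                    f"{self.subject_id}: 5-min bins sum to "
                    f"{sum(self.infusion_bins_5min)} != total_infusions {self.total_infusions}")


# ---------------------------------------------------------------------------
# Raw-file parsing
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("Start Date", "End Date", "Subject", "Box", "Start Time",
                "End Time", "MSN")
_SCALAR_RE = re.compile(r"^([A-Z]):\s+(-?\d+(?:\.\d+)?)\s*$")
_ARRAY_START_RE = re.compile(r"^([A-Z]):\s*$")
_ARRAY_ROW_RE = re.compile(r"^\s+(\d+):((?:\s+-?\d+(?:\.\d+)?)+)\s*$")


def _parse_date(value: str, path, line):
    for fmt in ("%m/%d/%y", "%m/%d/%Y", "%Y-%m-%d"):
        try:
            return dt.datetime.strptime(value, fmt).date()
        except ValueError:
            continue
    raise MedPCParseError(f"unparseable date {value!r}", path, line)


def _parse_time(value: str, path, line):
    for fmt in ("%H:%M:%S", "%H:%M"):
        try:
            return dt.datetime.strptime(value, fmt).time()
        except ValueError:
            continue
    raise MedPCParseError(f"unparseable time {value!r}", path, line)


def _strip_padding(values: list[float], expected: int | None) -> list[float]:
    """Undo MedPC fixed-size zero padding.

    Trailing 0.0 fill values after the last real event are dropped; when the
    count implies one more event than survives stripping, a single 0.0 is
    kept to represent an event at t=0 (counts are the source of truth).
    """
    out = list(values)
    while out and out[-1] == 0.0:
        out.pop()
    # an all-zero padded array with count 1 encodes a single event at t=0;
    # any other leading 0.0 survives because only the tail is stripped
    if not out and expected == 1 and values:
        out = [0.0]
    return out


def parse_raw_file(path, vmap: VariableMap = DEFAULT_VARIABLE_MAP,
                   *, validate: bool = True) -> list[SessionRecord]:
    """Parse one MedPC raw TXT file into a list of :class:`SessionRecord`.

    One record per box block, in file order. Timestamps are converted to
    seconds from session start with ``vmap.timestamp_unit``. Letters not in
    the map are retained verbatim in ``record.extras`` with a warning.
    Duplicate subjects within one file raise (mis-configured chambers).
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    # Block boundaries: each box block starts at a "Start Date:" line.
    starts = [i for i, ln in enumerate(lines) if ln.startswith("Start Date:")]
    if not starts:
        raise MedPCParseError("no 'Start Date:' block found", path, 1)
    records: list[SessionRecord] = []
    seen_subjects: set[str] = set()
    for bi, start in enumerate(starts):
        end = starts[bi + 1] if bi + 1 < len(starts) else len(lines)
        rec = _parse_block(lines, start, end, vmap, path)
        if rec.subject_id in seen_subjects:
            raise MedPCParseError(
                f"duplicate subject {rec.subject_id!r} in one file "
                "(mis-configured chambers?)", path, start + 1)
        seen_subjects.add(rec.subject_id)
        if validate:
            rec.validate()
        records.append(rec)
    return records


def _parse_block(lines, start, end, vmap, path) -> SessionRecord:
    header: dict[str, str] = {}
    i = start
    # header lines "Key: value" until the first single-letter variable line
    while i < end:
        ln = lines[i]
        if not ln.strip():
            i += 1
            continue
        if _SCALAR_RE.match(ln) or _ARRAY_START_RE.match(ln):
            break
        if ":" not in ln:
            raise MedPCParseError(f"malformed header line {ln!r}", path, i + 1)
        key, _, value = ln.partition(":")
        header[key.strip()] = value.strip()
        i += 1
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise MedPCParseError(f"header missing {missing}", path, start + 1)

    scalars: dict[str, float] = {}
    arrays: dict[str, list[float]] = {}
    extras: dict[str, object] = {}
    while i < end:
        ln = lines[i]
        if not ln.strip():
            i += 1
            continue
        m = _SCALAR_RE.match(ln)
        if m:
            scalars[m.group(1)] = float(m.group(2))
            i += 1
            continue
        m = _ARRAY_START_RE.match(ln)
        if m:
            letter = m.group(1)
            values: list[float] = []
            i += 1
            while i < end:
                row = _ARRAY_ROW_RE.match(lines[i])
                if not row:
                    break
                idx = int(row.group(1))
                if idx != len(values):
                    raise MedPCParseError(
                        f"array {letter}: row index {idx} != expected {len(values)}",
                        path, i + 1)
                values.extend(float(v) for v in row.group(2).split())
                i += 1
            arrays[letter] = values
            continue
        raise MedPCParseError(f"unrecognized line {ln!r}", path, i + 1)

    start_dt = dt.datetime.combine(
        _parse_date(header["Start Date"], path, start + 1),
        _parse_time(header["Start Time"], path, start + 1))
    end_dt = dt.datetime.combine(
        _parse_date(header["End Date"], path, start + 1),
        _parse_time(header["End Time"], path, start + 1))
    try:
        box = int(float(header["Box"]))
    except ValueError:
        raise MedPCParseError(f"bad Box value {header['Box']!r}", path, start + 1)

    rec = SessionRecord(
        subject_id=header["Subject"], box=box, program=header["MSN"],
        start_datetime=start_dt, end_datetime=end_dt,
        source_file=path.name)

    for letter, value in scalars.items():
        role = vmap.scalar_roles.get(letter)
        if role is None:
            logger.warning("%s: unknown scalar letter %r retained in extras",
                           path.name, letter)
            extras[letter] = value
            continue
        setattr(rec, role, int(round(value)))

    role_by_field = {"infusion_timestamps": "infusion_ts",
                     "active_timestamps": "active_ts",
                     "inactive_timestamps": "inactive_ts",
                     "timeout_timestamps": "timeout_ts"}
    for letter, values in arrays.items():
        role = vmap.array_roles.get(letter)
        if role is None:
            logger.warning("%s: unknown array letter %r retained in extras",
                           path.name, letter)
            extras[letter] = values
            continue
        if role == "infusion_bins_5min":
            bins = [int(round(v)) for v in values]
            # bins are genuine zeros, only strip the fixed-size tail beyond
            # the session's 5-min bin count
            n_bins = int(np.ceil((end_dt - start_dt).total_seconds() / 300)) or 1
            rec.infusion_bins_5min = bins[:n_bins] if len(bins) > n_bins else bins
            continue
        count_role = _COUNT_FOR_ARRAY.get(role)
        expected = scalars.get(_letter_for(vmap, count_role)) if count_role else None
        expected = int(round(expected)) if expected is not None else None
        ts = _strip_padding(values, expected)
        setattr(rec, role_by_field[role], [t * vmap.timestamp_unit for t in ts])

    # counts default to array lengths when the scalar letter is absent
    for count_attr, arr_attr in (("total_infusions", "infusion_ts"),
                                 ("total_active", "active_ts"),
                                 ("total_inactive", "inactive_ts")):
        if _letter_for(vmap, count_attr) not in scalars:
            setattr(rec, count_attr, len(getattr(rec, arr_attr)))
    rec.extras = extras
    return rec


def _letter_for(vmap: VariableMap, role: str | None) -> str | None:
    if role is None:
        return None
    for letter, r in vmap.scalar_roles.items():
        if r == role:
            return letter
    return None


# ---------------------------------------------------------------------------
# Raw-file writing (shared dialect contract with the synthetic generator)
# ---------------------------------------------------------------------------

def write_raw_file(records: list[SessionRecord], path,
                   vmap: VariableMap = DEFAULT_VARIABLE_MAP,
                   *, pad_multiple: int = 5) -> Path:
    """Write records in the MedPC dialect (inverse of :func:`parse_raw_file`).

    Arrays are zero-padded to a multiple of ``pad_multiple`` values to mimic
    MedPC's fixed-size arrays, exercising the parser's padding stripper.
    """
    path = Path(path)
    chunks: list[str] = []
    for rec in records:
        chunks.append(_format_block(rec, vmap, pad_multiple))
    path.write_text("\n".join(chunks))
    return path


def _fmt_array(values, pad_multiple) -> str:
    vals = list(values)
    if pad_multiple > 1:
        target = max(pad_multiple,
                     int(np.ceil(len(vals) / pad_multiple)) * pad_multiple)
        vals = vals + [0.0] * (target - len(vals))
    rows = []
    for i in range(0, len(vals), 5):
        row = "".join(f"{v:13.3f}" for v in vals[i:i + 5])
        rows.append(f"{i:6d}:{row}")
    return "\n".join(rows)


def _format_block(rec: SessionRecord, vmap: VariableMap, pad_multiple: int) -> str:
    out = [
        "",
        f"Start Date: {rec.start_datetime.strftime('%m/%d/%y')}",
        f"End Date: {rec.end_datetime.strftime('%m/%d/%y')}",
        f"Subject: {rec.subject_id}",
        f"Box: {rec.box}",
        f"Start Time: {rec.start_datetime.strftime('%H:%M:%S')}",
        f"End Time: {rec.end_datetime.strftime('%H:%M:%S')}",
        f"MSN: {rec.program}",
    ]
    scalar_values = {
        "total_infusions": rec.total_infusions,
        "total_active": rec.total_active,
        "total_inactive": rec.total_inactive,
        "breakpoint": rec.breakpoint,
        "total_shocks": rec.total_shocks,
        "infusions_after_shock": rec.infusions_after_shock,
    }
    for letter in sorted(vmap.scalar_roles):
        value = scalar_values[vmap.scalar_roles[letter]]
        if value is None:
            continue
        out.append(f"{letter}:{float(value):13.3f}")
    array_values = {
        "infusion_timestamps": rec.infusion_ts,
        "active_timestamps": rec.active_ts,
        "inactive_timestamps": rec.inactive_ts,
        "timeout_timestamps": rec.timeout_ts,
        "infusion_bins_5min": rec.infusion_bins_5min,
    }
    unit = vmap.timestamp_unit
    for letter in sorted(vmap.array_roles):
        role = vmap.array_roles[letter]
        values = array_values[role]
        if values is None:
            continue
        if role != "infusion_bins_5min":
            values = [t / unit for t in values]
        out.append(f"{letter}:")
        body = _fmt_array(values, pad_multiple)
        if body:
            out.append(body)
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Session workbook (one session per computer; rats in columns)
# ---------------------------------------------------------------------------

_WB_FIXED_ROWS = ("session", "subject_id", "box", "program", "start_date",
                  "start_time", "end_date", "end_time", "total_infusions",
                  "total_active", "total_inactive")
_WB_TS_ROWS = ("infusion_ts", "active_ts", "inactive_ts", "timeout_ts")


def _session_extras(session_type: str) -> tuple[str, ...]:
    if session_type == "PR":
        return ("breakpoint",)
    if session_type == "SHOCK":
        return ("total_shocks", "infusions_after_shock")
    return ()


def write_session_workbook(records: list[SessionRecord], meta: SessionMeta,
                           path, *, csv_twin: bool = True) -> Path:
    """Write the per-computer session workbook: one column per rat, fixed row
    order, timestamp arrays as space-delimited lists. A CSV twin with
    identical cells is written next to the XLSX unless disabled."""
    if not records:
        raise ValueError("write_session_workbook requires >= 1 record")
    for rec in records:
        if (rec.breakpoint is not None) != (meta.session_type == "PR"):
            raise ValueError(
                f"{rec.subject_id}: breakpoint presence inconsistent with "
                f"session type {meta.session_type} (mixed session types?)")
        if (rec.total_shocks is not None) != (meta.session_type == "SHOCK"):
            raise ValueError(
                f"{rec.subject_id}: shock fields inconsistent with session "
                f"type {meta.session_type} (mixed session types?)")

    rows = list(_WB_FIXED_ROWS) + list(_session_extras(meta.session_type)) \
        + list(_WB_TS_ROWS) + ["source_file"]
    session_name = compose_session_filename(meta, ext="")
    grid: list[list[str]] = [["variable"] + [r.subject_id for r in records]]
    for row in rows:
        cells = [row]
        for rec in records:
            cells.append(_wb_cell(rec, row, session_name))
        grid.append(cells)

    path = Path(path)
    if path.suffix.lower() == ".csv":
        _write_csv_grid(grid, path)
        return path
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = "session"
    for cells in grid:
        ws.append(cells)
    wb.save(path)
    if csv_twin:
        _write_csv_grid(grid, path.with_suffix(".csv"))
    return path


def _wb_cell(rec: SessionRecord, row: str, session_name: str) -> str:
    if row == "session":
        return session_name
    if row == "start_date":
        return rec.start_datetime.date().isoformat()
    if row == "start_time":
        return rec.start_datetime.time().isoformat()
    if row == "end_date":
        return rec.end_datetime.date().isoformat()
    if row == "end_time":
        return rec.end_datetime.time().isoformat()
    if row in _WB_TS_ROWS:
        return " ".join(f"{t:.3f}" for t in getattr(rec, row))
    value = getattr(rec, row)
    return "" if value is None else str(value)


def _write_csv_grid(grid, path):
    with open(path, "w", newline="") as fh:
        csv.writer(fh).writerows(grid)


def read_session_workbook(path) -> tuple[list[SessionRecord], SessionMeta]:
    """Faithful inverse of :func:`write_session_workbook` (XLSX or CSV)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            grid = [row for row in csv.reader(fh)]
    else:
        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
        ws = wb.active
        grid = [["" if c is None else str(c) for c in row]
                for row in ws.iter_rows(values_only=True)]
        wb.close()
    if not grid:
        raise SchemaError(f"{path}: empty workbook")
    by_row = {row[0]: row[1:] for row in grid[1:]}
    for mandatory in _WB_FIXED_ROWS + _WB_TS_ROWS + ("source_file",):
        if mandatory not in by_row:
            raise SchemaError(f"{path}: missing mandatory row {mandatory!r}")
    session_name = by_row["session"][0]
    meta = parse_session_filename(session_name + ".txt")
    extras = _session_extras(meta.session_type)
    for row in extras:
        if row not in by_row:
            raise SchemaError(f"{path}: missing mandatory row {row!r} for "
                              f"{meta.session_type} session")

    n = len(by_row["subject_id"])
    records = []
    for j in range(n):
        subject = by_row["subject_id"][j]
        if not subject:
            continue
        start = dt.datetime.fromisoformat(
            f"{by_row['start_date'][j]}T{by_row['start_time'][j]}")
        end = dt.datetime.fromisoformat(
            f"{by_row['end_date'][j]}T{by_row['end_time'][j]}")
        rec = SessionRecord(
            subject_id=subject, box=int(by_row["box"][j]),
            program=by_row["program"][j], start_datetime=start, end_datetime=end,
            total_infusions=int(by_row["total_infusions"][j]),
            total_active=int(by_row["total_active"][j]),
            total_inactive=int(by_row["total_inactive"][j]),
            source_file=by_row["source_file"][j])
        for row in _WB_TS_ROWS:
            cell = by_row[row][j]
            setattr(rec, row, [float(v) for v in cell.split()] if cell else [])
        for row in extras:
            cell = by_row[row][j]
            setattr(rec, row, int(cell) if cell != "" else None)
        records.append(rec)
    return records, meta


__all__ = [
    "VariableMap", "DEFAULT_VARIABLE_MAP", "SessionMeta", "SessionRecord",
    "SESSION_TYPES", "PHASE_ORDER", "DRUGS",
    "parse_raw_file", "write_raw_file",
    "parse_session_filename", "compose_session_filename",
    "session_token", "parse_session_token", "session_sort_key",
    "write_session_workbook", "read_session_workbook",
]
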