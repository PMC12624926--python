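"""Cohort summary and visualization outputs.

Four artifacts mirror daily lab practice: the per-animal behavior-trace
report (each animal against cohort, male and female averages with SEM), the
cohort behavior matrix (animals × sessions, one block per variable, with
issue and exit annotations), timestamp-derived session views (event rasters
and inter-infusion-interval histograms), and gap diagnostics that surface
naming mistakes and missing files as data gaps.

The tidy CSV/JSON data is the tested contract; PDF rendering through
matplotlib is best-effort on top of the same numbers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FilenameError, OperantDBError
from .medpc_io import (SESSION_TYPES, SessionRecord, parse_session_filename,
                       session_sort_key)
from .store import RawDatabase, deserialize_list

logger = logging.getLogger(__name__)

TRACE_VARIABLES = ("total_infusions", "total_active", "total_inactive")


# ---------------------------------------------------------------------------
# Inter-infusion intervals
# ---------------------------------------------------------------------------

def inter_infusion_intervals(record_or_ts, bin_width_s: float = 60.0,
                             ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Intervals between successive drug infusions, plus histogram counts.

    Accepts a :class:`SessionRecord` or a raw timestamp sequence. Zero or
    one timestamp yields an empty interval set. ``sum(intervals)`` equals
    the span ``last - first`` by construction.
    """
    ts = np.asarray(record_or_ts.infusion_ts
                    if isinstance(record_or_ts, SessionRecord)
                    else record_or_ts, dtype=float)
    intervals = np.diff(ts) if len(ts) > 1 else np.array([], dtype=float)
    if len(intervals):
        top = np.ceil(intervals.max() / bin_width_s) * bin_width_s
        edges = np.arange(0.0, max(top, bin_width_s) + bin_width_s / 2,
                          bin_width_s)
        counts, edges = np.histogram(intervals, bins=edges)
    else:
        edges = np.array([0.0, bin_width_s])
        counts = np.zeros(1, dtype=int)
    return intervals, (counts, edges)


# ---------------------------------------------------------------------------
# Event raster
# ---------------------------------------------------------------------------

@dataclass
class EventRaster:
    """Per-class event timestamps of one session (the interactive timeline's
    data contract)."""

    rfid: str
    active_ts: list[float]
    inactive_ts: list[float]
    timeout_ts: list[float]
    infusion_ts: list[float]
    duration_s: float

    def validate(self) -> None:
        for name in ("active_ts", "inactive_ts", "timeout_ts", "infusion_ts"):
            ts = getattr(self, name)
            if any(t < 0 or t > self.duration_s for t in ts):
                raise ValueError(f"{name}: timestamp outside [0, duration]")

    def to_json(self) -> str:
        return json.dumps(vars(self))


def build_event_raster(record: SessionRecord, rfid: str | None = None
                       ) -> EventRaster:
    raster = EventRaster(
        rfid=rfid or record.subject_id,
        active_ts=list(record.active_ts), inactive_ts=list(record.inactive_ts),
        timeout_ts=list(record.timeout_ts), infusion_ts=list(record.infusion_ts),
        duration_s=record.duration_s)
    raster.validate()
    return raster


# ---------------------------------------------------------------------------
# Behavior matrix
# ---------------------------------------------------------------------------

_LEADING = ["subject_id", "rfid", "drug_group", "experiment_group"]
_TRAILING = ["last_good_session", "exit_date", "exit_code", "notes"]

_MATRIX_VARIABLES = {
    "infusions": ("total_infusions", None),
    "active": ("total_active", None),
    "inactive": ("total_inactive", None),
    "breakpoint": ("breakpoint", "PR"),
    "total_shocks": ("total_shocks", "SHOCK"),
    "infusions_after_shock": ("infusions_after_shock", "SHOCK"),
}


@dataclass
class BehaviorMatrix:
    """Cohort-wide summary: one body row per animal, one column per session,
    repeated per variable; session date / ID / issue header rows on top."""

    cohort: str
    header: pd.DataFrame                 # rows: date, session_id, issues, issue_notes
    bodies: dict[str, pd.DataFrame]      # variable -> animals × sessions
    leading: pd.DataFrame                # subject_id, rfid, drug_group, experiment_group
    trailing: pd.DataFrame               # last_good_session, exit_date, exit_code, notes

    def sheet(self, variable: str) -> pd.DataFrame:
        """Assemble one spreadsheet-shaped frame for a variable."""
        body = self.bodies[variable]
        top = pd.DataFrame("", index=self.header.index,
                           columns=_LEADING + list(body.columns) + _TRAILING)
        top.loc[:, body.columns] = self.header[body.columns]
        mid = pd.concat([self.leading, body, self.trailing], axis=1)
        return pd.concat([top, mid])


def build_behavior_matrix(db: RawDatabase, cohort: str) -> BehaviorMatrix:
    """Build the behavior matrix from stored values (no recomputation)."""
    operant = db.operant()
    operant = operant[operant["cohort"] == cohort]
    subject = db.table("subject")
    subject = subject[subject["cohort"] == cohort].set_index("rfid")
    issues = db.table("issue")
    exits = db.table("exit").set_index("rfid")

    tokens = sorted(operant["session_token"].unique(), key=session_sort_key)
    dates = operant.groupby("session_token")["session_date"].min()
    issue_code, issue_note = {}, {}
    for iss in issues.itertuples():
        if iss.session_id in tokens:
            issue_code.setdefault(iss.session_id, []).append(
                f"{iss.subject_id or iss.rfid}:{iss.issue_code}")
            if iss.notes:
                issue_note.setdefault(iss.session_id, []).append(
                    f"{iss.subject_id or iss.rfid}:{iss.notes}")
    header = pd.DataFrame(
        {t: [dates.get(t, ""), t,
             "; ".join(issue_code.get(t, [])),
             "; ".join(issue_note.get(t, []))] for t in tokens},
        index=["date", "session_id", "issues", "issue_notes"])

    rfids = sorted(subject.index)
    leading = pd.DataFrame(
        {c: [subject.at[r, c] if c != "rfid" else r for r in rfids]
         for c in _LEADING}, index=rfids)
    trailing = pd.DataFrame(
        {c: [exits.at[r, c] if r in exits.index else "" for r in rfids]
         for c in _TRAILING}, index=rfids)

    by_key = {(r.rfid, r.session_token): r for r in operant.itertuples()}
    bodies = {}
    for var, (col, only_type) in _MATRIX_VARIABLES.items():
        cols = [t for t in tokens
                if only_type is None or t.startswith(only_type)]
        # guard: PR-prefixed filter would also catch nothing else; token
        # prefixes are unambiguous (SHA/LGA/PR/SHOCK)
        if only_type == "PR":
            cols = [t for t in cols if not t.startswith("SHOCK")]
        if not cols:
            continue
        body = pd.DataFrame("", index=rfids, columns=cols, dtype=object)
        for r in rfids:
            for t in cols:
                row = by_key.get((r, t))
                if row is None:
                    continue
                value = getattr(row, col)
                if value is not None and not pd.isna(value):
                    body.at[r, t] = value
        bodies[var] = body
    return BehaviorMatrix(cohort=cohort, header=header, bodies=bodies,
                          leading=leading, trailing=trailing)


def write_behavior_matrix(matrix: BehaviorMatrix, path) -> Path:
    """Write the matrix as XLSX (one sheet per variable) plus CSV twins."""
    import openpyxl
    path = Path(path)
    wb = openpyxl.Workbook()
    wb.remove(wb.active)
    for var in matrix.bodies:
        sheet = matrix.sheet(var)
        ws = wb.create_sheet(title=var[:31])
        ws.append([""] + list(sheet.columns))
        for idx, row in sheet.iterrows():
            ws.append([idx] + ["" if pd.isna(v) else v for v in row])
        sheet.to_csv(path.with_suffix("") .with_name(
            f"{path.stem}_{var}.csv"))
    wb.save(path)
    return path


# ---------------------------------------------------------------------------
# Trace report
# ---------------------------------------------------------------------------

@dataclass
class TracePanel:
    """One animal × phase × variable trace against group averages."""

    rfid: str
    phase: str
    variable: str
    sessions: list[str]
    animal: list[float | None]
    cohort_mean: list[float | None]
    cohort_sem: list[float | None]
    male_mean: list[float | None]
    male_sem: list[float | None]
    female_mean: list[float | None]
    female_sem: list[float | None]
    annotations: dict = field(default_factory=dict)


def _group_stats(frame: pd.DataFrame, tokens: list[str]):
    """Mean and SEM per session over the animals present that session."""
    means, sems = [], []
    for t in tokens:
        vals = frame[frame["session_token"] == t]["value"].dropna()
        if len(vals) == 0:
            means.append(None)
            sems.append(None)
            continue
        means.append(float(vals.mean()))
        sems.append(0.0 if len(vals) < 2
                    else float(vals.std(ddof=1) / np.sqrt(len(vals))))
    return means, sems


def build_trace_report(db: RawDatabase, combined: pd.DataFrame,
                       rfids: list[str] | None = None,
                       *, stable: pd.DataFrame | None = None,
                       include_imputed: bool = True) -> list[TracePanel]:
    """Per-animal trace panels over the combined (exclusion-joined) table.

    Group means/SEM are computed only over non-excluded animals; with
    ``stable`` supplied and ``include_imputed`` true, imputed values take
    part in the averages (the default, for smooth traces). Missing sessions
    stay gaps — they are never interpolated for display.
    """
    subject = db.table("subject").set_index("rfid")
    issues = db.table("issue")
    exits = db.table("exit").set_index("rfid")

    long = _trace_long(combined, stable, include_imputed)
    long = long.merge(subject[["sex"]], left_on="rfid", right_index=True,
                      how="left")

    if rfids is None:
        rfids = sorted(combined["rfid"].unique())
    else:
        known = set(combined["rfid"].unique()) | set(subject.index)
        for r in rfids:
            if r not in known:
                raise OperantDBError(f"animal {r!r} not in database")

    panels = []
    for phase in SESSION_TYPES:
        sub = long[long["phase"] == phase]
        if sub.empty:
            continue
        tokens = sorted(sub["session_token"].unique(), key=session_sort_key)
        for variable in ("infusions", "active", "inactive"):
            v = sub[sub["variable"] == variable]
            cmean, csem = _group_stats(v, tokens)
            mmean, msem = _group_stats(v[v["sex"] == "M"], tokens)
            fmean, fsem = _group_stats(v[v["sex"] == "F"], tokens)
            for rfid in rfids:
                mine = v[v["rfid"] == rfid].set_index("session_token")["value"]
                animal = [None if t not in mine.index or pd.isna(mine[t])
                          else float(mine[t]) for t in tokens]
                ann = {"issues": [
                    {"session": i.session_id, "code": i.issue_code,
                     "keep": bool(i.keep)}
                    for i in issues.itertuples() if i.rfid == rfid
                    and i.session_id in tokens]}
                if rfid in exits.index:
                    ann["exit"] = {
                        "exit_date": exits.at[rfid, "exit_date"],
                        "exit_code": exits.at[rfid, "exit_code"],
                        "last_good_session": exits.at[rfid, "last_good_session"]}
                panels.append(TracePanel(
                    rfid=rfid, phase=phase, variable=variable,
                    sessions=tokens, animal=animal,
                    cohort_mean=cmean, cohort_sem=csem,
                    male_mean=mmean, male_sem=msem,
                    female_mean=fmean, female_sem=fsem,
                    annotations=ann))
    return panels


def _trace_long(combined, stable, include_imputed) -> pd.DataFrame:
    if stable is not None and include_imputed:
        df = stable.rename(columns={"session": "session_token"}).copy()
        df = df[df["flag"] != "missing"]
        df["phase"] = df["phase"].astype(str)
        return df[["rfid", "phase", "session_token", "variable", "value"]]
    rows = []
    for r in combined.itertuples():
        for variable, col in (("infusions", "total_infusions"),
                              ("active", "total_active"),
                              ("inactive", "total_inactive")):
            rows.append({"rfid": r.rfid, "phase": r.session_type,
                         "session_token": r.session_token,
                         "variable": variable,
                         "value": getattr(r, col)})
    return pd.DataFrame(rows)


def write_trace_report(panels: list[TracePanel], outdir,
                       *, pdf: bool = True) -> Path:
    """JSON sidecar (the contract) plus a one-page-per-animal PDF render."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = [vars(p) for p in panels]
    json_path = outdir / "trace_report.json"
    json_path.write_text(json.dumps(payload, indent=1))
    if pdf:
        _render_trace_pdf(panels, outdir / "trace_report.pdf")
    return json_path


def _render_trace_pdf(panels, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.backends.backend_pdf import PdfPages

    by_rfid: dict[str, list[TracePanel]] = {}
    for p in panels:
        by_rfid.setdefault(p.rfid, []).append(p)
    with PdfPages(path) as pdf:
        for rfid, plist in by_rfid.items():
            ncols = 3
            nrows = max(1, -(-len(plist) // ncols))
            fig, axes = plt.subplots(nrows, ncols,
                                     figsize=(11, 2.8 * nrows), squeeze=False)
            for ax, p in zip(axes.ravel(), plist):
                x = np.arange(len(p.sessions))
                for series, sem, color, label in (
                        (p.cohort_mean, p.cohort_sem, "0.6", "cohort"),
                        (p.male_mean, p.male_sem, "tab:blue", "male"),
                        (p.female_mean, p.female_sem, "tab:orange", "female")):
                    y = np.array([np.nan if v is None else v for v in series])
                    e = np.array([np.nan if v is None else v for v in sem])
                    ax.plot(x, y, color=color, label=label, lw=1)
                    ax.fill_between(x, y - e, y + e, color=color, alpha=0.2)
                y = np.array([np.nan if v is None else v for v in p.animal])
                ax.plot(x, y, color="tab:red", lw=1.5, label=rfid)
                ax.set_title(f"{p.phase} {p.variable}", fontsize=8)
                ax.tick_params(labelsize=6)
            for ax in axes.ravel()[len(plist):]:
                ax.axis("off")
            fig.suptitle(rfid, fontsize=10)
            fig.tight_layout()
            pdf.savefig(fig)
            plt.close(fig)


# ---------------------------------------------------------------------------
# Gap diagnostics
# ---------------------------------------------------------------------------

def diagnose_gaps(db: RawDatabase, raw_dir=None,
                  parse_failures: list[str] | None = None) -> pd.DataFrame:
    """Report processing gaps: unparseable filenames (naming mistakes),
    files that failed to parse, and expected rat-sessions with no stored row.

    Returns a frame with columns (kind, rfid, session, filename, reason).
    A complete cohort yields an empty frame.
    """
    rows = []
    failures = set(parse_failures or [])
    if raw_dir is not None:
        for f in sorted(Path(raw_dir).glob("*.txt")):
            try:
                parse_session_filename(f.name)
            except FilenameError as exc:
                rows.append({"kind": "unparseable_file", "rfid": None,
                             "session": None, "filename": f.name,
                             "reason": "name mismatch",
                             "detail": str(exc)})
    operant = db.operant()
    if not operant.empty:
        tokens = sorted(operant["session_token"].unique(), key=session_sort_key)
        subjects = db.table("subject")
        present = {(r.rfid, r.session_token) for r in operant.itertuples()}
        for rfid in sorted(subjects["rfid"]):
            for t in tokens:
                if (rfid, t) in present:
                    continue
                reason = "no file"
                for fname in failures:
                    if t in fname:
                        reason = "parse failure"
                        break
                rows.append({"kind": "missing_session", "rfid": rfid,
                             "session": t, "filename": None,
                             "reason": reason, "detail": None})
    return pd.DataFrame(rows, columns=["kind", "rfid", "session", "filename",
                                       "reason", "detail"])


def session_rasters(db: RawDatabase, rfid: str) -> list[EventRaster]:
    """Event rasters for every stored session of one animal (feeds the
    interactive timeline)."""
    operant = db.operant()
    mine = operant[operant["rfid"] == rfid]
    rasters = []
    for r in mine.itertuples():
        start = pd.Timestamp(f"{r.session_date}T{r.start_time}")
        end = pd.Timestamp(f"{r.session_date}T{r.end_time}")
        duration = (end - start).total_seconds()
        if duration < 0:
            duration += 86400.0
        raster = EventRaster(
            rfid=rfid,
            active_ts=deserialize_list(r.active_ts),
            inactive_ts=deserialize_list(r.inactive_ts),
            timeout_ts=deserialize_list(r.timeout_ts),
            infusion_ts=deserialize_list(r.infusion_ts),
            duration_s=duration)
        raster.validate()
        rasters.append(raster)
    return rasters


__all__ = [
    "inter_infusion_intervals", "EventRaster", "build_event_raster",
    "BehaviorMatrix", "build_behavior_matrix", "write_behavior_matrix",
    "TracePanel", "build_trace_report", "write_trace_report",
    "diagnose_gaps", "session_rasters",
]
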