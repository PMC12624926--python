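"""Synthetic-cohort generator.

The behavior model is a renewal process honoring the FR1 + 20-s-timeout
paradigm: lever presses arrive with exponential waiting times; a press
landing outside the post-infusion timeout triggers an infusion and opens a
new 20-s timeout window; presses inside the window are logged as timeout
presses and have no consequence. Intake escalates linearly across
long-access (LgA) sessions with a per-rat slope drawn from a configured
distribution. Inactive presses are an independent Poisson process.

Anomalies (impossible infusion counts above syringe capacity, missing
sessions, daily-issue records, exits) are injected *after* simulation by
overwriting counts and arrays, so the ground truth stays exact. All
randomness flows from one seed through named substreams.

Event times are handled in centiseconds internally so that written MedPC
files round-trip bit-exactly and the 20-s refractory contract survives
rounding.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..medpc_io import (DEFAULT_VARIABLE_MAP, SESSION_TYPES, SessionMeta,
                        SessionRecord, compose_session_filename,
                        session_token, write_raw_file)

COMPUTER_LETTERS = "ABCDE"


def _default_phase_plan():
    return {"SHA": 4, "LGA": 14, "PR": 2, "SHOCK": 2}


def _default_session_hours():
    return {"SHA": 2.0, "LGA": 6.0, "PR": 2.0, "SHOCK": 1.0}


@dataclass
class CohortSimConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the real operation: 60 rats on 16-chamber computers
    (hence 4 raw files per session), 2-h short-access and 6-h long-access
    sessions, FR1 with a 20-s post-infusion timeout, and linear intake
    escalation across LgA.
    """

    n_subjects: int = 60
    chambers_per_computer: int = 16
    drug: str = "OXY"
    cohort: str = "C01"
    location: str = "MTF134"
    phase_plan: dict[str, int] = field(default_factory=_default_phase_plan)
    session_hours: dict[str, float] = field(default_factory=_default_session_hours)
    start_date: dt.date = dt.date(2024, 1, 8)
    timeout_s: float = 20.0
    infusion_rate_per_h: float = 8.0      # baseline, SHA and first LgA session
    escalation_mean: float = 2.5          # infusions/session added across LgA
    escalation_sd: float = 1.0
    inactive_rate_per_h: float = 4.0
    timeout_press_mean: float = 1.0       # extra presses per timeout window
    breakpoint_mean: float = 12.0
    breakpoint_sd: float = 4.0
    shock_fraction: float = 0.3           # fraction of shock-session infusions shocked
    compulsivity_range: tuple[float, float] = (0.2, 0.9)
    noise: str = "stochastic"             # "stochastic" | "none"
    # anomaly plan
    n_single_outlier_rats: int = 1
    n_multi_outlier_rats: int = 1
    n_missing_sessions: int = 3
    n_keep_issues: int = 2
    n_discard_issues: int = 1
    n_exits: int = 2
    misname_session: str | None = None    # token whose computer-A file gets a bad name
    seed: int = 0

    def n_computers(self) -> int:
        return -(-self.n_subjects // self.chambers_per_computer)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_computers() > len(COMPUTER_LETTERS):
            raise ValueError(
                f"infeasible plan: {self.n_subjects} rats need "
                f"{self.n_computers()} computers but only "
                f"{len(COMPUTER_LETTERS)} (A-E) exist")
        if self.timeout_s < 0 or self.infusion_rate_per_h < 0 \
                or self.inactive_rate_per_h < 0:
            raise ValueError("rates and timeout must be >= 0")
        if self.noise not in ("stochastic", "none"):
            raise ValueError("noise must be 'stochastic' or 'none'")

    def session_tokens(self) -> list[str]:
        tokens = []
        for stype in SESSION_TYPES:
            for k in range(1, self.phase_plan.get(stype, 0) + 1):
                tokens.append(session_token(stype, k))
        return tokens


@dataclass
class GroundTruth:
    """Exact record of what the generator produced and what the curation
    rules are expected to do with it."""

    config: dict
    rats: list[dict]                       # subject_id, rfid, sex, computer, box, traits
    sessions: dict[str, dict[str, dict]]   # rfid -> token -> session payload
    session_dates: dict[str, str]          # token -> ISO date
    outliers: list[dict]                   # {rfid, session, value, kind}
    missing: list[list[str]]               # [rfid, token] blocks absent from raw files
    issues: list[dict]
    exits: list[dict]
    expected_excluded: list[list[str]]     # [rfid, token] pairs absent from combined
    misnamed_files: list[str]

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         sort_keys=True))

    @classmethod
    def load(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Event simulation (centisecond integer grid)
# ---------------------------------------------------------------------------

def _cs(seconds: float) -> int:
    return int(round(seconds * 100))


def simulate_fr1_session(rng: np.random.Generator, *, hours: float,
                         infusion_rate_per_h: float, timeout_s: float = 20.0,
                         timeout_press_mean: float = 1.0,
                         inactive_rate_per_h: float = 4.0) -> dict:
    """Simulate one FR1 session; returns timestamp lists in seconds.

    Press waiting times are exponential with rate chosen so the mean
    inter-infusion interval (timeout + mean wait) matches the requested
    infusion rate. Every infusion timestamp is also an active-press
    timestamp; no two infusions are closer than the timeout.
    """
    duration_cs = _cs(hours * 3600)
    timeout_cs = _cs(timeout_s)
    if infusion_rate_per_h <= 0:
        mean_wait = None
    else:
        mean_wait = max(3600.0 / infusion_rate_per_h - timeout_s, 1.0)
    infusion, active, timeout_presses = [], [], []
    last_inf = -timeout_cs - 1
    t = 0
    while mean_wait is not None:
        t += max(_cs(rng.exponential(mean_wait)), 1)
        if t >= duration_cs:
            break
        if t - last_inf >= timeout_cs:
            infusion.append(t)
            active.append(t)
            last_inf = t
            n_extra = rng.poisson(timeout_press_mean)
            lo, hi = t + 1, min(t + timeout_cs, duration_cs) - 1
            if n_extra and hi > lo:
                timeout_presses.extend(
                    int(v) for v in np.sort(rng.integers(lo, hi, n_extra)))
        else:
            timeout_presses.append(t)
    n_inact = rng.poisson(inactive_rate_per_h * hours)
    inactive = sorted(int(v) for v in rng.integers(1, duration_cs, n_inact)) \
        if n_inact else []
    return {
        "infusion_ts": [v / 100.0 for v in infusion],
        "active_ts": [v / 100.0 for v in active],
        "timeout_ts": [v / 100.0 for v in sorted(timeout_presses)],
        "inactive_ts": [v / 100.0 for v in inactive],
        "duration_s": duration_cs / 100.0,
    }


def _evenly_spaced(n: int, duration_s: float, min_gap_s: float) -> list[float]:
    """n deterministic event times, strictly inside (0, duration), at least
    min_gap apart (used by the noise-free mode and anomaly overwrites)."""
    if n <= 0:
        return []
    gap = duration_s / (n + 1)
    if gap < min_gap_s:
        gap = min_gap_s
    return [round(gap * (j + 1), 2) for j in range(n)]


def _bins_5min(infusion_ts: list[float], duration_s: float) -> list[int]:
    n_bins = max(int(np.ceil(duration_s / 300.0)), 1)
    counts = [0] * n_bins
    for t in infusion_ts:
        counts[min(int(t // 300), n_bins - 1)] += 1
    return counts


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _rat_roster(config: CohortSimConfig, rng_meta: np.random.Generator):
    rats = []
    for i in range(config.n_subjects):
        comp = COMPUTER_LETTERS[i // config.chambers_per_computer]
        box = i % config.chambers_per_computer + 1
        if config.noise == "none":
            slope = float(rng_meta.integers(1, 6))
            motivation = float(rng_meta.integers(5, 21))
        else:
            slope = float(rng_meta.normal(config.escalation_mean,
                                          config.escalation_sd))
            motivation = float(max(1.0, rng_meta.normal(
                config.breakpoint_mean, config.breakpoint_sd)))
        lo, hi = config.compulsivity_range
        compulsivity = float(rng_meta.uniform(lo, hi))
        rats.append({
            "subject_id": f"R{i + 1:03d}",
            "rfid": f"93300032{config.cohort[1:]}{i + 1:05d}",
            "sex": "M" if i % 2 == 0 else "F",
            "computer": comp, "box": box,
            "slope": slope, "motivation": motivation,
            "compulsivity": compulsivity,
        })
    return rats


def _target_rate(config: CohortSimConfig, rat: dict, stype: str, k: int) -> float:
    hours = config.session_hours[stype]
    base = config.infusion_rate_per_h
    if stype == "LGA":
        return base + rat["slope"] * (k - 1) / hours
    if stype == "SHOCK":
        return base * 0.7
    return base


def _simulate_rat_session(config: CohortSimConfig, rat: dict, stype: str,
                          k: int, rng: np.random.Generator) -> dict:
    hours = config.session_hours[stype]
    duration = hours * 3600.0
    if config.noise == "none":
        if stype == "LGA":
            n_inf = int(round(config.infusion_rate_per_h * hours
                              + rat["slope"] * (k - 1)))
        elif stype == "PR":
            n_inf = int(rat["motivation"])
        elif stype == "SHOCK":
            n_inf = int(round(rat["compulsivity"]
                              * config.infusion_rate_per_h * hours))
        else:
            n_inf = int(round(config.infusion_rate_per_h * hours))
        inf = _evenly_spaced(n_inf, duration, config.timeout_s + 0.02)
        n_inact = int(round(config.inactive_rate_per_h * hours))
        sess = {"infusion_ts": inf, "active_ts": list(inf),
                "timeout_ts": [],
                "inactive_ts": _evenly_spaced(n_inact, duration, 0.02),
                "duration_s": duration}
    else:
        rate = _target_rate(config, rat, stype, k)
        sess = simulate_fr1_session(
            rng, hours=hours, infusion_rate_per_h=rate,
            timeout_s=config.timeout_s,
            timeout_press_mean=config.timeout_press_mean,
            inactive_rate_per_h=config.inactive_rate_per_h)
    sess["infusions"] = len(sess["infusion_ts"])
    sess["active"] = len(sess["active_ts"])
    sess["inactive"] = len(sess["inactive_ts"])
    sess["bins_5min"] = _bins_5min(sess["infusion_ts"], sess["duration_s"])
    if stype == "PR":
        if config.noise == "none":
            bp = int(rat["motivation"])
        else:
            bp = max(1, int(round(rng.normal(rat["motivation"], 2.0))))
        sess["breakpoint"] = bp
    if stype == "SHOCK":
        sess["total_shocks"] = int(round(config.shock_fraction
                                         * sess["infusions"]))
        sess["infusions_after_shock"] = int(round(
            rat["compulsivity"] * sess["infusions"]))
    return sess


def _overwrite_outlier(config: CohortSimConfig, sess: dict, value: int) -> None:
    """Inject an impossible infusion count, keeping arrays consistent with
    the counts so the record still parses cleanly."""
    inf = _evenly_spaced(value, sess["duration_s"], config.timeout_s + 0.02)
    sess["infusion_ts"] = inf
    sess["active_ts"] = list(inf)
    sess["infusions"] = value
    sess["active"] = value
    sess["bins_5min"] = _bins_5min(inf, sess["duration_s"])


def _phase_token_order(config: CohortSimConfig) -> list[str]:
    return config.session_tokens()


def generate_cohort(config: CohortSimConfig, outdir) -> GroundTruth:
    """Generate a full synthetic cohort under ``outdir``.

    Writes ``raw/`` (one MedPC TXT per computer per session), ``templates/``
    (Cohort Information as CSV+XLSX; Daily Issues, Exit, Von Frey, tail
    immersion, irritability as CSV; an empty Corrections Record) and
    ``ground_truth.json``. Same seed ⇒ byte-identical tree.
    """
    config.validate()
    outdir = Path(outdir)
    raw_dir = outdir / "raw"
    tpl_dir = outdir / "templates"
    raw_dir.mkdir(parents=True, exist_ok=True)
    tpl_dir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(config.seed)
    rng_behavior, rng_anomaly, rng_meta = (np.random.default_rng(c)
                                           for c in ss.spawn(3))

    rats = _rat_roster(config, rng_meta)
    tokens = _phase_token_order(config)
    session_dates = {tok: (config.start_date + dt.timedelta(days=d)).isoformat()
                     for d, tok in enumerate(tokens)}

    sessions: dict[str, dict[str, dict]] = {r["rfid"]: {} for r in rats}
    for rat in rats:
        for tok in tokens:
            stype = tok[:-2]
            k = int(tok[-2:])
            sessions[rat["rfid"]][tok] = _simulate_rat_session(
                config, rat, stype, k, rng_behavior)

    outliers, missing, issues, exits = _inject_anomalies(
        config, rats, sessions, tokens, session_dates, rng_anomaly)

    misnamed = _write_raw_files(config, rats, sessions, tokens,
                                session_dates, missing, raw_dir)
    _write_templates(config, rats, tokens, session_dates, issues, exits,
                     tpl_dir, rng_meta)

    expected_excluded = _expected_exclusions(issues, exits, sessions, tokens)
    truth = GroundTruth(
        config={k: (v.isoformat() if isinstance(v, dt.date) else
                    list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()},
        rats=rats, sessions=sessions, session_dates=session_dates,
        outliers=outliers, missing=missing, issues=issues, exits=exits,
        expected_excluded=expected_excluded, misnamed_files=misnamed)
    truth.save(outdir / "ground_truth.json")
    return truth


def _inject_anomalies(config, rats, sessions, tokens, session_dates, rng):
    lga_tokens = [t for t in tokens if t.startswith("LGA")]
    pool = list(range(len(rats)))
    rng.shuffle(pool)
    outliers, missing, issues, exits = [], [], [], []

    def take(n):
        return [pool.pop() for _ in range(min(n, len(pool)))]

    if lga_tokens:
        for i in take(config.n_single_outlier_rats):
            rfid = rats[i]["rfid"]
            tok = lga_tokens[int(rng.integers(0, len(lga_tokens)))]
            value = int(rng.integers(251, 341))
            _overwrite_outlier(config, sessions[rfid][tok], value)
            outliers.append({"rfid": rfid, "session": tok, "value": value,
                             "kind": "single"})
        for i in take(config.n_multi_outlier_rats):
            rfid = rats[i]["rfid"]
            picks = sorted(rng.choice(len(lga_tokens),
                                      size=min(3, len(lga_tokens)),
                                      replace=False).tolist())
            for p in picks:
                tok = lga_tokens[p]
                value = int(rng.integers(251, 341))
                _overwrite_outlier(config, sessions[rfid][tok], value)
                outliers.append({"rfid": rfid, "session": tok,
                                 "value": value, "kind": "multi"})

    # exits: the rats leave mid-LgA; sessions after the last good one stay
    # in the raw files and must be excluded at combine time
    for i in take(config.n_exits):
        rat = rats[i]
        if len(lga_tokens) >= 2:
            last_good = lga_tokens[len(lga_tokens) // 2]
        else:
            last_good = tokens[len(tokens) // 2]
        exits.append({
            "subject_id": rat["subject_id"], "rfid": rat["rfid"],
            "cohort": config.cohort,
            "exit_date": session_dates[last_good],
            "last_good_session": last_good,
            "exit_code": ["Death", "Brevital Fail", "Other"][int(rng.integers(0, 3))],
            "decision_type": "objective",
            "behavioral_testing_status": "incomplete",
            "tissue_collection_status": "collected",
            "notes": "synthetic exit", "replaced": "no"})

    plain = [i for i in range(len(rats))
             if i in pool]  # rats untouched by outlier/exit plans
    codes = ["disconnected", "tangled", "empty syringe", "sick", "other"]
    for _ in range(config.n_discard_issues):
        if not plain:
            break
        i = plain[int(rng.integers(0, len(plain)))]
        tok = tokens[int(rng.integers(0, len(tokens)))]
        issues.append({"subject_id": rats[i]["subject_id"],
                       "rfid": rats[i]["rfid"],
                       "date": session_dates[tok], "session_id": tok,
                       "issue_code": codes[int(rng.integers(0, len(codes)))],
                       "keep": "discard", "decision_type": "objective",
                       "notes": "synthetic discard"})
    for _ in range(config.n_keep_issues):
        if not plain:
            break
        i = plain[int(rng.integers(0, len(plain)))]
        tok = tokens[int(rng.integers(0, len(tokens)))]
        issues.append({"subject_id": rats[i]["subject_id"],
                       "rfid": rats[i]["rfid"],
                       "date": session_dates[tok], "session_id": tok,
                       "issue_code": codes[int(rng.integers(0, len(codes)))],
                       "keep": "keep", "decision_type": "subjective",
                       "notes": "synthetic note"})

    # missing sessions: the raw-file block simply never gets written
    discard_keys = {(iss["rfid"], iss["session_id"]) for iss in issues
                    if iss["keep"] == "discard"}
    for _ in range(config.n_missing_sessions):
        if not plain:
            break
        i = plain[int(rng.integers(0, len(plain)))]
        tok = tokens[int(rng.integers(0, len(tokens)))]
        if (rats[i]["rfid"], tok) in discard_keys \
                or [rats[i]["rfid"], tok] in missing:
            continue
        missing.append([rats[i]["rfid"], tok])
    return outliers, missing, issues, exits


def _session_record(config, rat, tok, sess, session_dates) -> SessionRecord:
    stype = tok[:-2]
    date = dt.date.fromisoformat(session_dates[tok])
    start = dt.datetime.combine(date, dt.time(9, 0, 0))
    end = start + dt.timedelta(seconds=sess["duration_s"])
    return SessionRecord(
        subject_id=rat["subject_id"], box=rat["box"],
        program=f"{config.drug}_{stype}",
        start_datetime=start, end_datetime=end,
        total_infusions=sess["infusions"], total_active=sess["active"],
        total_inactive=sess["inactive"],
        infusion_ts=sess["infusion_ts"], active_ts=sess["active_ts"],
        inactive_ts=sess["inactive_ts"], timeout_ts=sess["timeout_ts"],
        infusion_bins_5min=sess["bins_5min"],
        breakpoint=sess.get("breakpoint"),
        total_shocks=sess.get("total_shocks"),
        infusions_after_shock=sess.get("infusions_after_shock"))


def _write_raw_files(config, rats, sessions, tokens, session_dates,
                     missing, raw_dir) -> list[str]:
    missing_set = {tuple(m) for m in missing}
    misnamed = []
    for tok in tokens:
        stype = tok[:-2]
        k = int(tok[-2:])
        for ci in range(config.n_computers()):
            comp = COMPUTER_LETTERS[ci]
            members = [r for r in rats if r["computer"] == comp]
            records = []
            for rat in members:
                if (rat["rfid"], tok) in missing_set:
                    continue
                rec = _session_record(config, rat, tok,
                                      sessions[rat["rfid"]][tok],
                                      session_dates)
                records.append(rec)
            if not records:
                continue
            meta = SessionMeta(location=config.location, computer=comp,
                               cohort=config.cohort, drug=config.drug,
                               session_type=stype, session_index=k)
            name = compose_session_filename(meta)
            if config.misname_session == tok and comp == COMPUTER_LETTERS[0]:
                name = name.replace(tok, f"XYZ{k}")
                misnamed.append(name)
            for rec in records:
                rec.source_file = name
            write_raw_file(records, raw_dir / name, DEFAULT_VARIABLE_MAP)
    return misnamed


def _write_csv(path, header, rows):
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


def _write_templates(config, rats, tokens, session_dates, issues, exits,
                     tpl_dir, rng):
    import openpyxl

    first = config.start_date
    header = ["Subject ID", "RFID", "Sex", "Cohort", "Experiment Group",
              "Drug Group", "Date of Birth", "Coat Color", "Ear Marks",
              "Parentage", "Dissection Group", "Technician IDs",
              "date_surgery", "date_sha_start", "date_lga_start",
              "weight_1_date", "weight_1_g", "weight_2_date", "weight_2_g",
              "weight_3_date", "weight_3_g",
              "patency_1_date", "patency_1_result"]
    drug_group = "oxycodone" if config.drug == "OXY" else "cocaine"
    sha_start = session_dates.get(session_token("SHA", 1), first.isoformat())
    lga_start = session_dates.get(session_token("LGA", 1), first.isoformat())
    rows = []
    for rat in rats:
        dob = (first - dt.timedelta(days=70)).isoformat()
        weights = [round(float(250 + 25 * (rat["sex"] == "M")
                               + rng.normal(0, 8) + 5 * w), 1)
                   for w in range(3)]
        wdates = [(first + dt.timedelta(days=7 * w)).isoformat()
                  for w in range(3)]
        rows.append([rat["subject_id"], rat["rfid"], rat["sex"],
                     config.cohort, "drug", drug_group, dob, "brown",
                     "none", "HS", "D1", "tech1",
                     (first - dt.timedelta(days=14)).isoformat(),
                     sha_start, lga_start,
                     wdates[0], weights[0], wdates[1], weights[1],
                     wdates[2], weights[2],
                     (first - dt.timedelta(days=7)).isoformat(), "pass"])
    _write_csv(tpl_dir / "cohort_info.csv", header, rows)
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.append(header)
    for row in rows:
        ws.append(row)
    wb.save(tpl_dir / "cohort_info.xlsx")

    _write_csv(tpl_dir / "issues.csv",
               ["Subject ID", "RFID", "Date", "Session ID", "Issue Code",
                "Keep", "Decision Type", "Notes"],
               [[i["subject_id"], i["rfid"], i["date"], i["session_id"],
                 i["issue_code"], i["keep"], i["decision_type"], i["notes"]]
                for i in issues])
    _write_csv(tpl_dir / "exits.csv",
               ["Subject ID", "RFID", "Cohort", "Exit Date",
                "Last Good Session", "Exit Code", "Decision Type",
                "Behavioral Testing Status", "Tissue Collection Status",
                "Notes", "Replaced"],
               [[e["subject_id"], e["rfid"], e["cohort"], e["exit_date"],
                 e["last_good_session"], e["exit_code"], e["decision_type"],
                 e["behavioral_testing_status"],
                 e["tissue_collection_status"], e["notes"], e["replaced"]]
                for e in exits])

    vf_rows, ti_rows, irr_rows = [], [], []
    for rat in rats:
        f = [round(float(rng.uniform(20, 60)), 2) for _ in range(4)]
        lat = [round(float(rng.uniform(2, 10)), 2) for _ in range(4)]
        vf_rows.append([rat["rfid"], rat["subject_id"],
                        f[0], f[1], round((f[0] + f[1]) / 2, 6),
                        lat[0], lat[1], round((lat[0] + lat[1]) / 2, 6),
                        f[2], f[3], round((f[2] + f[3]) / 2, 6),
                        lat[2], lat[3], round((lat[2] + lat[3]) / 2, 6),
                        round((f[2] + f[3]) / 2 - (f[0] + f[1]) / 2, 6),
                        round((lat[2] + lat[3]) / 2 - (lat[0] + lat[1]) / 2, 6)])
        t = [round(float(rng.uniform(1, 12)), 2) for _ in range(3)]
        ti_rows.append([rat["rfid"], rat["subject_id"], t[0], t[1], t[2],
                        round(t[2] - t[1], 6)])
        a = [int(rng.integers(0, 15)) for _ in range(4)]
        d = [int(rng.integers(0, 15)) for _ in range(4)]
        irr_rows.append([rat["rfid"], rat["subject_id"], config.cohort,
                         a[0], a[1], round((a[0] + a[1]) / 2, 6),
                         d[0], d[1], round((d[0] + d[1]) / 2, 6),
                         a[2], a[3], round((a[2] + a[3]) / 2, 6),
                         d[2], d[3], round((d[2] + d[3]) / 2, 6),
                         round((a[2] + a[3]) / 2 - (a[0] + a[1]) / 2, 6),
                         round((d[2] + d[3]) / 2 - (d[0] + d[1]) / 2, 6)])
    _write_csv(tpl_dir / "vonfrey.csv",
               ["RFID", "Subject ID",
                "force_left_pre", "force_right_pre", "force_avg_pre",
                "latency_left_pre", "latency_right_pre", "latency_avg_pre",
                "force_left_post", "force_right_post", "force_avg_post",
                "latency_left_post", "latency_right_post", "latency_avg_post",
                "force_diff", "latency_diff"], vf_rows)
    _write_csv(tpl_dir / "tail_immersion.csv",
               ["RFID", "Subject ID", "latency_presha_nodrug",
                "latency_presha_drug", "latency_postlga_drug",
                "latency_diff"], ti_rows)
    _write_csv(tpl_dir / "irritability.csv",
               ["RFID", "Subject ID", "Cohort",
                "aggressive_obs1_pre", "aggressive_obs2_pre", "aggressive_avg_pre",
                "defensive_obs1_pre", "defensive_obs2_pre", "defensive_avg_pre",
                "aggressive_obs1_post", "aggressive_obs2_post", "aggressive_avg_post",
                "defensive_obs1_post", "defensive_obs2_post", "defensive_avg_post",
                "aggressive_diff", "defensive_diff"], irr_rows)
    (tpl_dir / "corrections.csv").write_text("")


def _expected_exclusions(issues, exits, sessions, tokens) -> list[list[str]]:
    token_pos = {t: i for i, t in enumerate(tokens)}
    out = set()
    for iss in issues:
        if iss["keep"] == "discard":
            out.add((iss["rfid"], iss["session_id"]))
    for ex in exits:
        last = token_pos[ex["last_good_session"]]
        for tok in tokens:
            if token_pos[tok] > last and tok in sessions.get(ex["rfid"], {}):
                out.add((ex["rfid"], tok))
    return sorted([list(p) for p in out])
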