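"""Curation of the combined table into the stable (released) table.

Three rules, applied in order, per animal, per variable, per phase:

1. **Outlier handling.** A syringe holds 250 infusions, so a per-session
   infusion count above 250 is physically impossible. A single such session
   in a series is treated as an equipment artifact: its infusion *and*
   active-lever values are removed. Two or more such sessions indicate a
   genuinely high-pressing animal: every exceeding infusion value is capped
   at 250 and the active-lever series is left untouched. Values at or below
   250 are never modified (the threshold is strict).
2. **Missing-session imputation.** An isolated interior gap is filled with
   the mean of its two observed neighbors; a single missing session at the
   series edge is filled with the mean of the two nearest observed values on
   its only observed side; runs of two or more consecutive missing sessions
   (interior or edge) are left missing.
3. **Dependent variables.** Per-animal summary phenotypes: the escalation
   index (least-squares slope of long-access infusions against session
   number), mean progressive-ratio breakpoint (motivation), shock resistance
   (mean infusions under shock relative to baseline long-access intake), the
   three population z-scores of these, and the composite Addiction Index
   (their arithmetic mean).

Every cell of the stable table carries a provenance flag: observed,
removed_outlier, capped, imputed_linear, imputed_nn, or missing.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ReleaseExistsError
from .medpc_io import PHASE_ORDER, SESSION_TYPES, session_sort_key

logger = logging.getLogger(__name__)

DEFAULT_CAP = 250

FLAG_OBSERVED = "observed"
FLAG_REMOVED = "removed_outlier"
FLAG_CAPPED = "capped"
FLAG_LINEAR = "imputed_linear"
FLAG_NN = "imputed_nn"
FLAG_MISSING = "missing"

VARIABLES = ("infusions", "active", "inactive")
_VAR_COLUMN = {"infusions": "total_infusions", "active": "total_active",
               "inactive": "total_inactive"}


@dataclass
class CuratedSeries:
    """Per-animal, per-variable session series with provenance flags.

    ``values`` uses NaN for missing cells; ``flags`` records how each cell
    came to hold its value.
    """

    rfid: str
    variable: str
    sessions: list[str]
    values: np.ndarray
    flags: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.flags = np.asarray(self.flags, dtype=object)
        if not (len(self.sessions) == len(self.values) == len(self.flags)):
            raise ValueError("sessions, values and flags must be aligned")

    @classmethod
    def from_values(cls, rfid, variable, sessions, values) -> "CuratedSeries":
        values = np.asarray(values, dtype=float)
        flags = np.where(np.isnan(values), FLAG_MISSING, FLAG_OBSERVED)
        return cls(rfid, variable, list(sessions), values,
                   flags.astype(object))

    def copy(self) -> "CuratedSeries":
        return CuratedSeries(self.rfid, self.variable, list(self.sessions),
                             self.values.copy(), self.flags.copy())

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)


# ---------------------------------------------------------------------------
# Rule 1: outliers
# ---------------------------------------------------------------------------

def handle_outliers(infusions: CuratedSeries, active: CuratedSeries,
                    cap: int = DEFAULT_CAP) -> tuple[CuratedSeries, CuratedSeries]:
    """Apply the syringe-capacity outlier rule to an aligned infusion/active
    series pair. Total function; values ≤ cap are never modified."""
    if infusions.sessions != active.sessions:
        raise ValueError("infusion and active series must share one session axis")
    inf, act = infusions.copy(), active.copy()
    over = np.flatnonzero(np.nan_to_num(inf.values, nan=-np.inf) > cap)
    if len(over) == 1:
        i = over[0]
        inf.values[i] = np.nan
        inf.flags[i] = FLAG_REMOVED
        act.values[i] = np.nan
        act.flags[i] = FLAG_REMOVED
    elif len(over) >= 2:
        # multiple outliers indicate a high-pressing animal: cap infusions,
        # leave active presses untouched
        for i in over:
            inf.values[i] = float(cap)
            inf.flags[i] = FLAG_CAPPED
    return inf, act


# ---------------------------------------------------------------------------
# Rule 2: imputation
# ---------------------------------------------------------------------------

def impute_missing(series: CuratedSeries) -> CuratedSeries:
    """Fill single-session gaps; leave multi-session gaps missing.

    Interior isolated gap → mean of the two flanking observed values
    (flag ``imputed_linear``). Single edge gap → mean of the two nearest
    observed values on the observed side (flag ``imputed_nn``); with only
    one observed value available there, that value is used. Edge gaps of
    length ≥ 2 follow the multi-gap rule and stay missing. Idempotent;
    observed cells are never altered.
    """
    out = series.copy()
    known = ~out.missing
    if known.sum() < 2:
        logger.warning("%s/%s: fewer than 2 observed values; imputation skipped",
                       series.rfid, series.variable)
        return out
    n = len(out.values)
    filled_values = out.values.copy()
    filled_flags = out.flags.copy()
    i = 0
    while i < n:
        if known[i]:
            i += 1
            continue
        run_start = i
        while i < n and not known[i]:
            i += 1
        run_len = i - run_start
        if run_len != 1:
            continue  # multiple consecutive missing sessions: not imputed
        j = run_start
        has_left = j > 0 and known[j - 1]
        has_right = j + 1 < n and known[j + 1]
        if has_left and has_right:
            filled_values[j] = (out.values[j - 1] + out.values[j + 1]) / 2.0
            filled_flags[j] = FLAG_LINEAR
        elif has_left or has_right:
            # edge gap: average the 2 nearest observed values on the
            # single observed side
            if has_right:
                obs = [k for k in range(j + 1, n) if known[k]][:2]
            else:
                obs = [k for k in range(j - 1, -1, -1) if known[k]][:2]
            filled_values[j] = float(np.mean(out.values[obs]))
            filled_flags[j] = FLAG_NN
    out.values = filled_values
    out.flags = filled_flags
    return out


# ---------------------------------------------------------------------------
# Rule 3: dependent variables
# ---------------------------------------------------------------------------

@dataclass
class DerivedPhenotypes:
    """Per-animal addiction-relevant summary phenotypes."""

    rfid: str
    escalation_index: float | None = None
    intake_total: float | None = None
    pr_breakpoint_summary: float | None = None
    shock_resistance: float | None = None
    z_escalation: float | None = None
    z_motivation: float | None = None
    z_compulsivity: float | None = None
    addiction_index: float | None = None


def escalation_slope(values: np.ndarray) -> float | None:
    """Least-squares slope of infusions against 1-based session number,
    skipping missing sessions (their session numbers keep their place)."""
    values = np.asarray(values, dtype=float)
    x = np.arange(1, len(values) + 1, dtype=float)
    ok = ~np.isnan(values)
    if ok.sum() < 2:
        return None
    slope, _ = np.polyfit(x[ok], values[ok], 1)
    return float(slope)


def _zscores(raw: dict[str, float | None]) -> dict[str, float | None]:
    vals = np.array([v for v in raw.values() if v is not None], dtype=float)
    if len(vals) < 2 or np.std(vals, ddof=1) == 0:
        return {k: None for k in raw}
    mean, sd = vals.mean(), vals.std(ddof=1)
    return {k: (None if v is None else float((v - mean) / sd))
            for k, v in raw.items()}


def compute_derived(series_by_rat: dict[str, dict[str, CuratedSeries]],
                    pr_breakpoints: dict[str, list[float]],
                    shock_infusions: dict[str, list[float]],
                    population: set[str] | None = None,
                    ) -> dict[str, DerivedPhenotypes]:
    """Compute per-animal phenotypes and population z-scores.

    ``series_by_rat`` maps rfid → {phase → curated infusion series};
    ``population`` is the standardization cohort (defaults to every rat
    present). The Addiction Index is the arithmetic mean of the escalation,
    motivation and compulsivity z-scores for animals with all three, else
    absent.
    """
    rfids = sorted(series_by_rat)
    if population is None:
        population = set(rfids)

    pheno = {r: DerivedPhenotypes(rfid=r) for r in rfids}
    for r in rfids:
        phases = series_by_rat[r]
        lga = phases.get("LGA")
        if lga is not None:
            pheno[r].escalation_index = escalation_slope(lga.values)
        total = 0.0
        any_obs = False
        for s in phases.values():
            obs = s.values[~np.isnan(s.values)]
            if len(obs):
                any_obs = True
                total += float(obs.sum())
        pheno[r].intake_total = total if any_obs else None
        bps = [b for b in pr_breakpoints.get(r, []) if b is not None
               and not (isinstance(b, float) and np.isnan(b))]
        if bps:
            pheno[r].pr_breakpoint_summary = float(np.mean(bps))
        shocks = [s for s in shock_infusions.get(r, []) if s is not None
                  and not (isinstance(s, float) and np.isnan(s))]
        if shocks and lga is not None:
            baseline = lga.values[~np.isnan(lga.values)]
            if len(baseline) and baseline.mean() > 0:
                pheno[r].shock_resistance = float(np.mean(shocks) / baseline.mean())
        missing = [c for c, v in (("LGA phase", pheno[r].escalation_index),
                                  ("PR phase", pheno[r].pr_breakpoint_summary),
                                  ("SHOCK phase", pheno[r].shock_resistance))
                   if v is None]
        if missing:
            logger.info("%s: missing %s; Addiction Index absent", r,
                        ", ".join(missing))

    for attr, zattr in (("escalation_index", "z_escalation"),
                        ("pr_breakpoint_summary", "z_motivation"),
                        ("shock_resistance", "z_compulsivity")):
        raw = {r: getattr(pheno[r], attr) for r in rfids if r in population}
        z = _zscores(raw)
        for r, v in z.items():
            setattr(pheno[r], zattr, v)

    for r in rfids:
        zs = [pheno[r].z_escalation, pheno[r].z_motivation,
              pheno[r].z_compulsivity]
        if all(v is not None for v in zs):
            pheno[r].addiction_index = float(np.mean(zs))
    return pheno


# ---------------------------------------------------------------------------
# build_stable
# ---------------------------------------------------------------------------

@dataclass
class StableRelease:
    """A versioned, immutable curated release of the combined table."""

    version: str
    stable: pd.DataFrame          # rfid, phase, session, variable, value, flag
    phenotypes: pd.DataFrame      # one row per rfid
    params: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        stable_path = outdir / f"stable_{self.version}.csv"
        pheno_path = outdir / f"phenotypes_{self.version}.csv"
        sidecar_path = outdir / f"stable_{self.version}.json"
        if stable_path.exists() or sidecar_path.exists():
            raise ReleaseExistsError(
                f"release {self.version!r} already exists at {outdir}; "
                "stable releases are immutable")
        outdir.mkdir(parents=True, exist_ok=True)
        self.stable.to_csv(stable_path, index=False)
        self.phenotypes.to_csv(pheno_path, index=False)
        sidecar = dict(self.params)
        sidecar["version"] = self.version
        sidecar["ai_formula_hash"] = hashlib.sha256(
            sidecar.get("ai_formula", "").encode()).hexdigest()
        sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))


AI_FORMULA = ("addiction_index = mean(z(escalation_slope_lga), "
              "z(mean_pr_breakpoint), z(shock_resistance))")


def build_stable(combined: pd.DataFrame, *, cap: int = DEFAULT_CAP,
                 version: str = "v1",
                 population: set[str] | None = None) -> StableRelease:
    """Apply outlier handling then imputation per rat/variable/phase, attach
    derived phenotypes, and stamp a release version.

    The session axis of each phase is the cohort-wide union of session
    tokens, so a rat's missing sessions appear as gaps eligible for
    imputation. Deterministic: rerunning on the same input yields an
    identical release.
    """
    long_rows = []
    series_store: dict[str, dict[str, CuratedSeries]] = {}
    all_series: dict[tuple, CuratedSeries] = {}
    for phase in SESSION_TYPES:
        sub = combined[combined["session_type"] == phase]
        if sub.empty:
            continue
        axis = sorted(sub["session_token"].unique(), key=session_sort_key)
        for rfid, grp in sub.groupby("rfid"):
            by_token = {t.session_token: t for t in grp.itertuples()}
            curated: dict[str, CuratedSeries] = {}
            for var in VARIABLES:
                col = _VAR_COLUMN[var]
                values = [getattr(by_token[t], col) if t in by_token else np.nan
                          for t in axis]
                curated[var] = CuratedSeries.from_values(rfid, var, axis, values)
            inf, act = handle_outliers(curated["infusions"],
                                       curated["active"], cap=cap)
            curated["infusions"], curated["active"] = inf, act
            for var in VARIABLES:
                curated[var] = impute_missing(curated[var])
                all_series[(rfid, phase, var)] = curated[var]
            series_store.setdefault(rfid, {})[phase] = curated["infusions"]

    for (rfid, phase, var), s in sorted(all_series.items()):
        for tok, val, flag in zip(s.sessions, s.values, s.flags):
            long_rows.append({"rfid": rfid, "phase": phase, "session": tok,
                              "variable": var,
                              "value": None if np.isnan(val) else float(val),
                              "flag": flag})
    stable = pd.DataFrame(long_rows, columns=["rfid", "phase", "session",
                                              "variable", "value", "flag"])

    pr_bps: dict[str, list[float]] = {}
    for row in combined[combined["session_type"] == "PR"].itertuples():
        if row.breakpoint is not None and not pd.isna(row.breakpoint):
            pr_bps.setdefault(row.rfid, []).append(float(row.breakpoint))
    shock_inf: dict[str, list[float]] = {}
    for row in combined[combined["session_type"] == "SHOCK"].itertuples():
        v = row.infusions_after_shock
        if v is not None and not pd.isna(v):
            shock_inf.setdefault(row.rfid, []).append(float(v))

    if population is None:
        drug = combined[combined["experiment_group"] == "drug"]["rfid"]
        population = set(drug.unique()) or set(combined["rfid"].unique())
    pheno = compute_derived(series_store, pr_bps, shock_inf, population)
    pheno_df = pd.DataFrame([vars(p) for p in
                             (pheno[r] for r in sorted(pheno))])

    params = {"cap": cap, "imputation": "single-gap linear / single-edge "
              "nearest-neighbor (mean of 2); multi-gaps left missing",
              "ai_formula": AI_FORMULA,
              "population_size": len(population),
              "built": dt.date.today().isoformat()}
    return StableRelease(version=version, stable=stable,
                         phenotypes=pheno_df, params=params)


__all__ = [
    "CuratedSeries", "DerivedPhenotypes", "StableRelease",
    "DEFAULT_CAP", "VARIABLES",
    "FLAG_OBSERVED", "FLAG_REMOVED", "FLAG_CAPPED", "FLAG_LINEAR",
    "FLAG_NN", "FLAG_MISSING",
    "handle_outliers", "impute_missing", "escalation_slope",
    "compute_derived", "build_stable",
]
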