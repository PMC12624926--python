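"""Brute-force curation oracle, used only for verification.

Recomputes, from the generator's ground truth alone and with straight-line
unoptimized loops, what the curated (stable) table must contain: the
exclusion set, the outlier rule (single >250 session removed together with
its active presses; two or more capped at 250), the imputation rule (single
interior gap = mean of neighbors; single edge gap = mean of the two nearest
on the observed side; longer gaps untouched), and the derived phenotypes.
Deliberately written without importing :mod:`operantdb.curation` so the two
paths stay independent.
"""

from __future__ import annotations

import math

from .generator import GroundTruth

_CAP = 250
_PHASES = ("SHA", "LGA", "PR", "SHOCK")
_VARIABLES = ("infusions", "active", "inactive")


def _phase_tokens(truth: GroundTruth, phase: str) -> list[str]:
    toks = [t for t in truth.session_dates if t[:-2] == phase]
    return sorted(toks, key=lambda t: int(t[-2:]))


def _excluded(truth: GroundTruth) -> set[tuple[str, str]]:
    return {tuple(p) for p in truth.expected_excluded}


def _raw_value(truth: GroundTruth, rfid: str, tok: str, var: str):
    """Value as it would appear in the combined table, or None for a gap."""
    if [rfid, tok] in truth.missing or (rfid, tok) in _excluded(truth):
        return None
    sess = truth.sessions.get(rfid, {}).get(tok)
    if sess is None:
        return None
    return float(sess[var])


def _curate_rat_phase(truth, rfid, phase):
    toks = _phase_tokens(truth, phase)
    series = {var: [_raw_value(truth, rfid, t, var) for t in toks]
              for var in _VARIABLES}
    flags = {var: ["observed" if v is not None else "missing"
                   for v in series[var]] for var in _VARIABLES}

    # outlier rule on the infusion/active pair
    over = [i for i, v in enumerate(series["infusions"])
            if v is not None and v > _CAP]
    if len(over) == 1:
        i = over[0]
        series["infusions"][i] = None
        flags["infusions"][i] = "removed_outlier"
        series["active"][i] = None
        flags["active"][i] = "removed_outlier"
    elif len(over) >= 2:
        for i in over:
            series["infusions"][i] = float(_CAP)
            flags["infusions"][i] = "capped"

    # imputation, variable by variable
    for var in _VARIABLES:
        vals, flg = series[var], flags[var]
        n = len(vals)
        if sum(v is not None for v in vals) < 2:
            continue
        out_vals, out_flg = list(vals), list(flg)
        for j in range(n):
            if vals[j] is not None:
                continue
            left_missing = j > 0 and vals[j - 1] is None
            right_missing = j < n - 1 and vals[j + 1] is None
            if left_missing or right_missing:
                continue  # part of a multi-session gap
            if 0 < j < n - 1:
                out_vals[j] = (vals[j - 1] + vals[j + 1]) / 2.0
                out_flg[j] = "imputed_linear"
            else:
                if j == 0:
                    neighbors = [v for v in vals[1:] if v is not None][:2]
                else:
                    neighbors = [v for v in reversed(vals[:-1])
                                 if v is not None][:2]
                out_vals[j] = sum(neighbors) / len(neighbors)
                out_flg[j] = "imputed_nn"
        series[var], flags[var] = out_vals, out_flg
    return toks, series, flags


def oracle_curate(truth: GroundTruth) -> dict:
    """Expected stable table and phenotypes.

    Returns ``{"stable": {(rfid, phase, session, variable): (value, flag)},
    "phenotypes": {rfid: {...}}}`` with values None where missing.
    """
    rfids = sorted(truth.sessions)
    stable: dict[tuple, tuple] = {}
    lga_series: dict[str, list] = {}
    all_series: dict[str, dict[str, list]] = {}
    for rfid in rfids:
        all_series[rfid] = {}
        for phase in _PHASES:
            toks = _phase_tokens(truth, phase)
            if not toks:
                continue
            if not any(_raw_value(truth, rfid, t, "infusions") is not None
                       for t in toks):
                continue
            toks, series, flags = _curate_rat_phase(truth, rfid, phase)
            for var in _VARIABLES:
                for t, v, f in zip(toks, series[var], flags[var]):
                    stable[(rfid, phase, t, var)] = (v, f)
            all_series[rfid][phase] = series["infusions"]
            if phase == "LGA":
                lga_series[rfid] = series["infusions"]

    phen: dict[str, dict] = {}
    for rfid in rfids:
        p = {"escalation_index": None, "intake_total": None,
             "pr_breakpoint_summary": None, "shock_resistance": None}
        lga = lga_series.get(rfid)
        if lga is not None:
            pts = [(k + 1, v) for k, v in enumerate(lga) if v is not None]
            if len(pts) >= 2:
                xm = sum(x for x, _ in pts) / len(pts)
                ym = sum(y for _, y in pts) / len(pts)
                sxx = sum((x - xm) ** 2 for x, _ in pts)
                sxy = sum((x - xm) * (y - ym) for x, y in pts)
                p["escalation_index"] = sxy / sxx
        total, seen = 0.0, False
        for phase_vals in all_series[rfid].values():
            for v in phase_vals:
                if v is not None:
                    total += v
                    seen = True
        p["intake_total"] = total if seen else None
        excl = _excluded(truth)
        bps = [truth.sessions[rfid][t]["breakpoint"]
               for t in _phase_tokens(truth, "PR")
               if [rfid, t] not in truth.missing and (rfid, t) not in excl
               and t in truth.sessions.get(rfid, {})]
        if bps:
            p["pr_breakpoint_summary"] = sum(bps) / len(bps)
        shocks = [truth.sessions[rfid][t]["infusions_after_shock"]
                  for t in _phase_tokens(truth, "SHOCK")
                  if [rfid, t] not in truth.missing
                  and (rfid, t) not in excl
                  and t in truth.sessions.get(rfid, {})]
        if shocks and lga is not None:
            base = [v for v in lga if v is not None]
            if base and sum(base) / len(base) > 0:
                p["shock_resistance"] = (sum(shocks) / len(shocks)) \
                    / (sum(base) / len(base))
        phen[rfid] = p

    for attr, zattr in (("escalation_index", "z_escalation"),
                        ("pr_breakpoint_summary", "z_motivation"),
                        ("shock_resistance", "z_compulsivity")):
        vals = [phen[r][attr] for r in rfids if phen[r][attr] is not None]
        if len(vals) >= 2:
            mean = sum(vals) / len(vals)
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals)
                           / (len(vals) - 1))
        else:
            mean, sd = 0.0, 0.0
        for r in rfids:
            v = phen[r][attr]
            phen[r][zattr] = ((v - mean) / sd
                              if v is not None and sd > 0 else None)
    for r in rfids:
        zs = [phen[r]["z_escalation"], phen[r]["z_motivation"],
              phen[r]["z_compulsivity"]]
        phen[r]["addiction_index"] = (sum(zs) / 3.0
                                      if all(z is not None for z in zs)
                                      else None)
    return {"stable": stable, "phenotypes": phen}
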