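"""Behavior matrix, trace panels, intervals, rasters, gap diagnostics."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from operantdb import reporting, store
from operantdb.medpc_io import SessionRecord
from operantdb.reporting import (build_behavior_matrix, build_event_raster,
                                 build_trace_report, diagnose_gaps,
                                 inter_infusion_intervals, session_rasters,
                                 write_behavior_matrix, write_trace_report)
from operantdb.synth_fixtures import CohortSimConfig, generate_cohort

from conftest import ingest_cohort, make_config


def _record(infusion_ts, hours=2.0):
    start = dt.datetime(2024, 1, 8, 9, 0)
    return SessionRecord(
        subject_id="R001", box=1, program="OXY_SHA",
        start_datetime=start,
        end_datetime=start + dt.timedelta(hours=hours),
        total_infusions=len(infusion_ts), total_active=len(infusion_ts),
        total_inactive=0, infusion_ts=list(infusion_ts),
        active_ts=list(infusion_ts), inactive_ts=[], timeout_ts=[])


class TestInterInfusionIntervals:
    @pytest.mark.parametrize("ts,expected", [
        ([0.0, 30.0, 90.0], [30.0, 60.0]),
        ([], []),
        ([42.0], []),
    ])
    def test_examples(self, ts, expected):
        intervals, _ = inter_infusion_intervals(_record(ts))
        assert list(intervals) == expected

    @given(st.lists(st.floats(min_value=0, max_value=7200,
                              allow_nan=False), min_size=0, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_interval_conservation(self, ts):
        """Sum of intervals equals the timestamp span, always."""
        ts = sorted(ts)
        intervals, (counts, edges) = inter_infusion_intervals(ts)
        if len(ts) > 1:
            assert intervals.sum() == pytest.approx(ts[-1] - ts[0])
            assert counts.sum() == len(intervals)
        else:
            assert len(intervals) == 0

    def test_fr1_sessions_respect_timeout(self, cohort):
        """Generated FR1 sessions never have infusions closer than the 20-s
        post-infusion timeout."""
        _, truth = cohort
        n_checked = 0
        outlier_keys = {(o["rfid"], o["session"]) for o in truth.outliers}
        for rfid, sessions in truth.sessions.items():
            for tok, sess in sessions.items():
                if (rfid, tok) in outlier_keys:
                    continue
                intervals, _ = inter_infusion_intervals(sess["infusion_ts"])
                if len(intervals):
                    assert intervals.min() >= 20.0
                    n_checked += 1
        assert n_checked > 50

    def test_histogram_bin_width_configurable(self):
        _, (counts, edges) = inter_infusion_intervals(
            [0.0, 25.0, 120.0], bin_width_s=30.0)
        assert np.diff(edges) == pytest.approx(30.0)
        assert counts.sum() == 2


class TestEventRaster:
    def test_raster_within_duration(self, cohort_db):
        db, truth = cohort_db
        rfid = truth.rats[0]["rfid"]
        rasters = session_rasters(db, rfid)
        assert rasters
        for r in rasters:
            for ts in (r.active_ts, r.inactive_ts, r.timeout_ts,
                       r.infusion_ts):
                assert all(0 <= t <= r.duration_s for t in ts)

    def test_out_of_range_timestamp_rejected(self):
        rec = _record([100.0, 7201.0])
        with pytest.raises(ValueError, match="outside"):
            build_event_raster(rec)


class TestBehaviorMatrix:
    def test_dimensions_match_fixture(self, cohort_db):
        db, truth = cohort_db
        m = build_behavior_matrix(db, "C01")
        n_animals = len(truth.rats)
        tokens = set(truth.session_dates)
        for var in ("infusions", "active", "inactive"):
            assert m.bodies[var].shape == (n_animals, len(tokens))

    def test_breakpoint_block_covers_pr_columns_only(self, cohort_db):
        db, truth = cohort_db
        m = build_behavior_matrix(db, "C01")
        assert all(c.startswith("PR") for c in m.bodies["breakpoint"].columns)
        assert not any(c.startswith("PR")
                       for c in m.bodies["infusions"].columns
                       if c.startswith("SHOCK"))
        assert set(m.bodies["total_shocks"].columns) == \
            {t for t in truth.session_dates if t.startswith("SHOCK")}

    def test_cell_blank_iff_no_record(self, cohort_db):
        db, truth = cohort_db
        m = build_behavior_matrix(db, "C01")
        body = m.bodies["infusions"]
        missing = {tuple(p) for p in truth.missing}
        for rfid in body.index:
            for tok in body.columns:
                cell = body.at[rfid, tok]
                if (rfid, tok) in missing:
                    assert cell == ""
                else:
                    assert cell != ""

    def test_cells_equal_store_values(self, cohort_db):
        """No recomputation drift: matrix cells are the stored counts."""
        db, _ = cohort_db
        m = build_behavior_matrix(db, "C01")
        operant = db.operant()
        for r in operant.itertuples():
            assert m.bodies["infusions"].at[r.rfid, r.session_token] == \
                r.total_infusions

    def test_leading_trailing_columns(self, cohort_db):
        db, truth = cohort_db
        m = build_behavior_matrix(db, "C01")
        assert list(m.leading.columns) == ["subject_id", "rfid",
                                           "drug_group", "experiment_group"]
        assert list(m.trailing.columns) == ["last_good_session", "exit_date",
                                            "exit_code", "notes"]
        for ex in truth.exits:
            assert m.trailing.at[ex["rfid"], "last_good_session"] == \
                ex["last_good_session"]

    def test_header_rows_and_write(self, cohort_db, tmp_path):
        db, truth = cohort_db
        m = build_behavior_matrix(db, "C01")
        assert list(m.header.index) == ["date", "session_id", "issues",
                                        "issue_notes"]
        for iss in truth.issues:
            assert iss["issue_code"] in m.header.at["issues",
                                                    iss["session_id"]]
        out = write_behavior_matrix(m, tmp_path / "C01_behavior.xlsx")
        assert out.exists()
        assert (tmp_path / "C01_behavior_infusions.csv").exists()


class TestTraceReport:
    def test_means_match_brute_force(self, cohort_db):
        """Every cohort/male/female mean and SEM equals an independent
        recomputation from the combined table."""
        db, truth = cohort_db
        combined = store.combine(db)
        panels = build_trace_report(db, combined)
        sex = {r["rfid"]: r["sex"] for r in truth.rats}
        by_key = {}
        for r in combined.itertuples():
            by_key.setdefault((r.session_type, r.session_token), []).append(
                (r.rfid, r.total_infusions))
        checked = 0
        for p in panels:
            if p.variable != "infusions":
                continue
            for j, tok in enumerate(p.sessions):
                vals = [v for _, v in by_key.get((p.phase, tok), [])]
                male = [v for rf, v in by_key.get((p.phase, tok), [])
                        if sex[rf] == "M"]
                for got_mean, got_sem, ref in ((p.cohort_mean[j],
                                                p.cohort_sem[j], vals),
                                               (p.male_mean[j],
                                                p.male_sem[j], male)):
                    if not ref:
                        assert got_mean is None
                        continue
                    assert got_mean == pytest.approx(np.mean(ref))
                    exp_sem = (0.0 if len(ref) < 2 else
                               np.std(ref, ddof=1) / np.sqrt(len(ref)))
                    assert got_sem == pytest.approx(exp_sem)
                    checked += 1
            break
        assert checked > 0

    def test_excluded_sessions_absent_from_animal_and_means(self, cohort_db):
        db, truth = cohort_db
        combined = store.combine(db)
        panels = build_trace_report(db, combined)
        excluded = {tuple(p) for p in truth.expected_excluded}
        for p in panels:
            for j, tok in enumerate(p.sessions):
                if (p.rfid, tok) in excluded:
                    assert p.animal[j] is None

    def test_identical_animals_have_zero_sem(self, tmp_path):
        cfg = make_config(noise="none", seed=5, n_subjects=4,
                          n_single_outlier_rats=0, n_multi_outlier_rats=0,
                          n_missing_sessions=0, n_keep_issues=0,
                          n_discard_issues=0, n_exits=0,
                          escalation_mean=0.0, escalation_sd=0.0)
        outdir = tmp_path / "ident"
        generate_cohort(cfg, outdir)
        db = ingest_cohort(outdir)
        combined = store.combine(db)
        panels = build_trace_report(db, combined)
        sha_inf = [p for p in panels
                   if p.phase == "SHA" and p.variable == "infusions"]
        # noise-free SHA sessions are identical across rats
        for p in sha_inf:
            for j in range(len(p.sessions)):
                assert p.animal[j] == p.cohort_mean[j]
                assert p.cohort_sem[j] == 0.0
        db.close()

    def test_unknown_animal_rejected(self, cohort_db):
        db, _ = cohort_db
        combined = store.combine(db)
        with pytest.raises(Exception, match="not in database"):
            build_trace_report(db, combined, rfids=["nope"])

    def test_json_sidecar_written(self, cohort_db, tmp_path):
        db, _ = cohort_db
        combined = store.combine(db)
        panels = build_trace_report(db, combined,
                                    rfids=[combined["rfid"].iloc[0]])
        out = write_trace_report(panels, tmp_path, pdf=True)
        assert out.exists()
        assert (tmp_path / "trace_report.pdf").exists()


class TestGapDiagnostics:
    def test_complete_fixture_yields_empty_report(self, clean_cohort):
        outdir, _ = clean_cohort
        db = ingest_cohort(outdir)
        gaps = diagnose_gaps(db, raw_dir=outdir / "raw")
        assert gaps.empty
        db.close()

    def test_misnamed_file_reported_as_name_mismatch(self, tmp_path):
        cfg = make_config(seed=13, misname_session="LGA03",
                          n_single_outlier_rats=0, n_multi_outlier_rats=0,
                          n_missing_sessions=0, n_keep_issues=0,
                          n_discard_issues=0, n_exits=0)
        outdir = tmp_path / "misnamed"
        truth = generate_cohort(cfg, outdir)
        assert truth.misnamed_files
        db = ingest_cohort(outdir)
        gaps = diagnose_gaps(db, raw_dir=outdir / "raw")
        bad = gaps[gaps["kind"] == "unparseable_file"]
        assert list(bad["filename"]) == truth.misnamed_files
        assert set(bad["reason"]) == {"name mismatch"}
        # the affected rats show up as missing-session gaps
        holes = gaps[gaps["kind"] == "missing_session"]
        affected = {r["rfid"] for r in truth.rats if r["computer"] == "A"}
        assert set(holes["rfid"]) == affected
        assert set(holes["session"]) == {"LGA03"}
        db.close()

    def test_missing_session_reported(self, cohort_db):
        db, truth = cohort_db
        gaps = diagnose_gaps(db)
        holes = {(r.rfid, r.session) for r in gaps.itertuples()
                 if r.kind == "missing_session"}
        assert {tuple(m) for m in truth.missing} <= holes
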