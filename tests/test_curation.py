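"""Outlier handling, imputation, derived phenotypes, and stable builds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from operantdb import curation, store
from operantdb.curation import (CuratedSeries, FLAG_CAPPED, FLAG_LINEAR,
                                FLAG_MISSING, FLAG_NN, FLAG_OBSERVED,
                                FLAG_REMOVED, build_stable, compute_derived,
                                escalation_slope, handle_outliers,
                                impute_missing)
from operantdb.synth_fixtures import oracle_curate

from conftest import ingest_cohort


def series(values, variable="infusions", rfid="X1"):
    sessions = [f"LGA{i + 1:02d}" for i in range(len(values))]
    return CuratedSeries.from_values(rfid, variable, sessions, values)


def pair(inf_values, act_values=None):
    if act_values is None:
        act_values = [v if v is None or not np.isnan(v) else v
                      for v in inf_values]
    return (series([np.nan if v is None else v for v in inf_values]),
            series([np.nan if v is None else v for v in act_values],
                   variable="active"))


class TestOutlierRule:
    def test_single_outlier_removes_infusions_and_active(self):
        inf, act = pair([80, 300, 90], [100, 320, 110])
        inf2, act2 = handle_outliers(inf, act)
        assert np.isnan(inf2.values[1]) and inf2.flags[1] == FLAG_REMOVED
        assert np.isnan(act2.values[1]) and act2.flags[1] == FLAG_REMOVED
        assert list(inf2.values[[0, 2]]) == [80, 90]
        assert list(act2.values[[0, 2]]) == [100, 110]

    def test_multiple_outliers_cap_infusions_only(self):
        inf, act = pair([300, 90, 310], [305, 95, 315])
        inf2, act2 = handle_outliers(inf, act)
        assert list(inf2.values) == [250, 90, 250]
        assert list(inf2.flags) == [FLAG_CAPPED, FLAG_OBSERVED, FLAG_CAPPED]
        assert list(act2.values) == [305, 95, 315]  # untouched

    def test_threshold_is_strict(self):
        """Exactly 250 is a full syringe, not an outlier."""
        inf, act = pair([250, 240, 250], [250, 240, 250])
        inf2, act2 = handle_outliers(inf, act)
        assert list(inf2.values) == [250, 240, 250]
        assert all(f == FLAG_OBSERVED for f in inf2.flags)

    @given(st.lists(st.integers(min_value=0, max_value=1000), min_size=1,
                    max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_post_curation_max_never_exceeds_cap(self, values):
        inf, act = pair(values, values)
        inf2, _ = handle_outliers(inf, act)
        obs = inf2.values[~np.isnan(inf2.values)]
        assert len(obs) == 0 or obs.max() <= 250

    @given(st.lists(st.integers(min_value=0, max_value=1000), min_size=1,
                    max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_values_at_or_below_cap_never_modified(self, values):
        inf, act = pair(values, values)
        inf2, act2 = handle_outliers(inf, act)
        for i, v in enumerate(values):
            if v <= 250:
                assert inf2.values[i] == v
                assert inf2.flags[i] == FLAG_OBSERVED


class TestImputation:
    def test_interior_single_gap_linear_mean(self):
        out = impute_missing(series([10, None, 20]))
        assert list(out.values) == [10, 15, 20]
        assert out.flags[1] == FLAG_LINEAR

    def test_leading_edge_gap_nearest_two(self):
        out = impute_missing(series([None, 10, 20, 30]))
        assert list(out.values) == [15, 10, 20, 30]
        assert out.flags[0] == FLAG_NN

    def test_trailing_edge_gap_nearest_two(self):
        out = impute_missing(series([10, 20, 30, None]))
        assert list(out.values) == [10, 20, 30, 25]
        assert out.flags[3] == FLAG_NN

    def test_interior_multi_gap_left_missing(self):
        out = impute_missing(series([10, None, None, 20]))
        assert np.isnan(out.values[1]) and np.isnan(out.values[2])
        assert list(out.flags[1:3]) == [FLAG_MISSING, FLAG_MISSING]

    def test_edge_multi_gap_left_missing(self):
        out = impute_missing(series([None, None, 10, 20]))
        assert np.isnan(out.values[0]) and np.isnan(out.values[1])

    def test_fewer_than_two_observed_returned_unchanged(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="operantdb.curation"):
            out = impute_missing(series([None, 10, None]))
        assert np.isnan(out.values[0]) and np.isnan(out.values[2])
        assert any("imputation skipped" in r.getMessage()
                   for r in caplog.records)

    def test_observed_cells_never_altered(self):
        vals = [5, None, 9, None, None, 13, None]
        out = impute_missing(series(vals))
        for i, v in enumerate(vals):
            if v is not None:
                assert out.values[i] == v
                assert out.flags[i] == FLAG_OBSERVED

    @given(st.lists(st.one_of(st.none(),
                              st.integers(min_value=0, max_value=250)),
                    min_size=1, max_size=15))
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, values):
        s = series([np.nan if v is None else float(v) for v in values])
        once = impute_missing(s)
        twice = impute_missing(once)
        np.testing.assert_array_equal(once.values, twice.values)
        assert list(once.flags) == list(twice.flags)

    @given(st.lists(st.one_of(st.none(),
                              st.integers(min_value=0, max_value=250)),
                    min_size=3, max_size=15))
    @settings(max_examples=200, deadline=None)
    def test_linear_fill_bounded_by_neighbors(self, values):
        s = series([np.nan if v is None else float(v) for v in values])
        out = impute_missing(s)
        for i, f in enumerate(out.flags):
            if f == FLAG_LINEAR:
                lo = min(s.values[i - 1], s.values[i + 1])
                hi = max(s.values[i - 1], s.values[i + 1])
                assert lo <= out.values[i] <= hi


class TestRuleOrder:
    def test_imputation_never_uses_raw_outlier_values(self):
        """A removed outlier becomes an ordinary missing cell; its fill
        comes from the neighbors, never the >cap raw value."""
        inf, act = pair([100, 900, 120])
        inf2, act2 = handle_outliers(inf, act)
        filled = impute_missing(inf2)
        assert filled.values[1] == 110  # mean of 100, 120 — not near 900
        assert filled.flags[1] == FLAG_LINEAR

    def test_capped_cells_feed_escalation(self):
        inf, act = pair([300, 240, 310])
        inf2, _ = handle_outliers(inf, act)
        slope = escalation_slope(inf2.values)
        assert slope == pytest.approx(0.0, abs=1e-9)  # [250, 240, 250]... symmetric


class TestDerived:
    def _series_map(self, values_by_rat):
        return {r: {"LGA": series(v, rfid=r)} for r, v in
                values_by_rat.items()}

    def test_constant_series_zero_slope(self):
        assert escalation_slope(np.array([50.0] * 10)) == pytest.approx(0.0)

    def test_exact_linear_series_recovers_slope(self):
        vals = np.array([20.0 + 3.0 * k for k in range(14)])
        assert escalation_slope(vals) == pytest.approx(3.0, abs=1e-12)

    def test_slope_with_missing_sessions_keeps_session_numbers(self):
        vals = np.array([10.0, np.nan, 16.0, 19.0])  # slope 3 on x=1,3,4
        assert escalation_slope(vals) == pytest.approx(3.0, abs=1e-12)

    def test_z_scores_standardized_over_population(self):
        rats = {f"r{i}": [10.0 + s * k for k in range(6)]
                for i, s in enumerate([1.0, 2.0, 3.0, 4.0])}
        pheno = compute_derived(self._series_map(rats),
                                pr_breakpoints={r: [5.0] for r in rats},
                                shock_infusions={r: [10.0] for r in rats})
        z = np.array([pheno[r].z_escalation for r in sorted(rats)])
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9

    def test_population_mean_animal_has_zero_ai(self):
        """An animal sitting at the population mean of all three components
        gets z ≈ 0 everywhere and AI ≈ 0."""
        rats = {"lo": [10.0 - 1.0 * k for k in range(6)],
                "mid": [10.0 + 0.0 * k for k in range(6)],
                "hi": [10.0 + 1.0 * k for k in range(6)]}
        # baselines are 7.5 / 10 / 12.5, so these give shock-resistance
        # ratios 0.9 / 1.0 / 1.1 — symmetric around the mid animal
        pheno = compute_derived(
            self._series_map(rats),
            pr_breakpoints={"lo": [4.0], "mid": [5.0], "hi": [6.0]},
            shock_infusions={"lo": [6.75], "mid": [10.0], "hi": [13.75]})
        assert pheno["mid"].z_escalation == pytest.approx(0.0, abs=1e-9)
        assert pheno["mid"].addiction_index == pytest.approx(0.0, abs=1e-9)

    def test_missing_phase_leaves_ai_absent(self):
        rats = {"a": [1.0 * k for k in range(6)],
                "b": [2.0 * k for k in range(6)]}
        pheno = compute_derived(self._series_map(rats),
                                pr_breakpoints={"a": [5.0], "b": [7.0]},
                                shock_infusions={"a": [10.0]})
        assert pheno["b"].shock_resistance is None
        assert pheno["b"].addiction_index is None
        assert pheno["a"].addiction_index is None  # z needs >= 2 values


class TestBuildStable:
    def test_matches_brute_force_oracle(self, cohort_db):
        db, truth = cohort_db
        combined = store.combine(db)
        rel = build_stable(combined, version="vtest")
        exp = oracle_curate(truth)
        got = {(r.rfid, r.phase, r.session, r.variable): (r.value, r.flag)
               for r in rel.stable.itertuples()}
        assert set(got) == set(exp["stable"])
        for key, (v, f) in exp["stable"].items():
            gv, gf = got[key]
            assert gf == f, key
            if v is None:
                assert gv is None or pd.isna(gv)
            else:
                assert gv == pytest.approx(v, abs=1e-9)
        ph = rel.phenotypes.set_index("rfid")
        for rfid, exp_p in exp["phenotypes"].items():
            for name, v in exp_p.items():
                gv = ph.at[rfid, name]
                if v is None:
                    assert gv is None or pd.isna(gv)
                else:
                    assert gv == pytest.approx(v, abs=1e-9), (rfid, name)

    def test_anomaly_free_input_is_identity(self, clean_cohort):
        outdir, truth = clean_cohort
        db = ingest_cohort(outdir)
        combined = store.combine(db)
        rel = build_stable(combined, version="vtest")
        assert set(rel.stable["flag"]) == {FLAG_OBSERVED}
        by_key = {(r.rfid, r.session_token): r for r in combined.itertuples()}
        for row in rel.stable[rel.stable["variable"] == "infusions"].itertuples():
            assert row.value == by_key[(row.rfid, row.session)].total_infusions
        db.close()

    def test_rerun_is_deterministic(self, cohort_db):
        db, _ = cohort_db
        combined = store.combine(db)
        a = build_stable(combined, version="v1")
        b = build_stable(combined, version="v1")
        pd.testing.assert_frame_equal(a.stable, b.stable)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)

    def test_release_refuses_overwrite(self, cohort_db, tmp_path):
        from operantdb.errors import ReleaseExistsError
        db, _ = cohort_db
        combined = store.combine(db)
        rel = build_stable(combined, version="v9")
        rel.write(tmp_path)
        assert (tmp_path / "stable_v9.csv").exists()
        assert (tmp_path / "stable_v9.json").exists()
        with pytest.raises(ReleaseExistsError):
            rel.write(tmp_path)

    def test_noise_free_slope_recovered_exactly(self, clean_cohort):
        """Generator-injected escalation slopes come back exactly through
        the full parse→store→combine→curate path."""
        outdir, truth = clean_cohort
        db = ingest_cohort(outdir)
        combined = store.combine(db)
        rel = build_stable(combined, version="vtest")
        ph = rel.phenotypes.set_index("rfid")
        for rat in truth.rats:
            assert ph.at[rat["rfid"], "escalation_index"] == \
                pytest.approx(rat["slope"], abs=1e-9)
        db.close()
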