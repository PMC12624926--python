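"""Shared fixtures: small synthetic cohorts generated at test time."""

import pathlib

import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True)
settings.load_profile("stable")

from operantdb import medpc_io, store, templates_io
from operantdb.synth_fixtures import CohortSimConfig, generate_cohort

SMALL_PLAN = {"SHA": 2, "LGA": 6, "PR": 2, "SHOCK": 1}


def make_config(**overrides) -> CohortSimConfig:
    base = dict(n_subjects=8, chambers_per_computer=4, phase_plan=SMALL_PLAN,
                seed=7)
    base.update(overrides)
    return CohortSimConfig(**base)


def ingest_cohort(cohort_dir: pathlib.Path, db_path=":memory:") -> store.RawDatabase:
    """Template + raw-file ingest of a generated cohort directory."""
    db = store.RawDatabase(db_path)
    tpl = cohort_dir / "templates"
    db.ingest_cohort_info(templates_io.load_cohort_info(tpl / "cohort_info.csv"))
    db.ingest_issues(templates_io.load_issues(tpl / "issues.csv"))
    db.ingest_exits(templates_io.load_exits(tpl / "exits.csv"))
    for kind, fname in (("vonfrey", "vonfrey.csv"),
                        ("tail_immersion", "tail_immersion.csv"),
                        ("irritability", "irritability.csv")):
        db.ingest_behavior_test(
            templates_io.load_behavior_test(tpl / fname, kind), kind)
    for path in sorted((cohort_dir / "raw").glob("*.txt")):
        try:
            meta = medpc_io.parse_session_filename(path.name)
        except Exception:
            continue
        db.ingest_session(medpc_io.parse_raw_file(path), meta)
    return db


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """A small stochastic cohort with the default anomaly plan."""
    outdir = tmp_path_factory.mktemp("cohort")
    truth = generate_cohort(make_config(), outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def cohort_db(cohort):
    outdir, truth = cohort
    db = ingest_cohort(outdir)
    yield db, truth
    db.close()


@pytest.fixture(scope="session")
def clean_cohort(tmp_path_factory):
    """A noise-free cohort with no anomalies (identity path)."""
    outdir = tmp_path_factory.mktemp("clean")
    cfg = make_config(noise="none", seed=11, n_single_outlier_rats=0,
                      n_multi_outlier_rats=0, n_missing_sessions=0,
                      n_keep_issues=0, n_discard_issues=0, n_exits=0)
    truth = generate_cohort(cfg, outdir)
    return outdir, truth
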