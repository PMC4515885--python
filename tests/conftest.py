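"""Shared fixtures: small generated cohorts, handcrafted long tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from misens import CohortConfig, LongCohort, calibrated_reference, generate_cohort
from misens.synthetic_cohort import LONG_COLUMNS, OUTCOME_VAR


def make_long_cohort(subjects: dict) -> LongCohort:
    """Build a LongCohort from a compact per-subject description.

    ``subjects`` maps subject_id -> dict with keys:
      pre: float (observed pre outcome)
      process: list of (session, value) or (session, value, observed)
      post: float | (value, observed) | None
      dropout: 0/1 (default 0)
    """
    rows = []
    subj_rows = []
    for sid, d in subjects.items():
        occ = 0
        rows.append((sid, "pre", occ, 0, OUTCOME_VAR, float(d["pre"]), True))
        for item in d.get("process", []):
            session, value, *rest = item
            occ += 1
            observed = rest[0] if rest else True
            rows.append((sid, "process", occ, session, OUTCOME_VAR, float(value), observed))
        post = d.get("post")
        if post is not None:
            occ += 1
            if isinstance(post, tuple):
                value, observed = post
            else:
                value, observed = post, True
            last_session = max((it[0] for it in d.get("process", [])), default=0) + 1
            rows.append((sid, "post", occ, last_session, OUTCOME_VAR, float(value), observed))
        subj_rows.append(
            {
                "subject_id": sid,
                "age": d.get("age", 40.0),
                "prior_treatment": d.get("prior_treatment", 0),
                "dropout": d.get("dropout", 0),
                "session_count": max((it[0] for it in d.get("process", [])), default=0),
            }
        )
    measurements = pd.DataFrame(rows, columns=list(LONG_COLUMNS))
    subj_cols = ["subject_id", "age", "prior_treatment", "dropout", "session_count"]
    subjects = pd.DataFrame(subj_rows, columns=subj_cols)
    return LongCohort(measurements, subjects)


@pytest.fixture(scope="session")
def cohort260() -> LongCohort:
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def reference260() -> pd.DataFrame:
    return calibrated_reference(seed=11)


def _termination_block(start_id: int, dropout: int, n_observed: int, n_imputable: int, n_not_imputable: int) -> dict:
    """Subjects for one termination row of the accounting table."""
    subjects = {}
    sid = start_id
    for _ in range(n_observed):
        subjects[sid] = {
            "pre": 80.0,
            "process": [(5, 70.0), (10, 60.0)],
            "post": 55.0,
            "dropout": dropout,
        }
        sid += 1
    for _ in range(n_imputable):
        subjects[sid] = {
            "pre": 80.0,
            "process": [(5, 72.0), (10, 64.0)],
            "post": (60.0, False),
            "dropout": dropout,
        }
        sid += 1
    for _ in range(n_not_imputable):
        subjects[sid] = {
            "pre": 80.0,
            "process": [(5, 75.0)],
            "post": (70.0, False),
            "dropout": dropout,
        }
        sid += 1
    return subjects


@pytest.fixture(scope="session")
def termination_cohort() -> LongCohort:
    """Cohort reproducing the published termination/missingness composition.

    Completers (mutual-consent termination): 181 with observed post, 27 with
    imputable missing outcome, 4 not imputable; dropouts (patient-decided
    discontinuation): 29 / 23 / 22.  Total 286.
    """
    subjects = {}
    subjects.update(_termination_block(0, dropout=0, n_observed=181, n_imputable=27, n_not_imputable=4))
    subjects.update(_termination_block(1000, dropout=1, n_observed=29, n_imputable=23, n_not_imputable=22))
    return make_long_cohort(subjects)
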