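import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from crowddx import (
    AnswerKey,
    StudyDesign,
    SynonymMap,
    SyntheticConfig,
    score,
    standardize,
)

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("det")


@pytest.fixture
def design():
    """Small between-subject design: 2 conditions sharing 3 cases, scale 1-8."""
    cases = ("c1", "c2", "c3")
    return StudyDesign(
        name="toy",
        assignment="between_subject",
        conditions=("control", "early_dss"),
        cases_per_condition={"control": cases, "early_dss": cases},
        confidence_scale=(1, 8),
    )


@pytest.fixture
def ratings_csv():
    return io.StringIO(
        "gp_id,case_id,condition,diagnosis,confidence,seniority_years\n"
        "g1,c1,control,Angina,5,12\n"
        "g1,c2,control, GERD ,6,12\n"
        "g1,c3,control,asthma,4,12\n"
    )


@pytest.fixture
def answer_key():
    return AnswerKey({"c1": "stable angina", "c2": "gerd", "c3": "copd"})


def make_records(rows, *, seniority=10.0, confidence=5.0):
    """Build a scored rating table from (gp, case, condition, diagnosis,
    correct_label) tuples; diagnosis equal to correct_label scores correct."""
    recs = pd.DataFrame(
        [
            {
                "gp_id": gp,
                "case_id": case,
                "condition": cond,
                "diagnosis_raw": dx,
                "diagnosis_std": pd.NA,
                "confidence": confidence,
                "seniority_years": seniority,
                "correct": pd.NA,
            }
            for gp, case, cond, dx in rows
        ]
    )
    recs["diagnosis_std"] = recs["diagnosis_std"].astype("string")
    recs["correct"] = recs["correct"].astype("boolean")
    return recs


@pytest.fixture
def iid_panel():
    """Panel of raters with i.i.d. categorical votes on a single case: a
    direct match for the multinomial oracle."""

    def _make(probs, n_gps, case="c1", condition="control", seed=0):
        rng = np.random.default_rng(seed)
        labels = [f"dx{i}" for i in range(len(probs))]
        votes = rng.choice(len(probs), size=n_gps, p=list(probs))
        rows = [
            (f"g{i:03d}", case, condition, labels[v]) for i, v in enumerate(votes)
        ]
        recs = make_records(rows)
        recs = standardize(recs, SynonymMap())
        key = AnswerKey({case: labels[0]})
        return score(recs, key), key

    return _make


def tiny_config(**overrides):
    """Minimal valid synthetic config, adjustable per test."""
    cases = ("c1", "c2", "c3")
    base = dict(
        design=StudyDesign(
            name="toy",
            assignment="between_subject",
            conditions=("control", "early_dss"),
            cases_per_condition={"control": cases, "early_dss": cases},
            confidence_scale=(1, 8),
        ),
        n_gps=20,
        easiness={"c1": 0.0, "c2": 0.5, "c3": -0.5},
        sigma_g=0.5,
        delta_cond={"control": 0.0, "early_dss": 0.3},
        correct_labels={c: f"{c}_true" for c in cases},
        wrong_labels={
            c: {f"{c}_w1": 0.5, f"{c}_w2": 0.3, f"{c}_w3": 0.2} for c in cases
        },
        conf_mean=5.0,
        conf_sd=1.5,
        conf_shift=0.5,
        seniority_bands=((0, 10, 0.6), (11, 20, 0.25), (21, 40, 0.15)),
        gamma=-0.02,
        seed=7,
    )
    base.update(overrides)
    return SyntheticConfig(**base)
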