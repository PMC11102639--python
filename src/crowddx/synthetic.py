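"""Synthetic rater-response generator.

The original rating datasets (GPs diagnosing standardized patient cases with
or without a decision-support system, DSS) are not publicly deposited, so
this module generates datasets with the same statistical structure, making
every downstream stage testable.

Generative model (all effects on the log-odds scale):

    P(GP g correct on case c in condition d) = logistic(e_c + s_g + delta_d)

where ``e_c`` is case easiness, ``delta_d`` a condition (DSS) effect with
``delta_control = 0``, and GP skill ``s_g ~ Normal(gamma * (years_g - mean
years), sigma_g)`` links skill weakly to seniority (``gamma < 0`` emulates
the observed weak negative seniority-accuracy association). An incorrect
response draws its diagnosis from a per-case wrong-answer alphabet with
weights ``w``; concentrating ``w`` on one label makes raters' errors
correlated (they converge on the same wrong diagnosis), which is the key
adversary of the plurality rule. Confidence is a latent normal, mean-shifted
by ``conf_shift`` for correct responses, discretized and clamped to the
design's ordinal scale; ``conf_shift = 0`` gives the null
confidence-accuracy association seen in the actor-patient study.

All generation is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .datamodel import RATING_COLUMNS, AnswerKey, StudyDesign

__all__ = [
    "SyntheticConfig",
    "sample_population",
    "simulate_response",
    "generate_study",
    "calibrate_easiness",
    "calibrate_condition_effect",
    "build_preset",
    "load_preset",
    "PRESET_NAMES",
]

PRESET_NAMES = ("vignette_like", "actor_patient_like")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class SyntheticConfig:
    """Full generative parameterization of a simulated study.

    Parameters
    ----------
    design:
        The study design (assignment scheme, conditions, case lists,
        confidence scale).
    n_gps:
        GPs per condition for a between-subject design; total GPs for a
        within-subject design.
    easiness:
        Case easiness ``e_c`` on the log-odds scale, per case id.
    sigma_g:
        Standard deviation of GP skill (log-odds).
    delta_cond:
        Condition effect per condition (log-odds); control must be 0.
    correct_labels:
        The single correct standardized diagnosis per case.
    wrong_labels:
        Per case: mapping wrong label -> weight (positive, summing to 1).
        Concentrated weights produce correlated errors.
    wrong_labels_by_condition:
        Optional per-condition overrides of ``wrong_labels`` (e.g. a DSS that
        also disperses errors).
    conf_mean, conf_sd, conf_shift:
        Latent confidence Normal(conf_mean + conf_shift * correct, conf_sd),
        rounded and clamped to the design's confidence scale.
    seniority_bands:
        Tuple of ``(lo, hi, weight)`` year bands; a GP draws a band by weight
        and an integer year uniformly within it.
    gamma:
        Skill-seniority slope (log-odds per year of experience).
    seed:
        Master seed; every sampling operation derives from it.
    """

    design: StudyDesign
    n_gps: int
    easiness: dict[str, float]
    sigma_g: float
    delta_cond: dict[str, float]
    correct_labels: dict[str, str]
    wrong_labels: dict[str, dict[str, float]]
    conf_mean: float
    conf_sd: float
    conf_shift: float
    seniority_bands: tuple[tuple[int, int, float], ...]
    gamma: float
    seed: int = 0
    wrong_labels_by_condition: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        self.seniority_bands = tuple(tuple(b) for b in self.seniority_bands)
        if self.n_gps < 1:
            raise ValueError("n_gps must be positive")
        if self.sigma_g < 0 or self.conf_sd <= 0:
            raise ValueError("sigma_g must be >= 0 and conf_sd > 0")
        for cond in self.design.conditions:
            self.delta_cond.setdefault(cond, 0.0)
        if abs(self.delta_cond.get("control", 0.0)) > 1e-12:
            raise ValueError("control condition effect must be 0")
        for case in self.design.all_cases:
            if case not in self.easiness:
                raise ValueError(f"no easiness for case {case!r}")
            if case not in self.correct_labels:
                raise ValueError(f"no correct label for case {case!r}")
            self._check_weights(self.wrong_labels.get(case), case)
        for cond, per_case in self.wrong_labels_by_condition.items():
            for case, w in per_case.items():
                self._check_weights(w, case)
        total_w = sum(b[2] for b in self.seniority_bands)
        if not math.isclose(total_w, 1.0, abs_tol=1e-9):
            raise ValueError("seniority band weights must sum to 1")

    @staticmethod
    def _check_weights(weights: dict[str, float] | None, case: str) -> None:
        if not weights:
            raise ValueError(f"case {case!r} needs a wrong-answer alphabet (>= 1 label)")
        vals = list(weights.values())
        if any(v <= 0 for v in vals):
            raise ValueError(f"case {case!r}: wrong-answer weights must be positive")
        if not math.isclose(sum(vals), 1.0, abs_tol=1e-9):
            raise ValueError(f"case {case!r}: wrong-answer weights must sum to 1")

    # -- derived quantities -------------------------------------------------

    @property
    def mean_years(self) -> float:
        """Expected years of experience under the band mixture."""
        return sum(w * (lo + hi) / 2.0 for lo, hi, w in self.seniority_bands)

    def wrong_weights(self, case: str, condition: str) -> dict[str, float]:
        override = self.wrong_labels_by_condition.get(condition, {})
        return override.get(case, self.wrong_labels[case])

    def answer_key(self) -> AnswerKey:
        return AnswerKey(dict(self.correct_labels))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"] = {
            "name": self.design.name,
            "assignment": self.design.assignment,
            "conditions": list(self.design.conditions),
            "cases_per_condition": {
                c: list(v) for c, v in self.design.cases_per_condition.items()
            },
            "confidence_scale": list(self.design.confidence_scale),
        }
        d["seniority_bands"] = [list(b) for b in self.seniority_bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        dd = d.pop("design")
        design = StudyDesign(
            name=dd["name"],
            assignment=dd["assignment"],
            conditions=tuple(dd["conditions"]),
            cases_per_condition={c: tuple(v) for c, v in dd["cases_per_condition"].items()},
            confidence_scale=tuple(dd["confidence_scale"]),
        )
        d["seniority_bands"] = tuple(tuple(b) for b in d["seniority_bands"])
        return cls(design=design, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, source) -> "SyntheticConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        return cls.from_dict(d)


# -- population -------------------------------------------------------------


def _sample_years(config: SyntheticConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    bands = config.seniority_bands
    idx = rng.choice(len(bands), size=n, p=[b[2] for b in bands])
    lo = np.array([bands[i][0] for i in idx])
    hi = np.array([bands[i][1] for i in idx])
    return lo + rng.integers(0, hi - lo + 1)  # integer years, inclusive bounds


def sample_population(config: SyntheticConfig) -> pd.DataFrame:
    """Draw the GP population: skill, seniority, condition assignment.

    Between-subject designs assign ``n_gps`` GPs to each condition;
    within-subject designs assign all ``n_gps`` GPs to every condition.
    Deterministic given ``config.seed``. Returns a DataFrame with columns
    ``gp_id, skill, seniority_years, conditions`` (tuple of assigned
    condition labels).
    """
    rng = np.random.default_rng([config.seed, 0])
    if config.design.assignment == "between_subject":
        n_total = config.n_gps * len(config.design.conditions)
        conditions = [
            (cond,) for cond in config.design.conditions for _ in range(config.n_gps)
        ]
    else:
        n_total = config.n_gps
        conditions = [tuple(config.design.conditions)] * n_total
    years = _sample_years(config, n_total, rng)
    skill = rng.normal(config.gamma * (years - config.mean_years), config.sigma_g)
    width = len(str(n_total - 1))
    return pd.DataFrame(
        {
            "gp_id": [f"gp{i:0{width}d}" for i in range(n_total)],
            "skill": skill,
            "seniority_years": years.astype(float),
            "conditions": conditions,
        }
    )


# -- responses --------------------------------------------------------------


def _discretize_confidence(
    latent: np.ndarray, scale: tuple[int, int]
) -> np.ndarray:
    lo, hi = scale
    return np.clip(np.rint(latent), lo, hi)


def simulate_response(
    gp, case_id: str, condition: str, config: SyntheticConfig, rng: np.random.Generator
) -> dict:
    """Simulate one GP's response to one case in one condition.

    Returns a record dict with the rating-table fields; ``diagnosis_std`` and
    ``correct`` are left unset (the record flows through the standard scoring
    path downstream).
    """
    if condition not in gp["conditions"]:
        raise ValueError(f"{gp['gp_id']} is not assigned to condition {condition!r}")
    p = float(
        _expit(config.easiness[case_id] + gp["skill"] + config.delta_cond[condition])
    )
    correct = bool(rng.random() < p)
    if correct:
        diagnosis = config.correct_labels[case_id]
    else:
        weights = config.wrong_weights(case_id, condition)
        labels = list(weights)
        diagnosis = labels[rng.choice(len(labels), p=list(weights.values()))]
    latent = rng.normal(config.conf_mean + config.conf_shift * correct, config.conf_sd)
    confidence = float(_discretize_confidence(np.array([latent]), config.design.confidence_scale)[0])
    return {
        "gp_id": gp["gp_id"],
        "case_id": case_id,
        "condition": condition,
        "diagnosis_raw": diagnosis,
        "diagnosis_std": pd.NA,
        "confidence": confidence,
        "seniority_years": gp["seniority_years"],
        "correct": pd.NA,
        "p_correct": p,
    }


def generate_study(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full study: one record per GP x assigned condition x case.

    Returns ``(records, truth)``: the rating table (unscored; run it through
    ``standardize`` and ``score`` like real data) and a truth table with the
    per-response success probability ``p_correct`` for parameter-recovery
    checks.
    """
    population = sample_population(config)
    rng = np.random.default_rng([config.seed, 1])
    rows = []
    for gp in population.to_dict("records"):
        for condition in gp["conditions"]:
            for case_id in config.design.cases_per_condition[condition]:
                rows.append(simulate_response(gp, case_id, condition, config, rng))
    df = pd.DataFrame(rows)
    truth = df[["gp_id", "case_id", "condition", "p_correct"]].copy()
    records = df[list(RATING_COLUMNS)].copy()
    records["diagnosis_std"] = records["diagnosis_std"].astype("string")
    records["correct"] = records["correct"].astype("boolean")
    return records, truth


# -- calibration ------------------------------------------------------------


def _calibration_draws(
    config: SyntheticConfig, condition: str, n: int, rng: np.random.Generator
):
    """Common random numbers for the monotone accuracy(offset) search."""
    cases = config.design.cases_per_condition[condition]
    e = np.array([config.easiness[c] for c in cases])[rng.integers(0, len(cases), n)]
    years = _sample_years(config, n, rng)
    skill = rng.normal(config.gamma * (years - config.mean_years), config.sigma_g)
    u = rng.random(n)
    return e + skill + config.delta_cond[condition], u


def _bisect_offset(base: np.ndarray, u: np.ndarray, target: float, tol: float) -> float:
    def acc(offset: float) -> float:
        return float(np.mean(u < _expit(base + offset)))

    lo, hi = -12.0, 12.0
    if acc(lo) > target + tol or acc(hi) < target - tol:
        raise ValueError(
            f"target accuracy {target} unattainable with the configured skill spread"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if acc(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_easiness(
    target_accuracy: float,
    config: SyntheticConfig,
    *,
    n: int = 50_000,
    tol: float = 0.01,
) -> dict[str, float]:
    """Shift all case easiness values by a common offset so that mean
    individual accuracy in the control condition hits ``target_accuracy``.

    Monotone bisection with common random numbers at ``n`` simulated
    responses; the returned easiness dict puts the simulated control accuracy
    within ``tol`` of the target. Raises if the target is unattainable.
    """
    if not 0.0 < target_accuracy < 1.0:
        raise ValueError("target accuracy must lie in (0, 1)")
    rng = np.random.default_rng([config.seed, 51_966])
    base, u = _calibration_draws(config, "control", n, rng)
    offset = _bisect_offset(base, u, target_accuracy, tol)
    return {c: e + offset for c, e in config.easiness.items()}


def calibrate_condition_effect(
    target_accuracy: float,
    condition: str,
    config: SyntheticConfig,
    *,
    n: int = 50_000,
    tol: float = 0.01,
) -> float:
    """Find the condition effect ``delta`` putting mean individual accuracy
    in ``condition`` at ``target_accuracy`` (easiness held fixed)."""
    if not 0.0 < target_accuracy < 1.0:
        raise ValueError("target accuracy must lie in (0, 1)")
    if condition == "control":
        raise ValueError("the control effect is fixed at 0; calibrate easiness instead")
    rng = np.random.default_rng([config.seed, 51_967])
    cfg0 = replace(config, delta_cond={**config.delta_cond, condition: 0.0})
    base, u = _calibration_draws(cfg0, condition, n, rng)
    return _bisect_offset(base, u, target_accuracy, tol)


# -- presets ----------------------------------------------------------------


def _vignette_case_table() -> tuple[dict[str, str], dict[str, dict[str, float]]]:
    """Illustrative diagnosis vocabulary: 3 presenting problems x 3 cases,
    each with one correct diagnosis and a dispersed wrong-answer alphabet."""
    table = {
        "v1": ("acute coronary syndrome", ["stable angina", "gerd", "musculoskeletal pain", "panic attack", "pericarditis"]),
        "v2": ("pulmonary embolism", ["pneumonia", "pleurisy", "panic attack", "musculoskeletal pain", "bronchitis"]),
        "v3": ("aortic dissection", ["acute coronary syndrome", "gerd", "musculoskeletal pain", "pericarditis", "pleurisy"]),
        "v4": ("appendicitis", ["gastroenteritis", "mesenteric adenitis", "urinary tract infection", "constipation", "ovarian cyst"]),
        "v5": ("ectopic pregnancy", ["appendicitis", "ovarian cyst", "urinary tract infection", "pelvic inflammatory disease", "miscarriage"]),
        "v6": ("diverticulitis", ["irritable bowel syndrome", "constipation", "gastroenteritis", "colorectal cancer", "urinary tract infection"]),
        "v7": ("heart failure", ["copd", "asthma", "pneumonia", "anaemia", "obesity-related dyspnoea"]),
        "v8": ("copd", ["asthma", "heart failure", "bronchitis", "pneumonia", "lung cancer"]),
        "v9": ("anaemia", ["heart failure", "hypothyroidism", "copd", "depression", "chronic fatigue"]),
    }
    dispersed = (0.30, 0.25, 0.20, 0.15, 0.10)
    correct = {c: t[0] for c, t in table.items()}
    wrong = {c: dict(zip(t[1], dispersed)) for c, t in table.items()}
    return correct, wrong


def _actor_case_table() -> tuple[dict[str, str], dict[str, dict[str, float]]]:
    """Actor-patient vocabulary: 12 cases (6 per condition); half the cases
    concentrate errors on a modal wrong diagnosis."""
    table = {
        "a01": ("acute coronary syndrome", ["gerd", "musculoskeletal pain", "panic attack"]),
        "a02": ("pulmonary embolism", ["pneumonia", "pleurisy", "panic attack"]),
        "a03": ("appendicitis", ["gastroenteritis", "urinary tract infection", "constipation"]),
        "a04": ("heart failure", ["copd", "asthma", "pneumonia"]),
        "a05": ("diverticulitis", ["irritable bowel syndrome", "gastroenteritis", "constipation"]),
        "a06": ("aortic dissection", ["acute coronary syndrome", "musculoskeletal pain", "gerd"]),
        "a07": ("ectopic pregnancy", ["appendicitis", "ovarian cyst", "pelvic inflammatory disease"]),
        "a08": ("copd", ["asthma", "heart failure", "bronchitis"]),
        "a09": ("anaemia", ["hypothyroidism", "heart failure", "depression"]),
        "a10": ("pericarditis", ["acute coronary syndrome", "musculoskeletal pain", "pleurisy"]),
        "a11": ("pyelonephritis", ["urinary tract infection", "appendicitis", "renal colic"]),
        "a12": ("asthma", ["copd", "bronchitis", "panic attack"]),
    }
    concentrated = (0.60, 0.25, 0.15)
    dispersed = (0.40, 0.35, 0.25)
    correct = {c: t[0] for c, t in table.items()}
    wrong = {
        c: dict(zip(t[1], concentrated if i % 2 == 0 else dispersed))
        for i, (c, t) in enumerate(table.items())
    }
    return correct, wrong


def build_preset(name: str, *, calibrate: bool = True) -> SyntheticConfig:
    """Construct a preset configuration from first principles.

    With ``calibrate=True`` (default) case easiness and DSS effects are tuned
    by :func:`calibrate_easiness` / :func:`calibrate_condition_effect` to the
    published mean individual accuracies (vignette: 63% control, 69% early
    DSS; actor-patient: 48% / 57%). The packaged YAML presets are frozen
    snapshots of these builds.
    """
    if name == "vignette_like":
        correct, wrong = _vignette_case_table()
        cases = tuple(correct)
        design = StudyDesign(
            name="vignette",
            assignment="between_subject",
            conditions=("control", "early_dss", "late_dss"),
            cases_per_condition={c: cases for c in ("control", "early_dss", "late_dss")},
            confidence_scale=(1, 8),
        )
        config = SyntheticConfig(
            design=design,
            n_gps=87,
            easiness=dict(zip(cases, map(float, np.linspace(-1.1, 1.1, len(cases))))),
            sigma_g=0.6,
            delta_cond={"control": 0.0, "early_dss": 0.0, "late_dss": 0.0},
            correct_labels=correct,
            wrong_labels=wrong,
            conf_mean=5.8,
            conf_sd=1.4,
            conf_shift=0.6,
            seniority_bands=((0, 10, 0.646), (11, 20, 0.181), (21, 40, 0.173)),
            gamma=-0.01,
            seed=202_406,
        )
        targets = {"early_dss": 0.69, "late_dss": 0.66}
        control_target = 0.63
    elif name == "actor_patient_like":
        correct, wrong = _actor_case_table()
        cases = tuple(correct)
        design = StudyDesign(
            name="actor_patient",
            assignment="within_subject",
            conditions=("control", "early_dss"),
            cases_per_condition={"control": cases[:6], "early_dss": cases[6:]},
            confidence_scale=(1, 10),
        )
        config = SyntheticConfig(
            design=design,
            n_gps=30,
            easiness=dict(
                zip(cases, map(float, np.tile(np.linspace(-1.0, 1.0, 6), 2)))
            ),
            sigma_g=0.6,
            delta_cond={"control": 0.0, "early_dss": 0.0},
            correct_labels=correct,
            wrong_labels=wrong,
            conf_mean=7.5,
            conf_sd=1.6,
            conf_shift=0.0,
            seniority_bands=((0, 10, 0.567), (11, 20, 0.166), (21, 40, 0.267)),
            gamma=-0.03,
            seed=202_407,
        )
        targets = {"early_dss": 0.57}
        control_target = 0.48
    else:
        raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")

    if calibrate:
        config.easiness = calibrate_easiness(control_target, config)
        for cond, target in targets.items():
            config.delta_cond[cond] = calibrate_condition_effect(target, cond, config)
    return config


def load_preset(name: str) -> SyntheticConfig:
    """Load one of the packaged study presets.

    ``"vignette_like"``: between-subject, 3 conditions (control / early DSS /
    late DSS), 9 shared cases, 87 GPs per condition, confidence scale 1-8,
    positive confidence-accuracy shift, dispersed errors; individual accuracy
    calibrated to 63% (control) and 69% (early DSS).

    ``"actor_patient_like"``: within-subject, 2 conditions, 6 cases each,
    30 GPs, confidence scale 1-10, null confidence-accuracy association,
    more concentrated errors; calibrated to 48% / 57%.
    """
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    from importlib import resources

    ref = resources.files("crowddx") / "presets" / f"{name}.yaml"
    with resources.as_file(ref) as path:
        return SyntheticConfig.from_yaml(path)
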