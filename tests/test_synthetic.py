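"""Synthetic study generator: structure, determinism, calibration, recovery."""

import numpy as np
import pandas as pd
import pytest

from crowddx import (
    StudyDesign,
    SynonymMap,
    SyntheticConfig,
    build_preset,
    calibrate_condition_effect,
    calibrate_easiness,
    generate_study,
    load_preset,
    sample_population,
    score,
    simulate_response,
    standardize,
)
from crowddx.synthetic import PRESET_NAMES, _expit

from conftest import tiny_config


def scored_study(config):
    records, truth = generate_study(config)
    records = standardize(records, SynonymMap())
    return score(records, config.answer_key()), truth


class TestPopulation:
    def test_between_subject_cell_sizes(self):
        cfg = tiny_config(n_gps=87, design=StudyDesign(
            name="v", assignment="between_subject",
            conditions=("control", "early_dss", "late_dss"),
            cases_per_condition={c: ("c1", "c2", "c3")
                                 for c in ("control", "early_dss", "late_dss")},
            confidence_scale=(1, 8)),
            delta_cond={"control": 0.0, "early_dss": 0.3, "late_dss": 0.1})
        pop = sample_population(cfg)
        assert len(pop) == 261
        counts = pop["conditions"].apply(lambda t: t[0]).value_counts()
        assert (counts == 87).all()

    def test_within_subject_everyone_gets_all_conditions(self):
        cfg = tiny_config(
            n_gps=30,
            design=StudyDesign(
                name="a", assignment="within_subject",
                conditions=("control", "early_dss"),
                cases_per_condition={"control": ("c1", "c2"), "early_dss": ("c3",)},
                confidence_scale=(1, 10)),
            easiness={"c1": 0.0, "c2": 0.1, "c3": 0.2},
            correct_labels={c: f"{c}_true" for c in ("c1", "c2", "c3")},
            wrong_labels={c: {f"{c}_w": 1.0} for c in ("c1", "c2", "c3")},
        )
        pop = sample_population(cfg)
        assert len(pop) == 30
        assert all(t == ("control", "early_dss") for t in pop["conditions"])

    def test_same_seed_same_population(self):
        cfg = tiny_config()
        pd.testing.assert_frame_equal(sample_population(cfg), sample_population(cfg))


class TestResponses:
    def test_logistic_midpoint(self):
        """At zero total log-odds the success probability is exactly 1/2."""
        cfg = tiny_config(sigma_g=0.0, gamma=0.0, easiness={"c1": 0.0, "c2": 0.0, "c3": 0.0},
                          delta_cond={"control": 0.0, "early_dss": 0.0})
        gp = {"gp_id": "g0", "skill": 0.0, "seniority_years": 5.0, "conditions": ("control",)}
        rec = simulate_response(gp, "c1", "control", cfg, np.random.default_rng(0))
        assert rec["p_correct"] == pytest.approx(0.5)

    def test_degenerate_wrong_alphabet(self):
        """With a single wrong label every error is identical."""
        cfg = tiny_config(
            easiness={"c1": -8.0, "c2": -8.0, "c3": -8.0}, sigma_g=0.0, gamma=0.0,
            wrong_labels={c: {"only_wrong": 1.0} for c in ("c1", "c2", "c3")},
        )
        recs, _ = scored_study(cfg)
        wrong = recs.loc[~recs["correct"].astype(bool), "diagnosis_std"]
        assert len(wrong) > 0
        assert set(wrong) == {"only_wrong"}

    def test_uniform_wrongs_modal_share_converges(self):
        """Uniform weights over m wrong labels: modal wrong share -> 1/m."""
        m = 4
        cfg = tiny_config(
            n_gps=2000,
            design=StudyDesign(name="one", assignment="between_subject",
                               conditions=("control",),
                               cases_per_condition={"control": ("c1",)},
                               confidence_scale=(1, 8)),
            easiness={"c1": -1.0}, sigma_g=0.0, gamma=0.0,
            delta_cond={"control": 0.0},
            correct_labels={"c1": "right"},
            wrong_labels={"c1": {f"w{i}": 1 / m for i in range(m)}},
        )
        recs, _ = scored_study(cfg)
        wrong = recs.loc[~recs["correct"].astype(bool), "diagnosis_std"]
        share = wrong.value_counts(normalize=True).iloc[0]
        assert share == pytest.approx(1 / m, abs=0.03)

    def test_zero_conf_shift_has_no_confidence_accuracy_gap(self):
        """conf_shift=0: mean confidence of correct vs incorrect responses
        differs by at most 2 Monte-Carlo standard errors at n ~ 10,000."""
        cfg = tiny_config(n_gps=1700, conf_shift=0.0, seed=3)
        recs, _ = scored_study(cfg)  # 1700 GPs x 2 cond x 3 cases ~ 10,200
        correct = recs["correct"].astype(bool)
        a, b = recs.loc[correct, "confidence"], recs.loc[~correct, "confidence"]
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert abs(a.mean() - b.mean()) <= 2 * se

    def test_confidence_within_scale(self):
        cfg = tiny_config(conf_mean=9.5, conf_sd=3.0)  # pushes past the top
        recs, _ = scored_study(cfg)
        assert recs["confidence"].between(1, 8).all()

    def test_exchangeable_cases_have_equal_accuracy(self):
        """sigma_g=0, gamma=0, equal easiness: per-case accuracies agree
        within binomial error."""
        cfg = tiny_config(
            n_gps=700, sigma_g=0.0, gamma=0.0,
            easiness={"c1": 0.4, "c2": 0.4, "c3": 0.4},
            delta_cond={"control": 0.0, "early_dss": 0.0}, seed=11,
        )
        recs, _ = scored_study(cfg)
        p = _expit(0.4)
        for _, sub in recs.groupby("case_id"):
            n = len(sub)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(sub["correct"].astype(float).mean() - p) <= 3.5 * se

    def test_generation_is_pure_function_of_config(self):
        a, _ = generate_study(tiny_config())
        b, _ = generate_study(tiny_config())
        pd.testing.assert_frame_equal(a, b)

    def test_record_count_matches_design(self):
        cfg = tiny_config(n_gps=13)
        recs, truth = generate_study(cfg)
        assert len(recs) == 13 * 2 * 3  # GPs x conditions x cases
        assert len(truth) == len(recs)


class TestCalibration:
    def test_logistic_zero_point(self):
        """Target 0.5 with no skill spread recovers easiness ~ 0."""
        cfg = tiny_config(sigma_g=0.0, gamma=0.0,
                          easiness={"c1": 0.7, "c2": 0.7, "c3": 0.7})
        cal = calibrate_easiness(0.5, cfg)
        assert all(abs(e) < 0.05 for e in cal.values())

    @pytest.mark.parametrize("target", [0.63, 0.48])
    def test_calibrated_accuracy_hits_target(self, target):
        """Independent large-n simulation of the calibrated model lands
        within +-0.01 of the target control accuracy."""
        cfg = tiny_config()
        cfg.easiness = calibrate_easiness(target, cfg)
        rng = np.random.default_rng(1234)
        n = 50_000
        cases = list(cfg.design.cases_per_condition["control"])
        e = np.array([cfg.easiness[c] for c in cases])[rng.integers(0, len(cases), n)]
        years = rng.choice([5, 15, 30], size=n, p=[0.6, 0.25, 0.15])
        # approximate band midpoints; exact band mixture checked elsewhere
        skill = rng.normal(cfg.gamma * (years - cfg.mean_years), cfg.sigma_g)
        acc = (rng.random(n) < _expit(e + skill)).mean()
        assert acc == pytest.approx(target, abs=0.012)

    def test_unattainable_target_errors(self):
        with pytest.raises(ValueError, match="unattainable"):
            # huge skill spread leaves a heavy tail of near-certain failures
            calibrate_easiness(0.999, tiny_config(sigma_g=8.0))

    def test_condition_effect_calibration(self):
        cfg = tiny_config()
        cfg.easiness = calibrate_easiness(0.6, cfg)
        delta = calibrate_condition_effect(0.7, "early_dss", cfg)
        assert delta > 0  # raising accuracy needs positive log-odds shift


class TestSeniorityModel:
    def test_negative_gamma_recovers_decreasing_accuracy(self):
        """gamma < 0: binned accuracy by seniority decreases at n ~ 10,000."""
        from crowddx.evaluation import seniority_band

        cfg = tiny_config(n_gps=1700, gamma=-0.05, sigma_g=0.3, seed=2)
        recs, _ = scored_study(cfg)
        acc = recs["correct"].astype(float).groupby(
            seniority_band(recs["seniority_years"]), observed=True
        ).mean()
        assert acc.iloc[0] > acc.iloc[1] > acc.iloc[2]

    def test_years_respect_bands(self):
        cfg = tiny_config(seniority_bands=((0, 10, 0.5), (21, 40, 0.5)))
        pop = sample_population(cfg)
        years = pop["seniority_years"]
        assert (((years >= 0) & (years <= 10)) | ((years >= 21) & (years <= 40))).all()


class TestConfigAndPresets:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = tiny_config()
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        again = SyntheticConfig.from_yaml(p)
        assert again.to_dict() == cfg.to_dict()

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            tiny_config(wrong_labels={c: {"w1": 0.5, "w2": 0.4}
                                      for c in ("c1", "c2", "c3")})

    def test_nonzero_control_effect_rejected(self):
        with pytest.raises(ValueError, match="control"):
            tiny_config(delta_cond={"control": 0.2, "early_dss": 0.0})

    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_packaged_presets_load_and_validate(self, name):
        cfg = load_preset(name)
        if name == "vignette_like":
            assert cfg.design.assignment == "between_subject"
            assert cfg.n_gps == 87
            assert len(cfg.design.all_cases) == 9
            assert cfg.design.confidence_scale == (1, 8)
        else:
            assert cfg.design.assignment == "within_subject"
            assert cfg.n_gps == 30
            assert len(cfg.design.all_cases) == 12
            assert cfg.design.confidence_scale == (1, 10)
            assert cfg.conf_shift == 0.0

    def test_packaged_preset_matches_builder(self):
        """The frozen YAML is a faithful snapshot of the code-built preset."""
        assert load_preset("vignette_like").to_dict() == build_preset("vignette_like").to_dict()

    def test_vignette_preset_structural_counts(self):
        recs, _ = generate_study(load_preset("vignette_like"))
        assert len(recs) == 9 * 87 * 3

    def test_actor_preset_structural_counts(self):
        recs, _ = generate_study(load_preset("actor_patient_like"))
        assert len(recs) == 30 * 12
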