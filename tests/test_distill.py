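"""The published risk score fixture and teacher→student distillation."""

import math
import warnings

import numpy as np
import pytest
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from scafkan import (CohortConfig, DistillConfig, RiskScoreModel,
                     distill_student, fidelity, generate_cohort)

MEAN_PATIENT = dict(lad=41.5, male_gender=1, ldh=218.3, bmi=24.0,
                    hypertension=1, lvpw_thickness=9.1, egfr=74.9,
                    septal_e_over_e_prime=12.4, lvedv=118.2,
                    coronary_heart_disease=0)


def hand_score(p):
    """Independent term-by-term calculator evaluation of the published formula."""
    return (0.407314 * p["lad"] - 1.810896 * p["male_gender"]
            + 2.026237 * math.log(p["ldh"] + 1) - 0.128719 * p["bmi"]
            - 0.571839 * p["hypertension"] - 0.439865 * p["lvpw_thickness"]
            - 0.000892 * p["egfr"] + 0.005358 * p["septal_e_over_e_prime"]
            - 0.023019 * p["lvedv"] - 1.335999 * p["coronary_heart_disease"]
            - 17.815156)


class TestPublishedScore:
    def test_mean_patient_matches_hand_calculation(self):
        rs = RiskScoreModel.published()
        s, p, flag = rs.score(MEAN_PATIENT)
        expected = hand_score(MEAN_PATIENT)
        assert s == pytest.approx(expected, abs=1e-9)
        assert s == pytest.approx(-2.1853, abs=1e-3)
        assert p == pytest.approx(1 / (1 + math.exp(-expected)), abs=1e-12)
        assert p == pytest.approx(0.1011, abs=1e-3)
        assert flag is False

    def test_unit_lad_increment_is_exact_coefficient(self):
        rs = RiskScoreModel.published()
        a = rs.score(MEAN_PATIENT)[0]
        b = rs.score({**MEAN_PATIENT, "lad": MEAN_PATIENT["lad"] + 1})[0]
        assert b - a == pytest.approx(0.407314, abs=1e-12)

    def test_zero_score_gives_probability_half(self):
        rs = RiskScoreModel(("lad",), ("identity",), (0.0,), 0.0)
        s, p, flag = rs.score({"lad": 50.0})
        assert (s, p, flag) == (0.0, 0.5, False)

    @pytest.mark.parametrize("mutation,match", [
        ({"lad": None}, "lad"),
        ({"ldh": -2.0}, "ldh"),
        ({"hypertension": 0.5}, "hypertension"),
    ])
    def test_invalid_inputs_refused_with_field_name(self, mutation, match):
        rs = RiskScoreModel.published()
        patient = {**MEAN_PATIENT, **mutation}
        if mutation.get("lad", 0) is None:
            patient.pop("lad")
        with pytest.raises(ValueError, match=match):
            rs.score(patient)

    def test_monotonicity_signs_of_published_coefficients(self):
        rs = RiskScoreModel.published()
        increasing = {"lad": 1.0, "ldh": 10.0, "septal_e_over_e_prime": 1.0}
        decreasing = {"male_gender": 1, "bmi": 1.0, "hypertension": 1,
                      "lvpw_thickness": 0.5, "egfr": 5.0, "lvedv": 10.0,
                      "coronary_heart_disease": 1}
        base = {**MEAN_PATIENT, "male_gender": 0, "hypertension": 0}
        p0 = rs.score(base)[1]
        for feat, delta in increasing.items():
            assert rs.score({**base, feat: base.get(feat, 0) + delta})[1] > p0, feat
        for feat, delta in decreasing.items():
            assert rs.score({**base, feat: base.get(feat, 0) + delta})[1] < p0, feat

    def test_json_roundtrip_bit_identical_predictions(self, tmp_path):
        rs = RiskScoreModel.published()
        path = tmp_path / "score.json"
        rs.save(path)
        rs2 = RiskScoreModel.load(path)
        cohort = generate_cohort(CohortConfig(n_patients=50, seed=1))
        assert np.array_equal(rs.predict_proba(cohort), rs2.predict_proba(cohort))

    def test_formula_export_lists_all_terms(self):
        text = RiskScoreModel.published().formula()
        assert "ln(ldh+1)" in text and "lad" in text
        assert "-17.815156" in text.replace(" ", "")


@pytest.fixture(scope="module")
def teacher_cohort():
    return generate_cohort(CohortConfig(n_patients=400, seed=5))


class TestDistillation:
    def test_alpha_zero_is_plain_logistic_fit(self, teacher_cohort):
        teacher = RiskScoreModel.published()
        p_t = teacher.predict_proba(teacher_cohort)
        stu = distill_student(p_t, teacher_cohort, teacher.features,
                              DistillConfig(alpha=0.0, temperature=2.0))
        Xt = teacher.design_matrix(teacher_cohort)
        ref = LogisticRegression(C=np.inf, max_iter=5000).fit(
            Xt, teacher_cohort.labels)
        assert np.abs(np.array(stu.coefficients) - ref.coef_[0]).max() < 5e-3
        assert stu.intercept == pytest.approx(ref.intercept_[0], abs=5e-2)

    def test_self_distillation_recovers_teacher(self, teacher_cohort):
        teacher = RiskScoreModel.published()
        p_t = teacher.predict_proba(teacher_cohort)
        stu = distill_student(p_t, teacher_cohort, teacher.features,
                              DistillConfig(alpha=1.0, temperature=1.0))
        assert np.abs(np.array(stu.coefficients)
                      - np.array(teacher.coefficients)).max() < 1e-4
        assert stu.intercept == pytest.approx(teacher.intercept, abs=1e-3)
        rep = fidelity(p_t, stu.predict_proba(teacher_cohort),
                       teacher_cohort.labels)
        assert 0.99 <= rep.auc_retention <= 1.01
        assert rep.correlation > 0.9999
        assert rep.mae < 1e-4

    def test_fixed_seed_and_config_reproducible(self, teacher_cohort):
        teacher = RiskScoreModel.published()
        p_t = teacher.predict_proba(teacher_cohort)
        a = distill_student(p_t, teacher_cohort, teacher.features)
        b = distill_student(p_t, teacher_cohort, teacher.features)
        assert a.coefficients == b.coefficients

    def test_degenerate_teacher_warns_and_falls_back(self, teacher_cohort):
        with pytest.warns(UserWarning, match="degenerate teacher"):
            stu = distill_student(np.full(400, 0.42), teacher_cohort,
                                  ("lad", "bmi"))
        assert np.isfinite(stu.coefficients).all()

    def test_distilled_student_not_worse_than_label_fit(self, teacher_cohort):
        # soft targets from a good teacher should not hurt validation AUC
        teacher = RiskScoreModel.published()
        p_t = teacher.predict_proba(teacher_cohort)
        half = 200
        from scafkan import CohortTable
        train = CohortTable(teacher_cohort.values[:half],
                            teacher_cohort.labels[:half], teacher_cohort.schema)
        soft = distill_student(p_t[:half], train, teacher.features,
                               DistillConfig(alpha=0.7, temperature=2.0))
        hard = distill_student(p_t[:half], train, teacher.features,
                               DistillConfig(alpha=0.0))
        from scafkan import roc_auc
        val = CohortTable(teacher_cohort.values[half:],
                          teacher_cohort.labels[half:], teacher_cohort.schema)
        auc_soft = roc_auc(val.labels, soft.predict_proba(val))
        auc_hard = roc_auc(val.labels, hard.predict_proba(val))
        assert auc_soft >= auc_hard - 0.05


class TestFidelity:
    def test_identical_models_perfect_fidelity(self):
        y = np.array([0, 1] * 20)
        p = np.linspace(0.05, 0.95, 40)
        rep = fidelity(p, p, y)
        assert rep.correlation == pytest.approx(1.0)
        assert rep.mae == 0.0
        assert rep.auc_retention == pytest.approx(1.0)

    def test_anticorrelated_scores(self):
        y = np.array([0, 1] * 20)
        p = np.linspace(0.05, 0.95, 40)
        rep = fidelity(p, 1 - p, y)
        assert rep.correlation == pytest.approx(-1.0)
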