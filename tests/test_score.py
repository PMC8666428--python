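"""Generalized importance, score evaluation, comparison and stratification."""

import numpy as np
import pandas as pd
import pytest

from rpscore.benchmark import ModelRunResult
from rpscore.exceptions import (
    MissingDataError,
    UnsupportedModelError,
    ValidationError,
)
from rpscore.score import (
    PUBLISHED_RPS,
    ScoreDefinition,
    compare_predictors,
    evaluate_score,
    generalized_importance,
    score_frame,
    select_score_size,
    sign_consistency_audit,
    stratify_quartiles,
)

PLANTED = ["early_monocyte", "distance_anal_verge", "early_PLT",
           "early_neutrophil", "early_eosinophil"]


def make_result(repeat_id, coefs, selected, kind="ridge", fs="clinical_early"):
    features = list(coefs)
    return ModelRunResult(
        repeat_id=repeat_id, model_kind=kind, feature_set=fs,
        selected_features=selected,
        coefficients_raw=dict(coefs),
        coefficients_std=dict(coefs),
        hyperparams={}, metrics={"valid": {"auroc": 0.6, "auprc": 0.6}},
        cutpoint=(0.5, 0.6, 0.6),
    )


class TestGeneralizedImportance:
    def test_mean_of_two_repeats(self):
        res = [
            make_result(0, {"a": 1.0}, ["a"]),
            make_result(1, {"a": 3.0}, ["a"]),
        ]
        t = generalized_importance(res).table
        assert t.loc[0, "beta_raw"] == pytest.approx(2.0)
        assert t.loc[0, "selection_count"] == 2

    def test_zero_imputation_for_unselected_repeat(self):
        res = [
            make_result(0, {"a": 4.0}, ["a"]),
            make_result(1, {"a": 0.0}, []),  # not selected: coefficient 0
        ]
        t = generalized_importance(res).table
        assert t.loc[0, "beta_raw"] == pytest.approx(2.0)
        assert t.loc[0, "selection_count"] == 1

    def test_all_positive_signs_fully_consistent(self):
        res = [make_result(i, {"a": 0.5 + i}, ["a"]) for i in range(4)]
        t = generalized_importance(res).table
        assert t.loc[0, "sign_consistency"] == 1.0

    def test_linearity_in_coefficients(self):
        res = [make_result(i, {"a": 1.0 + i, "b": -0.5}, ["a", "b"]) for i in range(3)]
        doubled = [
            make_result(i, {"a": 2 * (1.0 + i), "b": -1.0}, ["a", "b"])
            for i in range(3)
        ]
        t1 = generalized_importance(res).table.set_index("feature")
        t2 = generalized_importance(doubled).table.set_index("feature")
        assert np.allclose(2 * t1.beta_raw, t2.beta_raw)

    def test_nonlinear_kind_unsupported(self):
        res = [
            ModelRunResult(i, "rforest", "clinical_early", ["a"], None, None, {},
                           {"valid": {"auroc": 0.5, "auprc": 0.5}}, (0, 0, 0))
            for i in range(2)
        ]
        with pytest.raises(UnsupportedModelError):
            generalized_importance(res)

    def test_mixed_cells_rejected_without_filter(self):
        res = [
            make_result(0, {"a": 1.0}, ["a"], fs="clinical_early"),
            make_result(1, {"a": 1.0}, ["a"], fs="clinical_pre"),
        ]
        with pytest.raises(ValidationError):
            generalized_importance(res)
        assert len(generalized_importance(res + res, feature_set="clinical_pre").table) == 1


class TestEvaluateScore:
    def test_published_unit_inputs_reproduce_weights(self):
        zero = {f: 0.0 for f in PUBLISHED_RPS.features}
        for feature, weight in PUBLISHED_RPS.terms:
            assert evaluate_score(PUBLISHED_RPS, {**zero, feature: 1.0}) == pytest.approx(weight)
        assert evaluate_score(PUBLISHED_RPS, zero) == 0.0

    def test_hand_computed_profile(self):
        rec = {"early_monocyte": 300, "distance_anal_verge": 5, "early_PLT": 200,
               "early_neutrophil": 2500, "early_eosinophil": 100}
        # 300*0.000559 + 5*0.026172 + 200*0.001021 + 2500*0.000049 - 100*0.000433
        assert evaluate_score(PUBLISHED_RPS, rec) == pytest.approx(0.58196, abs=1e-9)

    def test_linearity_under_feature_scaling(self):
        rec = {"early_monocyte": 300, "distance_anal_verge": 5, "early_PLT": 200,
               "early_neutrophil": 2500, "early_eosinophil": 100}
        scaled = {k: 3 * v for k, v in rec.items()}
        assert evaluate_score(PUBLISHED_RPS, scaled) == pytest.approx(
            3 * evaluate_score(PUBLISHED_RPS, rec)
        )

    def test_missing_feature_named_in_error(self):
        with pytest.raises(MissingDataError, match="early_PLT"):
            evaluate_score(
                PUBLISHED_RPS,
                {"early_monocyte": 1, "distance_anal_verge": 1,
                 "early_neutrophil": 1, "early_eosinophil": 1},
            )

    def test_frame_matches_rowwise(self, planted_cohort):
        vec = score_frame(PUBLISHED_RPS, planted_cohort.head(20))
        for i in range(20):
            assert vec.iloc[i] == pytest.approx(
                evaluate_score(PUBLISHED_RPS, planted_cohort.iloc[i])
            )

    def test_definition_json_round_trip(self):
        back = ScoreDefinition.from_json(PUBLISHED_RPS.to_json())
        assert back.terms == PUBLISHED_RPS.terms
        assert back.provenance == "published"


class TestSelectScoreSize:
    def test_curve_length_equals_k_max(self, ridge_derivation):
        _, importance, curve, _ = ridge_derivation
        assert len(curve) == 10
        assert list(curve.K) == list(range(1, 11))

    def test_dominant_feature_yields_k_one(self):
        rng = np.random.default_rng(0)
        n = 120
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        frame = pd.DataFrame(
            {"big": y * 10.0 + rng.uniform(0, 1, n),  # perfectly separating
             "junk1": rng.normal(size=n), "junk2": rng.normal(size=n)}
        )
        res = [
            make_result(i, {"big": 1.0, "junk1": 1e-9, "junk2": -1e-9},
                        ["big", "junk1", "junk2"])
            for i in range(3)
        ]
        imp = generalized_importance(res)
        k_o, curve = select_score_size(imp, frame, y, k_max=3)
        assert k_o == 1  # ties on the P floor resolve to the smallest K

    def test_planted_minimum_far_below_null(self, ridge_derivation):
        from rpscore import SynthConfig, derive_score, generate_cohort

        _, _, planted_curve, _ = ridge_derivation
        null_cohort = generate_cohort(SynthConfig(seed=31).null()).table
        _, _, null_curve, _ = derive_score(null_cohort, n_repeats=20, master_seed=31)
        assert planted_curve.p_value.min() < 1e-6 * null_curve.p_value.min()


class TestSignConsistency:
    def test_half_and_half_is_point_five(self):
        res = [
            make_result(0, {"a": 1.0}, ["a"]),
            make_result(1, {"a": -1.0}, ["a"]),
            make_result(2, {"a": 2.0}, ["a"]),
            make_result(3, {"a": -2.0}, ["a"]),
        ]
        t = sign_consistency_audit(res)
        assert t.loc[t.feature == "a", "sign_consistency"].iloc[0] == pytest.approx(0.5)

    def test_never_selected_reported_as_nan(self):
        res = [make_result(i, {"a": 1.0, "b": 0.0}, ["a"]) for i in range(2)]
        t = sign_consistency_audit(res).set_index("feature")
        assert np.isnan(t.loc["b", "sign_consistency"])
        assert t.loc["b", "selection_count"] == 0

    def test_planted_features_consistent_in_derivation(self, ridge_derivation):
        _, _, _, results = ridge_derivation
        t = sign_consistency_audit(results, PLANTED).set_index("feature")
        assert (t.sign_consistency >= 0.95).all()


class TestComparePredictors:
    def test_score_and_negation_sum_to_one(self, planted_cohort):
        from rpscore.metrics import auroc
        from rpscore.features import labels_from_frame

        y = labels_from_frame(planted_cohort)
        s = score_frame(PUBLISHED_RPS, planted_cohort).to_numpy()
        assert auroc(s, y) + auroc(-s, y) == pytest.approx(1.0)

    def test_planted_cohort_score_is_best_predictor(self, planted_cohort, ridge_derivation):
        defn, _, _, _ = ridge_derivation
        table = compare_predictors(planted_cohort, defn)
        assert table.iloc[0].predictor == "score"

    def test_negatively_oriented_predictors_prefixed(self, planted_cohort):
        table = compare_predictors(planted_cohort, PUBLISHED_RPS)
        assert (table.auroc >= 0.5).all()
        assert table.predictor.str.startswith("-").any()

    def test_published_score_in_output(self, planted_cohort):
        table = compare_predictors(planted_cohort, PUBLISHED_RPS)
        assert "RPS" in set(table.predictor)


class TestStratifyQuartiles:
    def test_eight_distinct_scores_split_evenly(self, planted_cohort):
        rep = stratify_quartiles(
            np.arange(8, dtype=float), planted_cohort.head(8)
        )
        assert rep.group_sizes.tolist() == [2, 2, 2, 2]

    def test_counts_partition_cohort(self, planted_cohort):
        s = score_frame(PUBLISHED_RPS, planted_cohort)
        rep = stratify_quartiles(s, planted_cohort)
        assert rep.group_sizes.sum() == len(planted_cohort)
        assert rep.trg_table.to_numpy().sum() == len(planted_cohort)

    def test_null_scores_give_flat_response_rates(self, big_planted_cohort):
        rng = np.random.default_rng(17)
        s = rng.normal(size=len(big_planted_cohort))  # independent of outcome
        rep = stratify_quartiles(s, big_planted_cohort)
        overall = (big_planted_cohort.trg <= 1).mean()
        assert np.all(np.abs(rep.rates.good_response_rate - overall) <= 0.10)

    def test_tied_scores_warn_not_fail(self, planted_cohort):
        with pytest.warns(UserWarning):
            rep = stratify_quartiles(
                np.zeros(len(planted_cohort)), planted_cohort
            )
        assert rep.group_sizes.sum() == len(planted_cohort)

    def test_too_few_scores_rejected(self, planted_cohort):
        with pytest.raises(ValidationError):
            stratify_quartiles(np.arange(5), planted_cohort.head(5))
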