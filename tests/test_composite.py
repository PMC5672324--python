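"""Composite predictor, refit with factors, metabolic-age projections."""

import math

import numpy as np
import pandas as pd
import pytest

from allomer import (CompositeMERRegressor, CompositeModel, GeneratorConfig,
                     REFERENCE_K_TABLES, fit_allometric, generate_cohort,
                     metabolic_age, normalize_mer, predict_mer,
                     refit_with_factors, weight_gain_projection)

BASE = CompositeModel.from_preset("base")          # a=128, b=0.730, c=-0.050
COMPOSITE = CompositeModel.from_preset("composite")  # b=0.740 + k tables


class TestPredict:
    def test_unit_base(self):
        assert BASE.predict(1.0, 1.0) == pytest.approx(128.0)

    def test_thirty_kg_adult(self):
        assert BASE.predict(30.0, 1.0) == pytest.approx(128.0 * 30.0 ** 0.730)
        assert BASE.predict(30.0, 1.0) == pytest.approx(1532.8, abs=0.2)

    def test_spayed_female_correction(self):
        attrs = {"sex_neuter": "female_spayed"}
        assert COMPOSITE.predict(30.0, 1.0, attrs) == pytest.approx(
            0.85 * COMPOSITE.predict(30.0, 1.0))

    def test_unknown_levels_apply_unit_k(self):
        attrs = {"sex_neuter": "unknown", "bedding": "unknown"}
        assert COMPOSITE.predict(12.0, 3.0, attrs) == COMPOSITE.predict(12.0, 3.0)

    def test_k_product_multiplies(self):
        attrs = {"breed_group": "shepherd_high", "bedding": "outside",
                 "temperament": "active"}
        expected = 1.09 * 1.05 * 1.05 * COMPOSITE.predict(20.0, 4.0)
        assert COMPOSITE.predict(20.0, 4.0, attrs) == pytest.approx(expected)

    def test_monotone_in_bw_and_age(self):
        assert BASE.predict(31.0, 5.0) > BASE.predict(30.0, 5.0)
        assert BASE.predict(30.0, 6.0) < BASE.predict(30.0, 5.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            BASE.predict(0.0, 5.0)
        with pytest.raises(ValueError):
            BASE.predict(30.0, -1.0)

    def test_normalization_round_trip_identity(self):
        """normalize_mer(predict(...)) / ∏k returns the constant a."""
        attrs = {"breed_group": "retriever_low", "temperament": "active"}
        mer = COMPOSITE.predict(17.0, 6.5, attrs)
        norm = normalize_mer(mer, 17.0, 6.5, b=COMPOSITE.b, c=COMPOSITE.c)
        assert norm / COMPOSITE.factor_product(attrs) == pytest.approx(COMPOSITE.a)

    def test_functional_front(self):
        assert predict_mer(BASE, 30.0, 1.0) == BASE.predict(30.0, 1.0)

    def test_serialisation_round_trip(self):
        again = CompositeModel.from_dict(COMPOSITE.to_dict())
        assert again.predict(22.0, 3.0, {"bedding": "outside"}) == \
            COMPOSITE.predict(22.0, 3.0, {"bedding": "outside"})

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            CompositeModel(a=128, b=0.73, c=-0.05,
                           k_tables={"bedding": {"outside": -1.0}})


class TestMetabolicAge:
    def test_unit_at_one_year(self):
        assert metabolic_age(1.0) == 1.0

    @pytest.mark.parametrize("age,expected", [(5.0, 0.9227), (10.0, 0.8913)])
    def test_reference_values(self, age, expected):
        assert metabolic_age(age) == pytest.approx(expected, abs=5e-5)

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError):
            metabolic_age(0.0)


class TestWeightGainProjection:
    def test_thirty_kg_five_year_old(self):
        """Feeding a 5-year-old 30 kg dog its one-year-old ration projects
        ~5.6 kg gained per year at 7.7 kcal per gram of tissue."""
        gain = weight_gain_projection(BASE, 30.0, 5.0, rho_kcal_per_g=7.7)
        assert round(gain, 1) == 5.6

    def test_no_surplus_at_age_one(self):
        assert weight_gain_projection(BASE, 30.0, 1.0) == 0.0

    def test_strictly_increasing_in_age(self):
        gains = [weight_gain_projection(BASE, 30.0, a) for a in (2, 5, 8, 12)]
        assert all(x < y for x, y in zip(gains, gains[1:]))

    def test_denser_tissue_gains_less(self):
        assert weight_gain_projection(BASE, 30.0, 5.0, rho_kcal_per_g=9.0) < \
            weight_gain_projection(BASE, 30.0, 5.0, rho_kcal_per_g=7.7)

    def test_underage_rejected(self):
        with pytest.raises(ValueError):
            weight_gain_projection(BASE, 30.0, 0.5)


class TestRefitWithFactors:
    def test_identity_tables_match_plain_fit(self, cohort_319):
        plain = fit_allometric(cohort_319, include_age=True)
        refit = refit_with_factors(cohort_319, {})
        assert refit.a == pytest.approx(plain.a)
        assert refit.b == pytest.approx(plain.b)
        assert refit.r2 == pytest.approx(plain.r2)

    def test_true_tables_on_noiseless_data_are_exact(self):
        cfg = GeneratorConfig(n=400, sigma_log=0.0)
        cohort = generate_cohort(cfg, seed=9)
        refit = refit_with_factors(cohort, REFERENCE_K_TABLES)
        assert refit.r2 == pytest.approx(1.0, abs=1e-10)
        assert math.log(refit.a) == pytest.approx(math.log(128.0), abs=1e-10)
        assert refit.b == pytest.approx(0.730, abs=1e-10)
        assert refit.c == pytest.approx(-0.050, abs=1e-10)

    def test_true_tables_improve_r2_under_noise(self, cohort_5000):
        plain = fit_allometric(cohort_5000, include_age=True)
        refit = refit_with_factors(cohort_5000, REFERENCE_K_TABLES)
        assert refit.r2 > plain.r2
        assert abs(refit.a - 128.0) < abs(plain.a - 128.0)


class TestEndToEndEstimator:
    def test_fit_recovers_generator_truth(self, cohort_5000):
        frame = cohort_5000.to_frame()
        est = CompositeMERRegressor().fit(frame, frame["mer_kcal_d"].to_numpy())
        assert abs(est.b_ - 0.730) < 0.02
        assert abs(est.c_ + 0.050) < 0.02
        assert abs(est.a_ - 128.0) < 8.0
        assert est.r2_ > est.fit_bw_age_.r2
        assert est.k_tables_["sex_neuter"]["female_spayed"] == pytest.approx(0.85, abs=0.02)

    def test_predict_applies_learned_k(self, cohort_5000):
        frame = cohort_5000.to_frame()
        est = CompositeMERRegressor().fit(frame, frame["mer_kcal_d"].to_numpy())
        X = pd.DataFrame({"bw_kg": [30.0, 30.0], "age_years": [5.0, 5.0],
                          "sex_neuter": ["female_spayed", "male_intact"]})
        pred = est.predict(X)
        assert pred[0] == pytest.approx(
            pred[1] * est.k_tables_["sex_neuter"]["female_spayed"])

    def test_reference_predictor_needs_no_fit(self):
        est = CompositeMERRegressor.from_reference("composite")
        X = pd.DataFrame({"bw_kg": [30.0], "age_years": [1.0],
                          "bedding": ["outside"]})
        assert est.predict(X)[0] == pytest.approx(1.05 * 128.0 * 30.0 ** 0.740)

    def test_prediction_errors_on_unseen_model(self):
        est = CompositeMERRegressor()
        with pytest.raises(Exception):
            est.predict(pd.DataFrame({"bw_kg": [30.0], "age_years": [1.0]}))
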