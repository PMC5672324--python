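"""Synthetic-cohort generator: calibration, reproducibility, planted truth."""

import numpy as np
import pandas as pd
import pytest

from allomer import (DEFAULT_SIGMA_LOG, AllometricRegressor, GeneratorConfig,
                     apply_exclusions, calibrate_sigma, fit_allometric,
                     generate_cohort, generate_raw_database)


class TestReproducibility:
    def test_same_seed_identical_cohort(self):
        a = generate_cohort(seed=11)
        b = generate_cohort(seed=11)
        assert a.records == b.records

    def test_different_seed_differs(self):
        assert generate_cohort(seed=11).records != generate_cohort(seed=12).records

    def test_seed_argument_overrides_config(self):
        cfg = GeneratorConfig(seed=5)
        assert generate_cohort(cfg, seed=11).records == generate_cohort(seed=11).records


class TestMarginals:
    def test_weights_within_printed_range(self, cohort_319):
        bw = np.array([r.bw_kg for r in cohort_319])
        assert bw.min() >= 1.1 and bw.max() <= 80.0

    def test_bw_moments_match_target(self):
        """Post-truncation BW moments match the cohort statistics they
        emulate (pooled draw, so sampling error is negligible)."""
        pooled = np.concatenate([
            np.array([r.bw_kg for r in generate_cohort(GeneratorConfig(n=5000), seed=s)])
            for s in range(4)])
        assert pooled.mean() == pytest.approx(23.18, abs=0.15)
        assert pooled.std() == pytest.approx(13.55, abs=0.3)

    def test_ages_adult_and_matched(self, cohort_5000):
        age = np.array([r.age_years for r in cohort_5000])
        assert age.min() >= 1.0
        assert age.mean() == pytest.approx(4.91, abs=0.15)
        assert age.std() == pytest.approx(3.49, abs=0.2)

    def test_category_frequencies(self, cohort_5000):
        frame = cohort_5000.to_frame()
        males = (frame["sex"] == "male").mean()
        assert males == pytest.approx(171 / 319, abs=0.02)
        spayed = ((frame["sex"] == "female") & (frame["neutered"] == "yes")).sum()
        females = (frame["sex"] == "female").sum()
        assert spayed / females == pytest.approx(0.554, abs=0.03)
        assert (frame["temperament"] == "active").mean() == pytest.approx(
            112 / 319, abs=0.02)
        assert (frame["bedding"] == "outside").mean() == pytest.approx(
            42 / 319, abs=0.02)

    def test_compliant_cohort_passes_filter_untouched(self, cohort_319):
        report = apply_exclusions(cohort_319)
        assert len(report.retained) == len(cohort_319)


class TestSigmaCalibration:
    def test_default_sigma_reproduced_by_calibration(self):
        assert calibrate_sigma(0.816, n_mc=400_000, seed=0) == pytest.approx(
            DEFAULT_SIGMA_LOG, abs=0.004)

    def test_monotone_in_target(self):
        sigmas = [calibrate_sigma(t, n_mc=50_000) for t in (0.5, 0.7, 0.9)]
        assert sigmas[0] > sigmas[1] > sigmas[2]

    def test_limit_towards_one_vanishes(self):
        assert calibrate_sigma(0.9999, n_mc=50_000) < 0.01

    def test_target_out_of_range(self):
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                calibrate_sigma(bad)

    def test_calibrated_r2_attained(self):
        """The two-predictor log-log fit on cohorts generated with the
        default sigma reaches the calibration target on average."""
        r2s = [fit_allometric(generate_cohort(seed=s), include_age=True).r2
               for s in range(25)]
        assert np.mean(r2s) == pytest.approx(0.816, abs=0.015)


class TestRawDatabase:
    def test_default_retention(self):
        db = generate_raw_database(seed=7)
        report = apply_exclusions(db.cohort, db.kennel_ids)
        assert len(db.cohort) == 579
        assert len(report.retained) == 319

    def test_planted_truth_matches_filter_verdict(self):
        db = generate_raw_database(seed=3)
        report = apply_exclusions(db.cohort, db.kennel_ids)
        assert {i for i, _ in report.excluded} == set(db.planted)
        found = dict(report.excluded)
        for rec_id, rules in db.planted.items():
            assert set(rules) <= set(found[rec_id])

    def test_zero_violations_all_retained(self):
        cfg = GeneratorConfig(raw_mode=True, n_total=50, n_violations=0)
        db = generate_raw_database(cfg, seed=1)
        assert len(apply_exclusions(db.cohort, db.kennel_ids).retained) == 50

    def test_all_violating_none_retained(self):
        cfg = GeneratorConfig(raw_mode=True, n_total=40, n_violations=40)
        db = generate_raw_database(cfg, seed=1)
        assert len(apply_exclusions(db.cohort, db.kennel_ids).retained) == 0

    def test_overfull_violations_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_total=10, n_violations=11)


class TestConfigValidation:
    def test_bad_probability_table(self):
        tables = {f: dict(t) for f, t in GeneratorConfig().category_tables.items()}
        tables["bedding"] = {"inside": 0.5, "outside": 0.2, "unknown": 0.2}
        with pytest.raises(ValueError, match="sum"):
            GeneratorConfig(category_tables=tables)

    def test_bad_bw_bounds(self):
        with pytest.raises(ValueError):
            GeneratorConfig(bw_min=50.0, bw_max=20.0)


@pytest.fixture(scope="module")
def replicate_fits():
    fits = []
    for seed in range(300):
        cohort = generate_cohort(seed=seed)
        frame = pd.DataFrame({
            "bw_kg": [r.bw_kg for r in cohort],
            "age_years": [r.age_years for r in cohort]})
        mer = np.array([r.mer_kcal_d for r in cohort])
        fits.append(AllometricRegressor().fit(frame, mer))
    return fits


class TestSamplingTheory:
    def test_bw_exponent_unbiased(self, replicate_fits):
        """OLS on log-transformed data: the mean fitted BW exponent over
        replicated cohorts sits within 0.005 of the generator truth."""
        b_hat = np.array([f.b_ for f in replicate_fits])
        assert abs(b_hat.mean() - 0.730) < 0.005

    def test_empirical_sd_brackets_analytic_se(self, replicate_fits):
        """Simulation/theory agreement: the spread of fitted exponents
        matches the average analytic OLS standard error within 20 %."""
        b_hat = np.array([f.b_ for f in replicate_fits])
        analytic = np.mean([f.se_b_ for f in replicate_fits])
        assert 0.8 < b_hat.std() / analytic < 1.2

    def test_recovery_ladder(self):
        """Median |b̂ − b| shrinks as the cohort grows."""
        medians = []
        for n in (319, 1000, 5000):
            errs = [abs(fit_allometric(
                generate_cohort(GeneratorConfig(n=n), seed=s)).b - 0.730)
                for s in range(30)]
            medians.append(np.median(errs))
        assert medians[0] > medians[1] > medians[2]
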