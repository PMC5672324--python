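import pytest

from allomer import Cohort, DogRecord, GeneratorConfig, generate_cohort


def make_record(**overrides) -> DogRecord:
    """A fully compliant reference record; override fields per test."""
    base = dict(
        id="d1",
        breed="Border collie",
        sex="male",
        neutered="no",
        age_years=4.0,
        bw_kg=20.0,
        ideal_bw_kg=20.0,
        bcs=4,
        weight_variation_pct=2.0,
        bedding="inside",
        temperament="normal",
        ownership="parents",
        diet_type="dry",
        meals_per_day="two",
        work_hours_per_day=0.0,
        healthy=True,
        mer_kcal_d=1200.0,
    )
    base.update(overrides)
    return DogRecord(**base)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def small_cohort():
    """Five compliant records with varied fields, for round-trip tests."""
    return Cohort([
        make_record(id="a", breed="Labrador retriever", sex="female",
                    neutered="yes", bedding="outside", mer_kcal_d=900.5),
        make_record(id="b", breed="Beauceron", temperament="active",
                    age_years=2.5, bw_kg=31.2, ideal_bw_kg=31.2),
        make_record(id="c", neutered="unknown", bedding="unknown",
                    temperament="unknown", ownership="unknown"),
        make_record(id="d", diet_type="homemade", meals_per_day="ad_libitum",
                    mer_kcal_d=None),
        make_record(id="e", bw_kg=4.75, ideal_bw_kg=4.75, age_years=11.0,
                    bcs=5, mer_kcal_d=310.25),
    ])


@pytest.fixture(scope="session")
def cohort_319():
    """Default synthetic cohort at the reference size."""
    return generate_cohort(seed=0)


@pytest.fixture(scope="session")
def cohort_5000():
    """Large synthetic cohort for parameter-recovery checks."""
    return generate_cohort(GeneratorConfig(n=5000), seed=1)
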