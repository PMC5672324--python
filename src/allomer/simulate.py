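"""Synthetic cohorts with the study population's statistical structure.

The generator draws body weight from a lognormal moment-matched to a mean
of 23.18 kg (sd 13.55), truncated to [1.1, 80.0] kg by resampling; age as
1 + gamma moment-matched to mean 4.91 y (sd 3.49), so every dog is an
adult by construction; and every categorical attribute independently from
tables proportional to the reference cohort's printed counts (319 dogs:
171 males of whom 24.3 % neutered, 148 females of whom 55.4 % spayed;
bedding 192 inside / 42 outside / 85 unrecorded; temperament 138 normal /
112 active / 58 calm / 11 unrecorded; and so on). Observed intake is then

    MER = a · BW^b · age^c · ∏ k(levels) · exp(ε),   ε ~ N(0, σ_log²)

with default truth a = 128, b = 0.730, c = -0.050 and the reference
correction factors (0.88 retrievers, 1.09 shepherds, 0.85 spayed females,
1.05 outside, 1.05 active). σ_log defaults to the value
:func:`calibrate_sigma` returns for a target two-predictor r² of 0.816.

``generate_raw_database`` additionally plants protocol violations
(underage, unstable weight, out-of-range BCS, non-ideal weight, working,
kennel housing, disease, missing intake) into an exact number of records,
returning the planted truth so the exclusion cascade can be validated
record-for-record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .cohort import (Bedding, Cohort, DietType, DogRecord, MealsPerDay,
                     Neutered, Ownership, Sex, Temperament)
from .composite import REFERENCE_K_TABLES

#: Residual sd on the natural-log scale; the frozen output of
#: ``calibrate_sigma(0.816)`` under the default configuration.
DEFAULT_SIGMA_LOG = 0.1796

_N_REF = 319.0

#: Default level probabilities, proportional to the reference cohort counts.
DEFAULT_CATEGORY_TABLES: dict[str, dict[str, float]] = {
    "sex": {"male": 171 / _N_REF, "female": 148 / _N_REF},
    # neuter probability conditional on sex
    "neutered_given_sex": {"male": 0.243, "female": 0.554},
    "breed_group": {"retriever_low": 38 / _N_REF, "shepherd_high": 23 / _N_REF,
                    "other": 258 / _N_REF},
    "bedding": {"inside": 192 / _N_REF, "outside": 42 / _N_REF,
                "unknown": 85 / _N_REF},
    "temperament": {"normal": 138 / _N_REF, "active": 112 / _N_REF,
                    "calm": 58 / _N_REF, "unknown": 11 / _N_REF},
    "ownership": {"student": 49 / _N_REF, "parents": 110 / _N_REF,
                  "family": 23 / _N_REF, "other_student": 17 / _N_REF,
                  "other": 25 / _N_REF, "unknown": 95 / _N_REF},
    "diet_type": {"dry": 274 / _N_REF, "moist": 13 / _N_REF,
                  "mixed_commercial": 11 / _N_REF,
                  "commercial_plus_leftovers": 15 / _N_REF,
                  "homemade": 6 / _N_REF},
    "meals_per_day": {"one": 149 / _N_REF, "two": 147 / _N_REF,
                      "ad_libitum": 16 / _N_REF, "three": 6 / _N_REF,
                      "four": 1 / _N_REF},
}

#: Breed names drawn within each group (German shepherds are 'other').
_BREED_NAMES = {
    "retriever_low": ("Labrador retriever", "Golden retriever"),
    "shepherd_high": ("Belgian shepherd dog", "Beauce shepherd dog"),
    "other": ("Border collie", "German shepherd dog", "Fox terrier",
              "Yorkshire terrier", "Brittany spaniel", "Pyrenean shepherd dog",
              "Crossbreed"),
}

#: Exclusion rules the raw-database generator can plant, with the default
#: mix (relative weights) used to pick rules for each violating record.
_VIOLATION_WEIGHTS = {
    "underage": 3.0,
    "unhealthy": 2.0,
    "weight_unstable": 3.0,
    "bcs_out_of_range": 3.0,
    "not_ideal_weight": 2.0,
    "working": 2.0,
    "kennel": 2.0,
    "invalid_data": 3.0,
}


class GeneratorConfig(BaseModel):
    """All knobs of the synthetic-cohort generator (defaults = the study
    conditions; see module docstring)."""

    n: int = Field(default=319, gt=0)
    seed: int = 0
    bw_mean: float = Field(default=23.18, gt=0)
    bw_sd: float = Field(default=13.55, gt=0)
    bw_min: float = Field(default=1.1, gt=0)
    bw_max: float = 80.0
    age_mean: float = Field(default=4.91, gt=1)
    age_sd: float = Field(default=3.49, gt=0)
    category_tables: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {f: dict(t) for f, t in DEFAULT_CATEGORY_TABLES.items()})
    true_a: float = Field(default=128.0, gt=0)
    true_b: float = 0.730
    true_c: float = -0.050
    true_k_tables: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {f: dict(t) for f, t in REFERENCE_K_TABLES.items()})
    sigma_log: float = Field(default=DEFAULT_SIGMA_LOG, ge=0)
    raw_mode: bool = False
    n_total: int = Field(default=579, gt=0)
    n_violations: int = Field(default=260, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.bw_min >= self.bw_max:
            raise ValueError("bw_min must be < bw_max")
        if self.n_violations > self.n_total:
            raise ValueError("cannot plant more violations than records")
        for factor, table in self.category_tables.items():
            if factor == "neutered_given_sex":
                continue
            total = sum(table.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError(f"probabilities for {factor!r} sum to {total:g}, not 1")
            if any(p < 0 for p in table.values()):
                raise ValueError(f"negative probability in {factor!r}")
        return self


@dataclass
class RawDatabase:
    """A raw (pre-eligibility) database plus the planted ground truth."""

    cohort: Cohort
    kennel_ids: frozenset[str]
    planted: dict[str, list[str]]  # record id -> violated rule codes

    @property
    def n_compliant(self) -> int:
        return len(self.cohort) - len(self.planted)


@lru_cache(maxsize=64)
def _truncated_lognormal_params(mean: float, sd: float, lo: float, hi: float
                                ) -> tuple[float, float]:
    """Parent (μ, σ) of a lognormal whose [lo, hi]-truncation has the given
    mean and sd.

    The target statistics describe the bounded sample itself, so matching
    the parent's moments would bias the truncated mean and sd downwards
    (the upper tail carries much of a lognormal's variance). Closed-form
    truncated moments E[X^k] ∝ Φ(β−kσ)−Φ(α−kσ) are solved for (μ, σ) by
    root finding, started from the plain (untruncated) moment match.
    """
    from scipy import optimize
    from scipy.stats import norm

    log_lo, log_hi = math.log(lo), math.log(hi)

    def moments(params: np.ndarray) -> np.ndarray:
        mu, sigma = params
        alpha, beta = (log_lo - mu) / sigma, (log_hi - mu) / sigma
        z = norm.cdf(beta) - norm.cdf(alpha)
        m1 = math.exp(mu + sigma ** 2 / 2) * (
            norm.cdf(beta - sigma) - norm.cdf(alpha - sigma)) / z
        m2 = math.exp(2 * mu + 2 * sigma ** 2) * (
            norm.cdf(beta - 2 * sigma) - norm.cdf(alpha - 2 * sigma)) / z
        return np.array([m1 - mean, m2 - (mean ** 2 + sd ** 2)])

    cv2 = (sd / mean) ** 2
    sigma0 = math.sqrt(math.log1p(cv2))
    mu0 = math.log(mean) - sigma0 ** 2 / 2
    sol = optimize.root(moments, x0=np.array([mu0, sigma0]))
    if not sol.success or sol.x[1] <= 0:
        raise ValueError(f"cannot match truncated moments mean={mean}, sd={sd}")
    return float(sol.x[0]), float(sol.x[1])


def _draw_bw(rng: np.random.Generator, cfg: GeneratorConfig, n: int) -> np.ndarray:
    """Truncated lognormal BW whose post-truncation moments match the target."""
    mu_ln, sigma_ln = _truncated_lognormal_params(
        cfg.bw_mean, cfg.bw_sd, cfg.bw_min, cfg.bw_max)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu_ln, sigma_ln, size=max(n - filled, 16))
        ok = draw[(draw >= cfg.bw_min) & (draw <= cfg.bw_max)]
        take = min(ok.size, n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def _draw_age(rng: np.random.Generator, cfg: GeneratorConfig, n: int) -> np.ndarray:
    """Adult ages as 1 + gamma, moment-matched to (age_mean, age_sd)."""
    mean_excess = cfg.age_mean - 1.0
    shape = (mean_excess / cfg.age_sd) ** 2
    scale = cfg.age_sd ** 2 / mean_excess
    return 1.0 + rng.gamma(shape, scale, size=n)


def _choice(rng: np.random.Generator, table: dict[str, float]) -> str:
    names = list(table)
    probs = np.asarray([table[k] for k in names], dtype=float)
    return names[rng.choice(len(names), p=probs / probs.sum())]


def _true_k(cfg: GeneratorConfig, levels: dict[str, str]) -> float:
    prod = 1.0
    for factor, level in levels.items():
        prod *= cfg.true_k_tables.get(factor, {}).get(level, 1.0)
    return prod


def generate_cohort(config: Optional[GeneratorConfig] = None,
                    seed: Optional[int] = None) -> Cohort:
    """Generate a protocol-compliant synthetic cohort.

    Deterministic given the seed (``seed`` overrides ``config.seed``);
    every generated record passes the eligibility cascade untouched.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    tables = cfg.category_tables
    bw = _draw_bw(rng, cfg, cfg.n)
    age = _draw_age(rng, cfg, cfg.n)
    records = []
    for i in range(cfg.n):
        sex = _choice(rng, tables["sex"])
        p_neutered = tables["neutered_given_sex"][sex]
        neutered = "yes" if rng.random() < p_neutered else "no"
        group = _choice(rng, tables["breed_group"])
        breed = _BREED_NAMES[group][rng.choice(len(_BREED_NAMES[group]))]
        bedding = _choice(rng, tables["bedding"])
        temperament = _choice(rng, tables["temperament"])
        ownership = _choice(rng, tables["ownership"])
        diet = _choice(rng, tables["diet_type"])
        meals = _choice(rng, tables["meals_per_day"])
        levels = {
            "breed_group": group,
            "sex_neuter": ("female_spayed" if sex == "female" and neutered == "yes"
                           else "female_intact" if sex == "female"
                           else "male_neutered" if neutered == "yes"
                           else "male_intact"),
            "bedding": bedding,
            "temperament": temperament,
            "diet_type": diet,
        }
        mer = (cfg.true_a * bw[i] ** cfg.true_b * age[i] ** cfg.true_c
               * _true_k(cfg, levels)
               * math.exp(rng.normal(0.0, cfg.sigma_log)))
        records.append(DogRecord(
            id=f"dog{i:04d}",
            breed=breed,
            sex=Sex(sex),
            neutered=Neutered(neutered),
            age_years=float(age[i]),
            bw_kg=float(bw[i]),
            ideal_bw_kg=float(bw[i]),
            bcs=int(rng.choice([4, 5])),
            weight_variation_pct=float(rng.uniform(0.0, 4.5)),
            bedding=Bedding(bedding),
            temperament=Temperament(temperament),
            ownership=Ownership(ownership),
            diet_type=DietType(diet),
            meals_per_day=MealsPerDay(meals),
            work_hours_per_day=float(rng.uniform(0.0, 0.9)),
            healthy=True,
            mer_kcal_d=float(mer),
        ))
    return Cohort(records, provenance=f"synthetic(seed={cfg.seed if seed is None else seed})")


def generate_raw_database(config: Optional[GeneratorConfig] = None,
                          seed: Optional[int] = None) -> RawDatabase:
    """Generate a raw database with an exact number of planted violations.

    Starts from ``n_total`` compliant records, then mutates a random subset
    of exactly ``n_violations`` of them so that each violates one or two
    eligibility rules (mix in ``_VIOLATION_WEIGHTS``). Returns the cohort,
    the set of kennel-housed ids (a pre-parse flag, not a record field) and
    the planted rule list per violating id.
    """
    cfg = config or GeneratorConfig(raw_mode=True)
    actual_seed = cfg.seed if seed is None else seed
    base_cfg = cfg.model_copy(update={"n": cfg.n_total})
    cohort = generate_cohort(base_cfg, seed=actual_seed)
    rng = np.random.default_rng(np.random.SeedSequence([actual_seed, 0xA11])
                                .generate_state(1)[0])
    idx = rng.choice(cfg.n_total, size=cfg.n_violations, replace=False)
    rules = list(_VIOLATION_WEIGHTS)
    weights = np.asarray([_VIOLATION_WEIGHTS[r] for r in rules])
    weights = weights / weights.sum()
    planted: dict[str, list[str]] = {}
    kennel_ids: set[str] = set()
    for i in idx:
        record = cohort[int(i)]
        n_rules = 1 if rng.random() < 0.8 else 2
        chosen = [str(r) for r in rng.choice(rules, size=n_rules, replace=False,
                                             p=weights)]
        for rule in chosen:
            if rule == "underage":
                record.age_years = float(rng.uniform(0.2, 0.99))
            elif rule == "unhealthy":
                record.healthy = False
            elif rule == "weight_unstable":
                record.weight_variation_pct = float(rng.uniform(5.5, 15.0))
            elif rule == "bcs_out_of_range":
                record.bcs = int(rng.choice([1, 2, 3, 6, 7, 8, 9]))
            elif rule == "not_ideal_weight":
                factor = 1.0 + rng.choice([-1, 1]) * rng.uniform(0.05, 0.25)
                record.ideal_bw_kg = float(record.bw_kg * factor)
            elif rule == "working":
                record.work_hours_per_day = float(rng.uniform(1.5, 8.0))
            elif rule == "kennel":
                kennel_ids.add(record.id)
            elif rule == "invalid_data":
                record.mer_kcal_d = None
        planted[record.id] = sorted(set(chosen))
    return RawDatabase(cohort=cohort, kennel_ids=frozenset(kennel_ids),
                       planted=planted)


def calibrate_sigma(target_r2: float,
                    config: Optional[GeneratorConfig] = None,
                    n_mc: int = 200_000,
                    seed: int = 0) -> float:
    """Residual σ_log that makes the two-predictor log-log fit hit target r².

    Decomposes the log-intake variance by a large Monte-Carlo draw from the
    configured marginals: the fit's explained part is
    Var[b·ln BW + c·ln age]; its residual collects both the planted
    correction-factor heterogeneity Var[ln ∏k] and the noise σ², so

        σ² = Var_signal · (1 − r²)/r² − Var_k,

    floored at zero (an over-dispersed k table alone can exceed the target
    residual). With no planted k effects this reduces to the plain
    variance-partition identity r² = Var_signal/(Var_signal + σ²).
    """
    if not 0.0 < target_r2 < 1.0:
        raise ValueError("target_r2 must lie strictly between 0 and 1")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    bw = _draw_bw(rng, cfg, n_mc)
    age = _draw_age(rng, cfg, n_mc)
    signal = cfg.true_b * np.log(bw) + cfg.true_c * np.log(age)
    var_signal = float(np.var(signal))

    # ln ∏k per draw, from the categorical marginals
    tables = cfg.category_tables
    log_k = np.zeros(n_mc)
    sex = rng.random(n_mc) < tables["sex"]["male"]
    p_neut = np.where(sex, tables["neutered_given_sex"]["male"],
                      tables["neutered_given_sex"]["female"])
    neutered = rng.random(n_mc) < p_neut
    sex_neuter = np.where(sex, np.where(neutered, "male_neutered", "male_intact"),
                          np.where(neutered, "female_spayed", "female_intact"))
    for factor, column in (("sex_neuter", sex_neuter),):
        table = cfg.true_k_tables.get(factor, {})
        for lvl, k in table.items():
            log_k[column == lvl] += math.log(k)
    for factor in ("breed_group", "bedding", "temperament", "diet_type"):
        table = cfg.true_k_tables.get(factor, {})
        probs = tables[factor]
        names = list(probs)
        draws = rng.choice(len(names), size=n_mc,
                           p=np.asarray([probs[k] for k in names]) / sum(probs.values()))
        for j, name in enumerate(names):
            k = table.get(name, 1.0)
            if k != 1.0:
                log_k[draws == j] += math.log(k)
    var_k = float(np.var(log_k))

    resid = var_signal * (1.0 - target_r2) / target_r2
    return math.sqrt(max(resid - var_k, 0.0))
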