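"""Categorical factor screening and multiplicative correction factors.

Seven husbandry/phenotype factors are screened on the mass- and
age-adjusted requirement (normalized MER): ownership, breed group,
sex x neuter status, bedding location, temperament, diet type and meal
frequency. Each factor gets a global Kruskal–Wallis test across its
levels; when the global test is significant, pairwise two-sided rank-sum
tests follow, and a level whose comparison against the factor's reference
population is significant receives a multiplicative correction factor

    k(level) = mean normalized MER of the level / mean of the reference,

rounded to 2 decimals (1.0 otherwise). Five factors can contribute to the
composite predictor (breed group, sex x neuter, bedding, temperament, diet
type — k1..k5); ownership and meal frequency are screened for completeness
but never deploy a correction.

Two reference conventions are supported. ``"level"`` (default) compares
each level against the factor's designated baseline level (e.g. spayed
females against intact females, outside sleepers against inside sleepers),
which matches how the deployed corrections are defined and keeps the
baseline at exactly k = 1. ``"complement"`` compares a level against all
other analysed records, which is symmetric but lets a strong level leak
into every other level's reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .regression import normalize_mer
from .stats import kruskal_wallis, rank_sum_test

#: Factors screened, in reporting order.
FACTORS = (
    "ownership",
    "breed_group",
    "sex_neuter",
    "bedding",
    "temperament",
    "diet_type",
    "meal_frequency",
)

#: Factors that may deploy a correction factor (k1..k5, in order).
K_FACTORS = ("breed_group", "sex_neuter", "bedding", "temperament", "diet_type")

#: Baseline level per factor under the "level" reference convention.
REFERENCE_LEVELS = {
    "ownership": "parents",
    "breed_group": "other",
    "sex_neuter": "female_intact",
    "bedding": "inside",
    "temperament": "normal",
    "diet_type": "dry",
    "meal_frequency": "one",
}

#: DataFrame column backing each factor (cohort frames carry the derived
#: breed_group / sex_neuter columns; meal frequency is the meals column).
_FACTOR_COLUMNS = {
    "ownership": "ownership",
    "breed_group": "breed_group",
    "sex_neuter": "sex_neuter",
    "bedding": "bedding",
    "temperament": "temperament",
    "diet_type": "diet_type",
    "meal_frequency": "meals_per_day",
}


@dataclass
class FactorLevel:
    name: str
    n: int
    mean: float
    sd: float

    def to_dict(self) -> dict:
        return {"level": self.name, "n": self.n, "mean": self.mean, "sd": self.sd}


@dataclass
class FactorResult:
    """Screen outcome for one categorical factor."""

    factor: str
    levels: list[FactorLevel]
    H: float
    p_global: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    k_factors: dict[str, float] = field(default_factory=dict)
    reference: str = ""

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "levels": [l.to_dict() for l in self.levels],
            "H": self.H,
            "p_global": self.p_global,
            "pairwise": {f"{a}|{b}": p for (a, b), p in self.pairwise.items()},
            "k_factors": dict(self.k_factors),
            "reference": self.reference,
        }


def _analysis_frame(cohort) -> pd.DataFrame:
    frame = cohort.to_frame() if isinstance(cohort, Cohort) else cohort.copy()
    frame = frame[frame["mer_kcal_d"].notna()]
    return frame


def analyse_factor(
    cohort,
    factor: str,
    b: float = 0.730,
    c: float = -0.050,
    alpha: float = 0.05,
    reference: Literal["level", "complement"] = "level",
) -> FactorResult:
    """Screen one factor on normalized MER and derive its k values.

    Records whose level for this factor is unknown are dropped from this
    analysis only. Pairwise tests run only when the global Kruskal–Wallis
    p value is below ``alpha``; k values attach only to levels whose
    pairwise comparison against the reference population is significant.
    """
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}; one of {FACTORS}")
    frame = _analysis_frame(cohort)
    col = _FACTOR_COLUMNS[factor]
    frame = frame[frame[col] != "unknown"]
    norm = normalize_mer(frame["mer_kcal_d"].to_numpy(),
                         frame["bw_kg"].to_numpy(),
                         frame["age_years"].to_numpy(), b=b, c=c)
    frame = frame.assign(_norm=norm)
    level_names = sorted(frame[col].unique())
    if len(level_names) < 2:
        raise ValueError(f"factor {factor!r} has {len(level_names)} level(s); need >= 2")
    groups = {name: frame.loc[frame[col] == name, "_norm"].to_numpy()
              for name in level_names}

    levels = [FactorLevel(name=name, n=g.size, mean=float(g.mean()),
                          sd=float(g.std(ddof=1)) if g.size > 1 else 0.0)
              for name, g in groups.items()]
    H, p_global = kruskal_wallis(list(groups.values()))

    pairwise: dict[tuple[str, str], float] = {}
    k_factors: dict[str, float] = {name: 1.0 for name in level_names}
    ref_level = REFERENCE_LEVELS[factor]
    if p_global < alpha:
        for i, x in enumerate(level_names):
            for y in level_names[i + 1:]:
                pairwise[(x, y)] = rank_sum_test(groups[x], groups[y])
        for name in level_names:
            if reference == "level":
                if name == ref_level or ref_level not in groups:
                    continue
                ref_values = groups[ref_level]
                p_ref = pairwise.get((name, ref_level),
                                     pairwise.get((ref_level, name)))
            else:
                mask = frame[col] != name
                ref_values = frame.loc[mask, "_norm"].to_numpy()
                p_ref = rank_sum_test(groups[name], ref_values)
            if p_ref is not None and p_ref < alpha:
                k_factors[name] = round(float(groups[name].mean() / ref_values.mean()), 2)
    return FactorResult(factor=factor, levels=levels, H=H, p_global=p_global,
                        pairwise=pairwise, k_factors=k_factors,
                        reference=reference)


def analyse_all_factors(
    cohort,
    b: float = 0.730,
    c: float = -0.050,
    alpha: float = 0.05,
    reference: Literal["level", "complement"] = "level",
) -> tuple[list[FactorResult], dict[str, dict[str, float]]]:
    """Screen all seven factors; assemble the deployable k tables.

    Returns the per-factor results plus ``k_tables`` mapping each of the
    five deployable factors to its non-unit level corrections (ownership
    and meal frequency are screened but never contribute).
    """
    results = [analyse_factor(cohort, f, b=b, c=c, alpha=alpha, reference=reference)
               for f in FACTORS]
    k_tables: dict[str, dict[str, float]] = {}
    for res in results:
        if res.factor in K_FACTORS:
            k_tables[res.factor] = {lvl: k for lvl, k in res.k_factors.items()
                                    if k != 1.0}
    return results, k_tables


from sklearn.base import BaseEstimator, TransformerMixin  # noqa: E402


class CorrectionFactorAnalyzer(TransformerMixin, BaseEstimator):
    """Learn multiplicative correction factors from a cohort frame.

    ``fit(X, y)`` takes the cohort frame (``Cohort.to_frame()``; must carry
    ``bw_kg``, ``age_years`` and the factor columns) and the observed MER
    ``y``; it screens the seven factors and stores the per-factor results
    and the deployable k tables. ``transform(X)`` returns each record's
    combined correction ∏k as a column vector, so ``y / transform(X)``
    is the factor-adjusted intake a base-model refit consumes.

    Parameters
    ----------
    b, c : float
        Allometric exponents defining normalized MER.
    alpha : float
        Significance level for both the global and pairwise tests.
    reference : {"level", "complement"}
        Reference-population convention (module docstring).
    """

    def __init__(self, b: float = 0.730, c: float = -0.050, alpha: float = 0.05,
                 reference: str = "level") -> None:
        self.b = b
        self.c = c
        self.alpha = alpha
        self.reference = reference

    def fit(self, X: pd.DataFrame, y=None) -> "CorrectionFactorAnalyzer":
        frame = X.copy()
        if y is not None:
            frame = frame.assign(mer_kcal_d=np.asarray(y, dtype=float))
        self.results_, self.k_tables_ = analyse_all_factors(
            frame, b=self.b, c=self.c, alpha=self.alpha, reference=self.reference)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "k_tables_"):
            raise ValueError("CorrectionFactorAnalyzer is not fitted")
        return factor_products(X, self.k_tables_)[:, None]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["k_product"], dtype=object)


def factor_products(X: pd.DataFrame, k_tables: Mapping[str, Mapping[str, float]]) -> np.ndarray:
    """Per-record combined correction ∏k from a cohort frame; unknown or
    unlisted levels contribute k = 1."""
    out = np.ones(len(X), dtype=float)
    for factor, table in k_tables.items():
        col = _FACTOR_COLUMNS.get(factor, factor)
        if col not in X.columns or not table:
            continue
        out *= X[col].map(lambda lvl: table.get(lvl, 1.0)).to_numpy(dtype=float)
    return out
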