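"""The deployable composite MER predictor and derived projections.

The composite model multiplies the allometric base by the categorical
correction factors:

    MER = k1 · k2 · k3 · k4 · k5 · a · BW^b · age^c   (kcal/d)

with k1 breed group, k2 sex x neuter status, k3 bedding location,
k4 temperament and k5 diet type; any attribute that is unknown or carries
no correction contributes k = 1.

Two parameter presets ship. ``base`` (a = 128, b = 0.730, c = -0.050) is
the plain two-predictor fit, for prediction from BW and age alone.
``composite`` (a = 128, b = 0.740, c = -0.050) pairs with the reference k
tables and is the default whenever attributes are supplied. The reference
correction set is k = 0.88 for the retriever group, 1.09 for the shepherd
group, 0.85 for spayed females, 1.05 for outside sleepers and 1.05 for
active dogs; diet type carries no deployable correction (the one suggestive
diet contrast rests on too few dogs to act on).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort
from .factors import CorrectionFactorAnalyzer, factor_products
from .regression import AllometricFit, AllometricRegressor, fit_allometric

#: Named (a, b, c) presets.
PRESETS: dict[str, tuple[float, float, float]] = {
    "base": (128.0, 0.730, -0.050),
    "composite": (128.0, 0.740, -0.050),
}

#: Reference correction-factor tables (see module docstring).
REFERENCE_K_TABLES: dict[str, dict[str, float]] = {
    "breed_group": {"retriever_low": 0.88, "shepherd_high": 1.09},
    "sex_neuter": {"female_spayed": 0.85},
    "bedding": {"outside": 1.05},
    "temperament": {"active": 1.05},
    "diet_type": {},
}


@dataclass
class CompositeModel:
    """Base constants plus k lookup tables: the deployable predictor."""

    a: float
    b: float
    c: float
    k_tables: dict[str, dict[str, float]] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be positive")
        for factor, table in self.k_tables.items():
            for lvl, k in table.items():
                if k <= 0:
                    raise ValueError(f"k({factor}={lvl}) = {k} must be positive")

    @classmethod
    def from_preset(cls, name: str = "composite",
                    k_tables: Optional[Mapping[str, Mapping[str, float]]] = None,
                    ) -> "CompositeModel":
        a, b, c = PRESETS[name]
        if k_tables is None:
            k_tables = REFERENCE_K_TABLES if name == "composite" else {}
        return cls(a=a, b=b, c=c,
                   k_tables={f: dict(t) for f, t in k_tables.items()},
                   label=name)

    def factor_product(self, attributes: Optional[Mapping[str, str]] = None) -> float:
        """Combined ∏k for one animal's factor levels (unknown → 1)."""
        if not attributes:
            return 1.0
        prod = 1.0
        for factor, level in attributes.items():
            prod *= self.k_tables.get(factor, {}).get(level, 1.0)
        return prod

    def predict(self, bw_kg: float, age_years: float,
                attributes: Optional[Mapping[str, str]] = None) -> float:
        """Predicted MER (kcal/d); strictly positive inputs required."""
        if bw_kg <= 0 or age_years <= 0:
            raise ValueError("bw_kg and age_years must be strictly positive")
        return (self.factor_product(attributes)
                * self.a * bw_kg ** self.b * age_years ** self.c)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c,
                "k_tables": {f: dict(t) for f, t in self.k_tables.items()},
                "label": self.label}

    @classmethod
    def from_dict(cls, d: dict) -> "CompositeModel":
        return cls(a=d["a"], b=d["b"], c=d["c"],
                   k_tables={f: dict(t) for f, t in d.get("k_tables", {}).items()},
                   label=d.get("label", ""))


def predict_mer(model: CompositeModel, bw_kg: float, age_years: float,
                attributes: Optional[Mapping[str, str]] = None) -> float:
    """Functional front for :meth:`CompositeModel.predict`."""
    return model.predict(bw_kg, age_years, attributes)


def metabolic_age(age_years: float, c: float = -0.050) -> float:
    """Age raised to the (negative) age exponent: the slow multiplicative
    decline of requirements with age. 1.0 at one year."""
    if age_years <= 0:
        raise ValueError("age_years must be strictly positive")
    return age_years ** c


def weight_gain_projection(model: CompositeModel, bw_kg: float, age_years: float,
                           rho_kcal_per_g: float = 7.7) -> float:
    """Projected weight gain (kg/year) from not reducing intake with age.

    An older dog needs less energy than a one-year-old of the same ideal
    weight; feeding the one-year-old amount leaves a daily surplus
    predict(bw, 1) − predict(bw, age). Accumulated over a year and stored
    as adipose tissue at ``rho_kcal_per_g`` (default 7.7 kcal per gram of
    tissue gained), the surplus converts to kilograms gained per year.
    """
    if bw_kg <= 0 or rho_kcal_per_g <= 0:
        raise ValueError("bw_kg and rho_kcal_per_g must be strictly positive")
    if age_years < 1:
        raise ValueError("projection is referenced to age 1; need age_years >= 1")
    surplus_per_day = model.predict(bw_kg, 1.0) - model.predict(bw_kg, age_years)
    return 365.0 * surplus_per_day / (rho_kcal_per_g * 1000.0)


def refit_with_factors(cohort, k_tables: Mapping[str, Mapping[str, float]]
                       ) -> AllometricFit:
    """Refit the base constants after dividing out each record's ∏k.

    With correct k tables this removes the categorical heterogeneity from
    the response, so the refitted log-scale r² exceeds the unadjusted
    two-predictor fit's (strictly, when any k differs from 1).
    """
    frame = cohort.to_frame() if isinstance(cohort, Cohort) else cohort
    if frame["mer_kcal_d"].isna().any():
        raise ValueError("cohort contains records without observed MER; filter first")
    prods = factor_products(frame, k_tables)
    adjusted = frame["mer_kcal_d"].to_numpy(dtype=float) / prods
    est = AllometricRegressor(include_age=True).fit(
        frame[["bw_kg", "age_years"]], adjusted)
    return est.fit_result()


class CompositeMERRegressor(RegressorMixin, BaseEstimator):
    """End-to-end estimator: base fit, factor screen, joint refit, predict.

    ``fit(X, y)`` expects the cohort frame (``Cohort.to_frame()``) as X and
    the observed MER (kcal/d) as y, and runs the full pipeline:

    1. OLS power-law fits on natural logs, with and without age;
    2. rank-based factor screen on normalized MER → k tables;
    3. refit of (a, b, c) on the factor-adjusted intake y / ∏k.

    ``predict(X)`` then evaluates ∏k · a · BW^b · age^c per row, applying
    whatever factor columns X carries. ``from_reference()`` builds a
    ready-to-use predictor from the shipped preset constants instead.

    Attributes
    ----------
    a_, b_, c_ : float
        Refitted base constants.
    r2_ : float
        Log-scale r² of the factor-adjusted refit.
    k_tables_ : dict
        Deployed correction factors per factor and level.
    fit_bw_, fit_bw_age_, refit_ : AllometricFit
        The three underlying fits.
    model_ : CompositeModel
        The deployable predictor object.
    """

    def __init__(self, alpha: float = 0.05, reference: str = "level") -> None:
        self.alpha = alpha
        self.reference = reference

    def fit(self, X: pd.DataFrame, y) -> "CompositeMERRegressor":
        y = np.asarray(y, dtype=float)
        base = AllometricRegressor(include_age=True).fit(
            X[["bw_kg", "age_years"]], y)
        bw_only = AllometricRegressor(include_age=False).fit(
            X[["bw_kg"]], y)
        analyzer = CorrectionFactorAnalyzer(
            b=base.b_, c=base.c_, alpha=self.alpha,
            reference=self.reference).fit(X, y)
        self.factor_results_ = analyzer.results_
        self.k_tables_ = analyzer.k_tables_
        adjusted = y / factor_products(X, self.k_tables_)
        refit = AllometricRegressor(include_age=True).fit(
            X[["bw_kg", "age_years"]], adjusted)
        self.fit_bw_ = bw_only.fit_result()
        self.fit_bw_age_ = base.fit_result()
        self.refit_ = refit.fit_result()
        self.a_, self.b_, self.c_ = refit.a_, refit.b_, refit.c_
        self.r2_ = refit.r2_
        self.model_ = CompositeModel(a=self.a_, b=self.b_, c=self.c_,
                                     k_tables=self.k_tables_, label="fitted")
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "model_")
        prods = factor_products(X, self.k_tables_)
        bw = X["bw_kg"].to_numpy(dtype=float)
        age = X["age_years"].to_numpy(dtype=float)
        return prods * self.a_ * np.power(bw, self.b_) * np.power(age, self.c_)

    @classmethod
    def from_reference(cls, preset: str = "composite") -> "CompositeMERRegressor":
        """A predictor pre-loaded with the shipped preset and k tables."""
        est = cls()
        model = CompositeModel.from_preset(preset)
        est.a_, est.b_, est.c_ = model.a, model.b, model.c
        est.k_tables_ = model.k_tables
        est.r2_ = math.nan
        est.model_ = model
        return est
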