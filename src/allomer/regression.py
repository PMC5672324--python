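"""Allometric regression of maintenance energy requirements.

The model is the power law MER = a · BW^b (optionally · age^c), fitted by
ordinary least squares after natural-log transformation:

    ln MER = ln a + b · ln BW (+ c · ln age) + ε,   ε ~ N(0, σ²).

All goodness-of-fit and uncertainty quantities (r², standard errors,
residual spread) live on the log scale, the scale on which the model is
linear and the noise additive. ``normalize_mer`` inverts the systematic
part, yielding the mass- and age-adjusted requirement
MER / (BW^b · age^c) — the quantity the categorical factor screen compares
across groups.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


class SingularFitError(ValueError):
    """The log-scale design matrix is rank-deficient (degenerate cohort)."""


@dataclass
class AllometricFit:
    """Fitted power-law constants and their log-scale uncertainty."""

    a: float
    b: float
    c: Optional[float]
    r2: float
    n: int
    se_log_a: float
    se_b: float
    se_c: Optional[float]
    sigma_log: float

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AllometricFit":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__})

    def rounded(self) -> dict:
        """Constants at reporting precision (a integer; b, c 3 decimals)."""
        out = {"a": round(self.a), "b": round(self.b, 3), "r2": round(self.r2, 3)}
        if self.c is not None:
            out["c"] = round(self.c, 3)
        return out


def _extract_bw_age(X) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Pull body weight (kg) and age (years) columns out of X.

    Accepts a DataFrame with ``bw_kg`` (and optionally ``age_years``)
    columns, or a 2-D array whose first column is BW and optional second
    column age.
    """
    if isinstance(X, pd.DataFrame):
        if "bw_kg" not in X.columns:
            raise ValueError("X must carry a 'bw_kg' column")
        bw = X["bw_kg"].to_numpy(dtype=float)
        age = X["age_years"].to_numpy(dtype=float) if "age_years" in X.columns else None
        return bw, age
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2 or arr.shape[1] not in (1, 2):
        raise ValueError("X must have one (BW) or two (BW, age) columns")
    return arr[:, 0], (arr[:, 1] if arr.shape[1] == 2 else None)


class AllometricRegressor(RegressorMixin, BaseEstimator):
    """Power-law MER model fitted by OLS on natural logarithms.

    Parameters
    ----------
    include_age : bool, default True
        Fit MER = a · BW^b · age^c; when False, the age term is dropped
        and predictions ignore age.

    Attributes
    ----------
    a_ : float
        Multiplicative constant, kcal/d at BW = 1 kg (and age = 1 y).
    b_ : float
        Body-weight exponent (the metabolic-weight exponent).
    c_ : float or None
        Age exponent (negative: requirements decline slowly with age).
    r2_ : float
        Coefficient of determination of the log-scale regression.
    sigma_log_ : float
        Residual standard deviation on the natural-log scale.
    """

    def __init__(self, include_age: bool = True) -> None:
        self.include_age = include_age

    def fit(self, X, y) -> "AllometricRegressor":
        bw, age = _extract_bw_age(X)
        y = np.asarray(y, dtype=float)
        if y.shape != bw.shape:
            raise ValueError("y length does not match X")
        if self.include_age and age is None:
            raise ValueError("include_age=True requires an age column")
        if np.any(bw <= 0) or np.any(y <= 0) or (age is not None and np.any(age <= 0)):
            raise ValueError("BW, age and MER must be strictly positive")
        n_params = 3 if self.include_age else 2
        if bw.size < n_params + 1:
            raise ValueError(f"need at least {n_params + 1} records")

        cols = [np.log(bw)]
        if self.include_age:
            cols.append(np.log(age))
        exog = sm.add_constant(np.column_stack(cols), has_constant="add")
        if np.linalg.matrix_rank(exog) < exog.shape[1]:
            raise SingularFitError(
                "degenerate design: ln BW (and ln age) are collinear or constant")
        res = sm.OLS(np.log(y), exog).fit()

        self.intercept_log_ = float(res.params[0])
        self.a_ = float(np.exp(res.params[0]))
        self.b_ = float(res.params[1])
        self.c_ = float(res.params[2]) if self.include_age else None
        self.r2_ = float(res.rsquared)
        self.n_ = int(bw.size)
        self.se_log_a_ = float(res.bse[0])
        self.se_b_ = float(res.bse[1])
        self.se_c_ = float(res.bse[2]) if self.include_age else None
        self.sigma_log_ = float(np.sqrt(res.mse_resid))
        self.n_features_in_ = 2 if self.include_age else 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "a_")
        bw, age = _extract_bw_age(X)
        out = self.a_ * np.power(bw, self.b_)
        if self.include_age:
            if age is None:
                raise ValueError("model was fitted with age; X lacks it")
            out = out * np.power(age, self.c_)
        return out

    def fit_result(self) -> AllometricFit:
        check_is_fitted(self, "a_")
        return AllometricFit(
            a=self.a_, b=self.b_, c=self.c_, r2=self.r2_, n=self.n_,
            se_log_a=self.se_log_a_, se_b=self.se_b_, se_c=self.se_c_,
            sigma_log=self.sigma_log_,
        )


def _cohort_arrays(cohort) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    bw, age, mer = [], [], []
    for r in cohort:
        if r.mer_kcal_d is None:
            raise ValueError(f"record {r.id} has no observed MER; filter first")
        bw.append(r.bw_kg)
        age.append(r.age_years)
        mer.append(r.mer_kcal_d)
    return np.asarray(bw), np.asarray(age), np.asarray(mer)


def fit_allometric(cohort, include_age: bool = True) -> AllometricFit:
    """Fit MER = a·BW^b (· age^c) on a filtered cohort; see the module doc."""
    bw, age, mer = _cohort_arrays(cohort)
    X = pd.DataFrame({"bw_kg": bw, "age_years": age})
    est = AllometricRegressor(include_age=include_age).fit(X, mer)
    return est.fit_result()


def normalize_mer(mer, bw_kg, age_years=1.0, b: float = 0.730, c: float = -0.050):
    """Mass- and age-adjusted requirement MER / (BW^b · age^c).

    With the default exponents this is the kcal · kg^-0.730 · yr^0.050 / d
    quantity the factor screen tabulates per husbandry group. Accepts
    scalars or arrays; all physical inputs must be strictly positive.
    """
    mer = np.asarray(mer, dtype=float)
    bw = np.asarray(bw_kg, dtype=float)
    age = np.asarray(age_years, dtype=float)
    if np.any(mer <= 0) or np.any(bw <= 0) or np.any(age <= 0):
        raise ValueError("MER, BW and age must be strictly positive")
    out = mer / (np.power(bw, b) * np.power(age, c))
    return float(out) if out.ndim == 0 else out


@dataclass
class ModelComparison:
    """Outcome of comparing the BW-only and BW+age fits on one cohort."""

    fit_bw: AllometricFit
    fit_bw_age: AllometricFit
    delta_r2: float
    selected: str  # "bw_age" or "bw_only"

    def to_dict(self) -> dict:
        return {
            "fit_bw": self.fit_bw.to_dict(),
            "fit_bw_age": self.fit_bw_age.to_dict(),
            "delta_r2": self.delta_r2,
            "selected": self.selected,
        }


def compare_models(fit_bw: AllometricFit, fit_bw_age: AllometricFit) -> ModelComparison:
    """Select the age model iff it improves r²; ties go to the simpler model."""
    if fit_bw.n != fit_bw_age.n:
        raise ValueError("fits come from different cohort sizes")
    delta = fit_bw_age.r2 - fit_bw.r2
    selected = "bw_age" if delta > 0 else "bw_only"
    return ModelComparison(fit_bw=fit_bw, fit_bw_age=fit_bw_age,
                           delta_r2=delta, selected=selected)
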