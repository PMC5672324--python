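"""Metabolisable energy (ME) of foods and daily intake from rations.

ME is estimated from proximate analysis with fixed factors per gram of
protein, fat and nitrogen-free extract (NFE); crude fibre contributes no
energy in either factor system. Commercial complete feeds use the modified
Atwater factors 3.5/8.5/3.5 kcal/g; homemade foods (human foodstuffs) use
the classical Atwater factors 4/9/4 kcal/g. The factor sets live in
:data:`ME_FACTORS` and can be overridden per call.
"""

from __future__ import annotations

import enum
import logging
from typing import Mapping, Sequence, Tuple

import pandas as pd
from pydantic import BaseModel, Field, model_validator

logger = logging.getLogger(__name__)


class FoodClass(str, enum.Enum):
    commercial = "commercial"
    homemade = "homemade"


#: kcal per gram of (protein, fat, NFE), by food class.
ME_FACTORS: dict[str, Tuple[float, float, float]] = {
    "commercial": (3.5, 8.5, 3.5),
    "homemade": (4.0, 9.0, 4.0),
}


class FoodItem(BaseModel):
    """One food in a dog's ration: composition per 100 g as-fed + amount."""

    name: str
    food_class: FoodClass
    protein_pct: float = Field(ge=0)
    fat_pct: float = Field(ge=0)
    fibre_pct: float = Field(ge=0)
    ash_pct: float = Field(ge=0)
    moisture_pct: float = Field(ge=0)
    grams_per_day: float = Field(ge=0)

    @model_validator(mode="after")
    def _closure(self) -> "FoodItem":
        total = (self.protein_pct + self.fat_pct + self.fibre_pct
                 + self.ash_pct + self.moisture_pct)
        if total > 100 + 1e-9:
            raise ValueError(
                f"proximate components sum to {total:g} g/100 g > 100 (NFE < 0)")
        return self


def nfe(food: FoodItem) -> float:
    """Nitrogen-free extract, g/100 g: the carbohydrate fraction by difference."""
    return 100.0 - (food.protein_pct + food.fat_pct + food.fibre_pct
                    + food.ash_pct + food.moisture_pct)


def me_kcal_per_100g(
    food: FoodItem,
    factors: Mapping[str, Tuple[float, float, float]] | None = None,
) -> float:
    """ME density of a food (kcal/100 g) from its proximate analysis."""
    fac = (factors or ME_FACTORS)[food.food_class.value]
    return fac[0] * food.protein_pct + fac[1] * food.fat_pct + fac[2] * nfe(food)


def daily_intake_kcal(
    ration: Sequence[FoodItem],
    factors: Mapping[str, Tuple[float, float, float]] | None = None,
) -> float:
    """Total daily ME intake (kcal/d) of a ration; additive over items."""
    if not ration:
        raise ValueError("empty ration: daily intake (and hence MER) undefined")
    return sum(item.grams_per_day * me_kcal_per_100g(item, factors) / 100.0
               for item in ration)


RATION_COLUMNS = (
    "dog_id",
    "food_name",
    "food_class",
    "protein_pct",
    "fat_pct",
    "fibre_pct",
    "ash_pct",
    "moisture_pct",
    "grams_per_day",
)


def read_ration(path: str) -> dict[str, list[FoodItem]]:
    """Read a ration CSV into per-dog food lists."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"ration file missing column(s): {', '.join(missing)}")
    rations: dict[str, list[FoodItem]] = {}
    for _, row in frame.iterrows():
        item = FoodItem(
            name=row["food_name"],
            food_class=FoodClass(row["food_class"].strip().lower()),
            protein_pct=float(row["protein_pct"]),
            fat_pct=float(row["fat_pct"]),
            fibre_pct=float(row["fibre_pct"]),
            ash_pct=float(row["ash_pct"]),
            moisture_pct=float(row["moisture_pct"]),
            grams_per_day=float(row["grams_per_day"]),
        )
        rations.setdefault(str(row["dog_id"]).strip(), []).append(item)
    return rations


def attach_rations(cohort, rations: Mapping[str, Sequence[FoodItem]]) -> None:
    """Fill each record's MER from its ration when not directly observed.

    A directly recorded ``mer_kcal_d`` always wins; when both are present
    the ration-derived value is discarded with a warning.
    """
    for record in cohort:
        ration = rations.get(record.id)
        if ration is None:
            continue
        computed = daily_intake_kcal(ration)
        if record.mer_kcal_d is not None:
            logger.warning(
                "dog %s has both a recorded intake (%.1f kcal/d) and a ration "
                "(%.1f kcal/d); keeping the recorded value",
                record.id, record.mer_kcal_d, computed)
            continue
        record.mer_kcal_d = computed
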