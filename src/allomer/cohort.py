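"""Domain types for dog records and cohorts, with CSV input/output.

A :class:`DogRecord` holds one animal's phenotype, husbandry, diet class and
observed daily metabolisable-energy intake (kcal/d) at stable body weight —
the quantity taken as the dog's maintenance energy requirement (MER).
A :class:`Cohort` is an ordered, id-unique collection of records and is the
unit every fitting operation consumes.
"""

from __future__ import annotations

import enum
import unicodedata
from typing import Iterable, Iterator, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator


class SchemaError(ValueError):
    """The CSV header does not match the documented cohort schema."""


class RecordError(ValueError):
    """A row could not be parsed or violates a record invariant."""

    def __init__(self, row: int, message: str) -> None:
        self.row = row
        super().__init__(f"row {row}: {message}")


class BreedGroup(str, enum.Enum):
    retriever_low = "retriever_low"
    shepherd_high = "shepherd_high"
    other = "other"


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class Neutered(str, enum.Enum):
    yes = "yes"
    no = "no"
    unknown = "unknown"


class Bedding(str, enum.Enum):
    inside = "inside"
    outside = "outside"
    unknown = "unknown"


class Temperament(str, enum.Enum):
    calm = "calm"
    normal = "normal"
    active = "active"
    unknown = "unknown"


class Ownership(str, enum.Enum):
    student = "student"
    parents = "parents"
    family = "family"
    other_student = "other_student"
    other = "other"
    unknown = "unknown"


class DietType(str, enum.Enum):
    dry = "dry"
    moist = "moist"
    mixed_commercial = "mixed_commercial"
    commercial_plus_leftovers = "commercial_plus_leftovers"
    homemade = "homemade"


class MealsPerDay(str, enum.Enum):
    one = "one"
    two = "two"
    three = "three"
    four = "four"
    ad_libitum = "ad_libitum"


#: Enum fields whose empty CSV cell maps to ``unknown``.
_OPTIONAL_ENUMS = {"neutered", "bedding", "temperament", "ownership"}

#: Breed-name fragments (lowercase ASCII) mapping to the two special groups.
#: Retrievers (Labrador, golden) carry low mass-adjusted requirements; Belgian
#: and Beauce shepherds carry high ones; everything else is ``other``.
_RETRIEVER_SYNONYMS = ("labrador", "golden retriever")
_SHEPHERD_SYNONYMS = (
    "belgian shepherd",
    "berger belge",
    "beauceron",
    "beauce shepherd",
)


def _fold(text: str) -> str:
    """Lowercase and strip diacritics so breed matching is accent-proof."""
    norm = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in norm if not unicodedata.combining(ch)).lower()


def assign_breed_group(breed: str) -> BreedGroup:
    """Map a free-text breed name to its energy-requirement group.

    Labrador and golden retrievers form the low-requirement group, Belgian
    and Beauce shepherd dogs the high-requirement group; any unrecognised
    breed (including mixed breeds) falls back to ``other``. Matching is
    case- and diacritic-insensitive substring matching on a curated synonym
    list, so e.g. ``"Berger Belge Malinois"`` resolves to ``shepherd_high``
    while ``"German shepherd dog"`` stays ``other``.
    """
    folded = _fold(breed)
    if any(s in folded for s in _SHEPHERD_SYNONYMS):
        return BreedGroup.shepherd_high
    if any(s in folded for s in _RETRIEVER_SYNONYMS):
        return BreedGroup.retriever_low
    return BreedGroup.other


class DogRecord(BaseModel):
    """One animal's phenotype, husbandry and observed energy intake.

    ``mer_kcal_d`` is the daily metabolisable-energy intake observed at
    stable weight and body condition; it may be absent (``None``) when only
    an itemised ration is available, in which case
    :func:`allomer.energy.daily_intake_kcal` supplies it.
    """

    model_config = ConfigDict(validate_assignment=True)

    id: str
    breed: str
    sex: Sex
    neutered: Neutered = Neutered.unknown
    age_years: float = Field(gt=0)
    bw_kg: float = Field(gt=0)
    ideal_bw_kg: float = Field(gt=0)
    bcs: int = Field(ge=1, le=9, description="body condition score, 9-point scale")
    weight_variation_pct: float = Field(ge=0)
    bedding: Bedding = Bedding.unknown
    temperament: Temperament = Temperament.unknown
    ownership: Ownership = Ownership.unknown
    diet_type: DietType
    meals_per_day: MealsPerDay
    work_hours_per_day: float = Field(ge=0)
    healthy: bool
    mer_kcal_d: Optional[float] = Field(default=None, gt=0)

    @property
    def breed_group(self) -> BreedGroup:
        return assign_breed_group(self.breed)

    @field_validator("bcs", mode="before")
    @classmethod
    def _bcs_integral(cls, v: object) -> object:
        if isinstance(v, float) and not v.is_integer():
            raise ValueError("bcs must be an integer in 1-9")
        return v


#: Exact column order of the cohort CSV.
COHORT_COLUMNS = (
    "id",
    "breed",
    "sex",
    "neutered",
    "age_years",
    "bw_kg",
    "ideal_bw_kg",
    "bcs",
    "weight_variation_pct",
    "bedding",
    "temperament",
    "ownership",
    "diet_type",
    "meals_per_day",
    "work_hours_per_day",
    "healthy",
    "mer_kcal_d",
)

_ENUM_FIELDS = {
    "sex": Sex,
    "neutered": Neutered,
    "bedding": Bedding,
    "temperament": Temperament,
    "ownership": Ownership,
    "diet_type": DietType,
    "meals_per_day": MealsPerDay,
}

_FLOAT_FIELDS = ("age_years", "bw_kg", "ideal_bw_kg", "weight_variation_pct",
                 "work_hours_per_day")


class Cohort:
    """Ordered collection of :class:`DogRecord` with unique ids."""

    def __init__(self, records: Iterable[DogRecord], provenance: str = "") -> None:
        self.records: list[DogRecord] = list(records)
        self.provenance = provenance
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[DogRecord]:
        return iter(self.records)

    def __getitem__(self, idx: int) -> DogRecord:
        return self.records[idx]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Cohort) and self.records == other.records

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the CSV schema plus derived analysis columns.

        Adds ``breed_group`` (derived from ``breed``) and ``sex_neuter``
        (the combined sex x neuter-status level used in factor screening).
        """
        rows = []
        for r in self.records:
            d = {c: getattr(r, c) for c in COHORT_COLUMNS}
            for field, _ in _ENUM_FIELDS.items():
                d[field] = d[field].value
            d["breed_group"] = r.breed_group.value
            d["sex_neuter"] = sex_neuter_level(r.sex, r.neutered)
            rows.append(d)
        frame = pd.DataFrame(rows, columns=list(COHORT_COLUMNS) + ["breed_group", "sex_neuter"])
        if frame.empty:
            frame = pd.DataFrame(columns=list(COHORT_COLUMNS) + ["breed_group", "sex_neuter"])
        return frame


def sex_neuter_level(sex: Sex, neutered: Neutered) -> str:
    """Combined sex/neuter-status level; spayed females are the level the
    composite model corrects (k = 0.85)."""
    if neutered is Neutered.unknown:
        return "unknown"
    if sex is Sex.female:
        return "female_spayed" if neutered is Neutered.yes else "female_intact"
    return "male_neutered" if neutered is Neutered.yes else "male_intact"


def _parse_row(idx: int, row: "pd.Series") -> DogRecord:
    data: dict[str, object] = {}
    data["id"] = str(row["id"]).strip()
    data["breed"] = str(row["breed"]).strip()
    for field, enum_cls in _ENUM_FIELDS.items():
        raw = str(row[field]).strip().lower()
        if raw == "":
            if field in _OPTIONAL_ENUMS:
                data[field] = enum_cls("unknown")
                continue
            raise RecordError(idx, f"empty mandatory field {field!r}")
        try:
            data[field] = enum_cls(raw)
        except ValueError as exc:
            raise RecordError(idx, f"invalid {field!r} value {raw!r}") from exc
    for field in _FLOAT_FIELDS:
        raw = str(row[field]).strip()
        try:
            data[field] = float(raw)
        except ValueError as exc:
            raise RecordError(idx, f"unparseable numeric {field!r}={raw!r}") from exc
    raw_bcs = str(row["bcs"]).strip()
    try:
        data["bcs"] = int(float(raw_bcs))
        if float(raw_bcs) != data["bcs"]:
            raise ValueError
    except ValueError as exc:
        raise RecordError(idx, f"unparseable integer bcs={raw_bcs!r}") from exc
    raw_healthy = str(row["healthy"]).strip().lower()
    if raw_healthy in {"true", "1", "yes"}:
        data["healthy"] = True
    elif raw_healthy in {"false", "0", "no"}:
        data["healthy"] = False
    else:
        raise RecordError(idx, f"unparseable boolean healthy={raw_healthy!r}")
    raw_mer = str(row["mer_kcal_d"]).strip()
    if raw_mer == "":
        data["mer_kcal_d"] = None
    else:
        try:
            data["mer_kcal_d"] = float(raw_mer)
        except ValueError as exc:
            raise RecordError(idx, f"unparseable numeric mer_kcal_d={raw_mer!r}") from exc
    try:
        return DogRecord(**data)
    except Exception as exc:  # pydantic ValidationError
        if data["bcs"] is not None and not (1 <= int(data["bcs"]) <= 9):
            raise RecordError(idx, "bcs ∈ 1–9 violated") from exc
        raise RecordError(idx, str(exc)) from exc


def read_cohort(path: str, provenance: str | None = None) -> Cohort:
    """Read a cohort CSV (schema in :data:`COHORT_COLUMNS`).

    Enum cells parse case-insensitively; empty cells map to ``unknown``
    for fields that admit it (neuter status, bedding, temperament,
    ownership) and to an absent MER, and are errors elsewhere.

    Raises
    ------
    SchemaError
        If a mandatory column is missing (the message names it).
    RecordError
        For an unparseable or invariant-violating row (carries the index).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    records = [_parse_row(i, row) for i, row in frame.iterrows()]
    return Cohort(records, provenance=provenance if provenance is not None else str(path))


def write_cohort(cohort: Cohort, path: str) -> None:
    """Write a cohort CSV that :func:`read_cohort` restores field-for-field.

    ``unknown`` enum values and absent MER are written as empty cells;
    floats use Python's shortest round-trip representation.
    """
    rows = []
    for r in cohort:
        d: dict[str, object] = {}
        for col in COHORT_COLUMNS:
            v = getattr(r, col)
            if isinstance(v, enum.Enum):
                d[col] = "" if v.value == "unknown" else v.value
            elif isinstance(v, bool):
                d[col] = "true" if v else "false"
            elif v is None:
                d[col] = ""
            else:
                d[col] = v
        rows.append(d)
    frame = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    frame.to_csv(path, index=False)
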