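"""Eligibility cascade: retain only healthy adult dogs at stable, ideal weight.

A record is retained iff all of the following hold: healthy; at least one
year old; body weight stable within 5 % over the observation window; body
condition score 4 or 5 (ideal); actual weight equal to ideal weight within
a small relative tolerance; at most 1 h/d of forced work; not housed in a
cage or kennel; and an observed daily energy intake present. Every violated
rule is logged (not only the first), so the exclusion log is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Mapping

from .cohort import Cohort, DogRecord

#: Stable machine-readable rule codes, in evaluation order.
RULE_CODES = (
    "unhealthy",
    "underage",
    "weight_unstable",
    "bcs_out_of_range",
    "not_ideal_weight",
    "working",
    "kennel",
    "invalid_data",
)


@dataclass
class ExclusionReport:
    """Outcome of the eligibility cascade on one input cohort."""

    retained: Cohort
    excluded: list[tuple[str, list[str]]]
    counts_per_rule: dict[str, int] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.excluded)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": len(self.retained),
            "n_excluded": len(self.excluded),
            "excluded": [{"id": i, "rules": r} for i, r in self.excluded],
            "counts_per_rule": dict(self.counts_per_rule),
        }


def violated_rules(
    record: DogRecord,
    kennel_ids: Collection[str] = (),
    *,
    ideal_bw_rel_tol: float = 0.005,
    max_weight_variation_pct: float = 5.0,
    max_work_hours: float = 1.0,
) -> list[str]:
    """All eligibility rules the record violates (empty list = retained)."""
    codes: list[str] = []
    if not record.healthy:
        codes.append("unhealthy")
    if record.age_years < 1.0:
        codes.append("underage")
    if record.weight_variation_pct > max_weight_variation_pct:
        codes.append("weight_unstable")
    if record.bcs not in (4, 5):
        codes.append("bcs_out_of_range")
    if abs(record.bw_kg - record.ideal_bw_kg) / record.ideal_bw_kg > ideal_bw_rel_tol:
        codes.append("not_ideal_weight")
    if record.work_hours_per_day > max_work_hours:
        codes.append("working")
    if record.id in kennel_ids:
        codes.append("kennel")
    if record.mer_kcal_d is None:
        codes.append("invalid_data")
    return codes


def apply_exclusions(
    cohort: Cohort,
    kennel_ids: Collection[str] = (),
    *,
    ideal_bw_rel_tol: float = 0.005,
    max_weight_variation_pct: float = 5.0,
    max_work_hours: float = 1.0,
) -> ExclusionReport:
    """Apply the eligibility cascade and return an auditable report.

    ``kennel_ids`` carries the cage/kennel housing flag, which is recorded
    at intake but is not a field of the retained study population (no
    retained dog has it). The filter is idempotent: re-filtering
    ``report.retained`` excludes nothing.
    """
    kennel = frozenset(kennel_ids)
    retained: list[DogRecord] = []
    excluded: list[tuple[str, list[str]]] = []
    counts: dict[str, int] = {code: 0 for code in RULE_CODES}
    for record in cohort:
        codes = violated_rules(
            record,
            kennel,
            ideal_bw_rel_tol=ideal_bw_rel_tol,
            max_weight_variation_pct=max_weight_variation_pct,
            max_work_hours=max_work_hours,
        )
        if codes:
            excluded.append((record.id, codes))
            for c in codes:
                counts[c] += 1
        else:
            retained.append(record)
    counts = {c: n for c, n in counts.items() if n}
    report = ExclusionReport(
        retained=Cohort(retained, provenance=f"{cohort.provenance} [filtered]"),
        excluded=excluded,
        counts_per_rule=counts,
    )
    return report
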