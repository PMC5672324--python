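"""End-to-end pipeline orchestration and report generation.

``run_full_pipeline`` chains the stages — eligibility filter, allometric
fits with and without age, factor screen, factor-adjusted refit — and
returns a single JSON-serialisable report: exclusion counts, both fits,
per-factor tables with compact-letter significance groupings, the k
tables and the deployable composite model. The Markdown rendering is
generated from that JSON dict (single source), and a fixed seed makes the
whole report byte-reproducible.
"""

from __future__ import annotations

import json
from typing import Optional

from .cohort import Cohort
from .composite import CompositeMERRegressor, CompositeModel
from .filters import ExclusionReport, apply_exclusions
from .regression import compare_models
from .simulate import GeneratorConfig, generate_cohort, generate_raw_database
from .stats import compact_letter_display

REPORT_SCHEMA_VERSION = "1.0"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_full_pipeline(
    cohort: Optional[Cohort] = None,
    config: Optional[GeneratorConfig] = None,
    seed: Optional[int] = None,
    alpha: float = 0.05,
    reference: str = "level",
    kennel_ids=(),
) -> dict:
    """Run filter → fits → factor screen → refit and assemble the report.

    Either an existing ``cohort`` or a generator ``config`` must be given;
    with a config, a synthetic cohort (raw database when ``raw_mode``) is
    generated first. Any stage failure raises :class:`PipelineError`
    naming the stage.
    """
    if cohort is None:
        if config is None:
            raise ValueError("need either a cohort or a generator config")
        try:
            if config.raw_mode:
                raw = generate_raw_database(config, seed=seed)
                cohort, kennel_ids = raw.cohort, raw.kennel_ids
            else:
                cohort = generate_cohort(config, seed=seed)
        except Exception as exc:
            raise PipelineError("generate", exc) from exc

    try:
        exclusion: ExclusionReport = apply_exclusions(cohort, kennel_ids)
    except Exception as exc:
        raise PipelineError("apply_exclusions", exc) from exc

    clean = exclusion.retained
    frame = clean.to_frame()
    try:
        est = CompositeMERRegressor(alpha=alpha, reference=reference)
        est.fit(frame, frame["mer_kcal_d"].to_numpy())
    except Exception as exc:
        raise PipelineError("fit", exc) from exc

    comparison = compare_models(est.fit_bw_, est.fit_bw_age_)

    factor_tables = []
    for res in est.factor_results_:
        letters = compact_letter_display(
            [l.name for l in res.levels], res.pairwise, alpha=alpha)
        table = res.to_dict()
        for row in table["levels"]:
            row["letters"] = letters[row["level"]]
        factor_tables.append(table)

    model = CompositeModel(a=est.a_, b=est.b_, c=est.c_,
                           k_tables=est.k_tables_, label="fitted")
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": cohort.provenance,
        "exclusions": exclusion.to_dict(),
        "fit_bw": est.fit_bw_.to_dict(),
        "fit_bw_age": est.fit_bw_age_.to_dict(),
        "model_comparison": {"delta_r2": comparison.delta_r2,
                             "selected": comparison.selected},
        "factors": factor_tables,
        "k_tables": est.k_tables_,
        "refit": est.refit_.to_dict(),
        "composite_model": model.to_dict(),
    }


def report_to_markdown(report: dict) -> str:
    """Human-readable rendering of a pipeline report dict."""
    lines = [
        "# Maintenance energy requirement analysis",
        "",
        f"Input: {report['provenance']}",
        "",
        "## Eligibility",
        "",
        (f"{report['exclusions']['n_retained']} of "
         f"{report['exclusions']['n_input']} records retained "
         f"({report['exclusions']['n_excluded']} excluded)."),
        "",
    ]
    if report["exclusions"]["counts_per_rule"]:
        lines.append("| rule | n |")
        lines.append("| --- | --- |")
        for rule, n in report["exclusions"]["counts_per_rule"].items():
            lines.append(f"| {rule} | {n} |")
        lines.append("")
    lines += ["## Allometric fits (log-scale OLS)", ""]
    for key, label in (("fit_bw", "MER = a · BW^b"),
                       ("fit_bw_age", "MER = a · BW^b · age^c"),
                       ("refit", "factor-adjusted refit")):
        f = report[key]
        c_txt = "" if f["c"] is None else f" · age^{f['c']:.3f}"
        lines.append(f"- {label}: MER = {f['a']:.0f} × BW^{f['b']:.3f}{c_txt} "
                     f"(r² {f['r2']:.3f}, n {f['n']})")
    lines += ["", "## Factor screen (normalized MER per level)", ""]
    for table in report["factors"]:
        lines.append(f"### {table['factor']} "
                     f"(H = {table['H']:.2f}, p = {table['p_global']:.3g})")
        lines.append("")
        lines.append("| level | n | mean | sd | | k |")
        lines.append("| --- | --- | --- | --- | --- | --- |")
        for row in table["levels"]:
            k = table["k_factors"].get(row["level"], 1.0)
            lines.append(f"| {row['level']} | {row['n']} | {row['mean']:.1f} "
                         f"| {row['sd']:.1f} | {row['letters']} | {k:.2f} |")
        lines.append("")
    m = report["composite_model"]
    lines += ["## Composite model", "",
              (f"MER = ∏k × {m['a']:.0f} × BW^{m['b']:.3f} × age^{m['c']:.3f} "
               f"kcal/d (r² {report['refit']['r2']:.3f})"), ""]
    return "\n".join(lines)


def dump_report(report: dict, json_path: str, md_path: Optional[str] = None) -> None:
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if md_path:
        with open(md_path, "w", encoding="utf-8") as fh:
            fh.write(report_to_markdown(report))
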