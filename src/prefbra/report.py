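"""Markdown rendering of a pipeline results object.

A pure renderer: every number shown comes from the results dictionary
produced by :func:`prefbra.pipeline.run_pipeline`. Proportions are shown
as percentages at one decimal; years as years.
"""

from __future__ import annotations

from typing import Any, Mapping

_YEAR_ATTRS = {"proven_to_work"}


def _fmt_level(attribute: str, level: float) -> str:
    if attribute in _YEAR_ATTRS:
        return f"{level:.1f} yrs"
    return f"{100.0 * level:.1f}%"


def render_report(results: Mapping[str, Any]) -> str:
    alt_a, alt_b = results["alternatives"]
    lines = [
        f"# Benefit-risk analysis: {alt_a} vs {alt_b}",
        "",
        f"- configuration digest: `{results['config_digest']}`",
        f"- seed: {results['seed']}",
        f"- panel: {results['panel']['n_respondents']} respondents "
        f"({results['panel']['n_straight_liners']} straight-liners"
        f"{', excluded' if results['panel']['exclude_straight_liners'] else ', retained'})",
        "",
        "## Elicited indifference amounts (MIR/MRB)",
        "",
        "| Attribute | Group | Mean | SD | n | MIR > impact |",
        "|---|---|---|---|---|---|",
    ]
    for row in results["panel_summary"]:
        mean = _fmt_level(row["attribute"], row["mean_mir"]) \
            if row["n"] else "—"
        sd = _fmt_level(row["attribute"], row["sd_mir"]) \
            if row["n"] > 1 else "—"
        prop = (f"{100.0 * row['prop_mir_exceeds_impact']:.1f}%"
                if row["prop_mir_exceeds_impact"] == row["prop_mir_exceeds_impact"]
                else "—")
        lines.append(f"| {row['attribute']} | {row['group']} | {mean} "
                     f"| {sd} | {row['n']} | {prop} |")

    lines += ["", "## Incremental value and thresholds", ""]
    for group, block in results["groups"].items():
        lines += [
            f"### Group: {group}",
            "",
            f"Overall incremental value U({alt_a}) − U({alt_b}) = "
            f"{block['overall_increment']:.3f} (raw, invasiveness swing = 1)",
            "",
            "| Attribute | Kind | Threshold | Clamped |",
            "|---|---|---|---|",
        ]
        for name, t in block["thresholds"].items():
            lines.append(
                f"| {name} | {t['kind']} | {_fmt_level(name, t['level'])} "
                f"| {'yes' if t['clamped'] else 'no'} |")
        lines.append("")

    mcs = results["mcs"]
    lines += [
        "## Monte Carlo simulation",
        "",
        f"- iterations: {mcs['n_iterations']}, scheme: {mcs['scheme']}, "
        f"subgroup: {mcs['subgroup']}, exclusions: {mcs['exclusions']}",
        f"- Monte-Carlo SE: {100.0 * mcs['mc_se']:.2f} pp",
        "",
        "| Alternative | P(ranked first) |",
        "|---|---|",
    ]
    for name, p in mcs["p_first"].items():
        lines.append(f"| {name} | {100.0 * p:.1f}% |")
    lines.append("")
    return "\n".join(lines)
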