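"""End-to-end analysis: panel → weights → value model → thresholds → MCS.

``run_pipeline`` is the programmatic entry point behind the command-line
interface; it produces a single machine-readable results dictionary from
which the human-readable report is rendered (the report is a pure
renderer — every number it shows is in the results object).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

from . import io as _io
from .datasets import load_study_config
from .model import AlternativeProfile, Attribute, ModelError, \
    incremental_value, threshold_table
from .montecarlo import run_mcs
from .performance import impact_table
from .synth import PanelSpec, generate_panel
from .weights import RespondentRecord, filter_panel, group_weights, \
    panel_summary

log = logging.getLogger("prefbra")

GROUPS = ("all", "under60", "ge60")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``panel_path`` / ``panel_spec`` / ``panel`` supplies the
    respondent panel. Without a model config path the packaged study
    configuration is used.
    """

    config_path: str | Path | None = None
    panel_path: str | Path | None = None
    panel_spec: PanelSpec | None = None
    panel: Sequence[RespondentRecord] | None = None
    n_iterations: int = 10_000
    seed: int | None = None
    scheme: str = "respondent-bootstrap"
    exclude_straight_liners: bool = False
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        sources = [s is not None
                   for s in (self.panel_path, self.panel_spec, self.panel)]
        if sum(sources) != 1:
            raise ModelError(
                "exactly one of panel_path, panel_spec or panel must be set")


def _load_model(config: RunConfig) -> tuple[list[Attribute],
                                            dict[str, AlternativeProfile],
                                            Mapping[str, Any]]:
    if config.config_path is not None:
        return _io.read_config(config.config_path)
    return load_study_config()


def _load_panel(config: RunConfig,
                attributes: Sequence[Attribute]) -> list[RespondentRecord]:
    if config.panel is not None:
        return list(config.panel)
    if config.panel_path is not None:
        return _io.read_panel(config.panel_path, attributes)
    panel, _ = generate_panel(config.panel_spec, seed=config.seed)
    return panel


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full benefit-risk analysis and return the results object.

    Stages: load (or synthesise) the panel, derive group weight vectors,
    evaluate the incremental value decomposition, the per-attribute
    threshold analysis for every age group, the Table-style panel summary,
    and the Monte Carlo ranking simulation. Any stage error is re-raised
    with the stage name attached.
    """
    attributes, profiles, _transforms = _stage(
        "config", lambda: _load_model(config))
    if len(profiles) != 2:
        raise ModelError("the pipeline compares exactly two alternatives")
    (name_a, prof_a), (name_b, prof_b) = profiles.items()

    panel = _stage("panel", lambda: _load_panel(config, attributes))
    log.info("panel: %d respondents, %d straight-liners", len(panel),
             sum(r.straight_liner for r in panel))

    impacts = _stage("impacts",
                     lambda: impact_table(prof_a, prof_b, attributes))
    summary = _stage("summary",
                     lambda: panel_summary(panel, attributes, impacts))

    results: dict[str, Any] = {
        "alternatives": [name_a, name_b],
        "seed": config.seed,
        "config_digest": _io.config_digest(attributes, profiles),
        "impacts": impacts,
        "panel": {
            "n_respondents": len(panel),
            "n_straight_liners": sum(r.straight_liner for r in panel),
            "exclude_straight_liners": config.exclude_straight_liners,
        },
        "panel_summary": summary.to_dict(orient="records"),
        "groups": {},
    }

    def analyse_group(group: str) -> dict[str, Any]:
        weights = group_weights(
            panel, attributes, group,
            exclude_straight_liners=config.exclude_straight_liners)
        decomp = incremental_value(prof_a, prof_b, weights, attributes)
        thresholds = threshold_table(prof_a, prof_b, weights, attributes)
        return {
            "weights": {"raw": dict(weights.raw),
                        "normalized": dict(weights.normalized)},
            "overall_increment": decomp.overall_increment,
            "per_attribute_increment": dict(decomp.per_attribute),
            "thresholds": {
                name: {"level": t.threshold_level, "kind": t.kind.value,
                       "raw_level": t.raw_level, "clamped": t.clamped}
                for name, t in thresholds.items()
            },
        }

    for group in GROUPS:
        try:
            results["groups"][group] = _stage(f"weights/{group}",
                                              lambda g=group: analyse_group(g))
        except ModelError:
            if group == "all":
                raise
            log.warning("group %s empty or incomplete; skipped", group)

    mcs = _stage("mcs", lambda: run_mcs(
        [prof_a, prof_b], panel, attributes,
        n_iterations=config.n_iterations, seed=config.seed,
        scheme=config.scheme,
        exclude_straight_liners=config.exclude_straight_liners))
    results["mcs"] = mcs.to_dict()

    if config.out_dir is not None:
        _io.write_results(config.out_dir, {"results": results})
    return results


def _stage(name: str, thunk):
    try:
        return thunk()
    except Exception as exc:
        raise type(exc)(f"pipeline stage {name!r}: {exc}") from exc
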