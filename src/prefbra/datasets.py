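"""Packaged study inputs: attribute configuration and preference summaries."""

from __future__ import annotations

import json
from importlib import resources
from typing import Any

from .model import AlternativeProfile, Attribute, PerformanceEstimate


def _load_json(name: str) -> dict[str, Any]:
    with resources.files("prefbra.data").joinpath(name).open() as fh:
        return json.load(fh)


def parse_config(doc: dict[str, Any]) -> tuple[list[Attribute],
                                               dict[str, AlternativeProfile],
                                               dict[str, Any]]:
    """Build model objects from a configuration document (see io.read_config)."""
    from .model import ModelError

    for key in ("attributes", "alternatives"):
        if key not in doc:
            raise ModelError(f"configuration missing {key!r} section")
    attributes = [Attribute(name=a["name"], direction=a["direction"],
                            worst=a["worst"], best=a["best"],
                            units=a.get("units", "proportion"))
                  for a in doc["attributes"]]
    names = {a.name for a in attributes}
    profiles: dict[str, AlternativeProfile] = {}
    for alt in doc["alternatives"]:
        perf = {}
        for attr_name, cell in alt["performance"].items():
            if attr_name not in names:
                raise ModelError(
                    f"alternative {alt['name']!r}: unknown attribute "
                    f"{attr_name!r}")
            perf[attr_name] = PerformanceEstimate(
                mean=cell["mean"], ci_low=cell.get("ci_low"),
                ci_high=cell.get("ci_high"))
        profile = AlternativeProfile(name=alt["name"], performance=perf)
        profile.validate_against(attributes)
        profiles[alt["name"]] = profile
    return attributes, profiles, doc.get("transforms", {})


def load_study_config() -> tuple[list[Attribute],
                                 dict[str, AlternativeProfile],
                                 dict[str, Any]]:
    """The TAVR-vs-SAVR attribute set and performance profiles."""
    return parse_config(_load_json("study_config.json"))


def load_study_preferences() -> dict[str, Any]:
    """Published MIR/MRB summary per attribute × age group (model units)."""
    return _load_json("study_preferences.json")


def study_mean_mirs(group: str = "all") -> dict[str, float]:
    """Group-mean indifference amounts from the published summary."""
    summary = load_study_preferences()["mir_summary"]
    return {name: cells[group]["mean"] for name, cells in summary.items()}
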