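"""File formats: configuration JSON, panel CSV, choice-log CSV, results.

Panel CSV (long form): ``respondent_id, age_group, attribute, mir,
censored, straight_liner`` — one row per completed attribute. Wide form:
one row per respondent, one ``mir_<attribute>`` column per attribute.
Choice-log CSV: ``respondent_id, [age_group,] attribute, iteration,
offered_change, chose_procedure``.

All readers validate strictly and name the offending field and row; all
writers round-trip losslessly through their reader.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

from .datasets import parse_config
from .elicitation import ChoiceResponse, Ladder, estimate_indifference, \
    is_straight_pattern
from .model import AlternativeProfile, Attribute, ModelError
from .weights import AGE_GROUPS, RespondentRecord


class ValidationError(ModelError):
    """Malformed input file."""


def read_config(path: str | Path) -> tuple[list[Attribute],
                                           dict[str, AlternativeProfile],
                                           dict[str, Any]]:
    """Parse and validate an attribute/alternative configuration document."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: invalid JSON: {exc}") from exc
    try:
        return parse_config(doc)
    except (ModelError, KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_config(path: str | Path,
                 attributes: Sequence[Attribute],
                 profiles: Mapping[str, AlternativeProfile],
                 transforms: Mapping[str, Any] | None = None) -> None:
    doc = {
        "attributes": [
            {"name": a.name, "direction": a.direction.value, "worst": a.worst,
             "best": a.best, "units": a.units}
            for a in attributes
        ],
        "alternatives": [
            {"name": p.name, "performance": {
                name: {k: v for k, v in
                       (("mean", est.mean), ("ci_low", est.ci_low),
                        ("ci_high", est.ci_high)) if v is not None}
                for name, est in p.performance.items()}}
            for p in profiles.values()
        ],
        "transforms": dict(transforms or {}),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


# ---------------------------------------------------------------------------
# panel CSV

_PANEL_COLUMNS = ["respondent_id", "age_group", "attribute", "mir",
                  "censored", "straight_liner"]


def write_panel(path: str | Path, panel: Sequence[RespondentRecord]) -> None:
    """Write a panel in long form, one row per completed attribute."""
    rows = []
    for rec in panel:
        for attr, value in rec.mir.items():
            rows.append({
                "respondent_id": rec.respondent_id,
                "age_group": rec.age_group,
                "attribute": attr,
                "mir": value,
                "censored": rec.censored.get(attr, ""),
                "straight_liner": int(rec.straight_liner),
            })
    pd.DataFrame(rows, columns=_PANEL_COLUMNS).to_csv(path, index=False)


def read_panel(path: str | Path,
               attributes: Sequence[Attribute] | None = None,
               ) -> list[RespondentRecord]:
    """Read a panel CSV (long or wide form), validating each row strictly."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"respondent_id": str})
    if "attribute" in frame.columns and "mir" in frame.columns:
        return _panel_from_long(frame, path, attributes)
    mir_cols = [c for c in frame.columns if c.startswith("mir_")]
    if mir_cols:
        return _panel_from_wide(frame, path, attributes)
    raise ValidationError(
        f"{path}: neither long-form (attribute,mir) nor wide-form (mir_*) "
        "panel columns found")


def _check_attribute(name: str, attributes, path, row) -> None:
    if attributes is not None and name not in {a.name for a in attributes}:
        raise ValidationError(
            f"{path}: row {row}: unknown attribute {name!r}")


def _panel_from_long(frame: pd.DataFrame, path: Path,
                     attributes) -> list[RespondentRecord]:
    missing = set(["respondent_id", "age_group", "attribute", "mir"]) \
        - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records: dict[str, dict] = {}
    for i, row in frame.iterrows():
        rid = str(row["respondent_id"])
        attr = str(row["attribute"])
        _check_attribute(attr, attributes, path, i)
        mir = float(row["mir"])
        if not mir > 0:
            raise ValidationError(
                f"{path}: row {i}: nonpositive MIR {mir} for respondent "
                f"{rid!r}, attribute {attr!r}")
        rec = records.setdefault(rid, {
            "age_group": str(row["age_group"]),
            "mir": {}, "censored": {},
            "straight_liner": bool(int(row.get("straight_liner", 0) or 0)),
        })
        rec["mir"][attr] = mir
        cens = row.get("censored", "")
        if isinstance(cens, str) and cens:
            rec["censored"][attr] = cens
    return [RespondentRecord(respondent_id=rid, **fields)
            for rid, fields in records.items()]


def _panel_from_wide(frame: pd.DataFrame, path: Path,
                     attributes) -> list[RespondentRecord]:
    if "respondent_id" not in frame or "age_group" not in frame:
        raise ValidationError(
            f"{path}: wide panel needs respondent_id and age_group columns")
    mir_cols = [c for c in frame.columns if c.startswith("mir_")]
    out = []
    for i, row in frame.iterrows():
        mir = {}
        for col in mir_cols:
            attr = col[len("mir_"):]
            _check_attribute(attr, attributes, path, i)
            value = row[col]
            if pd.isna(value):
                continue
            if not float(value) > 0:
                raise ValidationError(
                    f"{path}: row {i}: nonpositive MIR {value} in {col}")
            mir[attr] = float(value)
        out.append(RespondentRecord(
            respondent_id=str(row["respondent_id"]),
            age_group=str(row["age_group"]), mir=mir,
            straight_liner=bool(int(row.get("straight_liner", 0) or 0))))
    return out


# ---------------------------------------------------------------------------
# choice logs

def write_choice_logs(path: str | Path, logs: pd.DataFrame) -> None:
    logs.to_csv(path, index=False)


def read_choice_logs(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path, dtype={"respondent_id": str})
    required = {"respondent_id", "attribute", "iteration", "offered_change",
                "chose_procedure"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return frame


def panel_from_choice_logs(
    logs: pd.DataFrame,
    ladders: Mapping[str, Ladder],
    *,
    age_groups: Mapping[str, str] | None = None,
) -> list[RespondentRecord]:
    """Rebuild a respondent panel from raw choice logs.

    Each respondent × attribute block of three iterations is mapped to an
    interval-censored indifference estimate; straight-lining is classified
    from the full set of a respondent's exercises. Ages come from an
    ``age_group`` column if present, else from the ``age_groups`` mapping.
    """
    records = []
    for rid, block in logs.groupby("respondent_id", sort=True):
        mir: dict[str, float] = {}
        censored: dict[str, str] = {}
        patterns = []
        if age_groups is not None and rid in age_groups:
            age = age_groups[rid]
        elif "age_group" in block.columns:
            age = str(block["age_group"].iloc[0])
        else:
            raise ValidationError(
                f"no age_group for respondent {rid!r}: add an age_group "
                "column to the log or pass age_groups=")
        for attr, rows in block.groupby("attribute"):
            rows = rows.sort_values("iteration")
            ladder = ladders.get(attr)
            if ladder is None:
                raise ValidationError(f"no ladder for attribute {attr!r}")
            responses = [
                ChoiceResponse(iteration=int(r["iteration"]),
                               chose_procedure_improvement=bool(
                                   int(r["chose_procedure"])))
                for _, r in rows.iterrows()
            ]
            estimate = estimate_indifference(ladder, responses)
            mir[attr] = estimate.point
            if estimate.censored != "none":
                censored[attr] = estimate.censored
            patterns.append(is_straight_pattern(responses))
        records.append(RespondentRecord(
            respondent_id=str(rid), age_group=age, mir=mir,
            censored=censored, straight_liner=all(patterns)))
    return records


# ---------------------------------------------------------------------------
# results

def config_digest(attributes: Sequence[Attribute],
                  profiles: Mapping[str, AlternativeProfile]) -> str:
    """Stable short digest identifying a model configuration."""
    payload = json.dumps({
        "attributes": [(a.name, a.direction.value, a.worst, a.best, a.units)
                       for a in attributes],
        "profiles": {name: {attr: (est.mean, est.ci_low, est.ci_high)
                            for attr, est in sorted(p.performance.items())}
                     for name, p in sorted(profiles.items())},
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_results(out_dir: str | Path,
                  objects: Mapping[str, Any]) -> dict[str, str]:
    """Write each named object as JSON under ``out_dir``; return a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, obj in objects.items():
        target = out_dir / f"{name}.json"
        target.write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")
        manifest[name] = str(target)
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2) + "\n")
    return manifest


def _jsonify(obj: Any) -> Any:
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
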