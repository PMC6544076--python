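"""Swing weights from elicited indifference amounts.

A respondent's maximum acceptable increase in risk (MIR) — or maximum
acceptable reduction in benefit (MRB) — on an attribute is the change on
that attribute they value the same as reducing procedure invasiveness.
With the invasiveness swing anchored at weight 1, an attribute whose full
modelled range is ``span`` units receives weight ``span / MIR``: tolerating
only a small change means the full swing is worth many invasiveness swings.

Group-level weights divide the range by the group's *mean* MIR (not the
mean of individual weights); individual weight vectors, used for Monte
Carlo resampling, divide by the respondent's own MIR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import Attribute, ModelError

AGE_GROUPS = ("under60", "ge60")


class WeightError(ModelError):
    """Invalid MIR or weight configuration."""


@dataclass(frozen=True)
class RespondentRecord:
    """One participant's elicited indifference amounts.

    ``mir`` maps attribute name → elicited MIR/MRB in attribute units
    (proportions on 0–1, years as years); attributes the respondent was not
    asked about, or did not complete, are simply absent. ``censored`` marks
    attributes where the elicitation ladder only bounded the value
    (``"at_max"`` / ``"at_min"``).
    """

    respondent_id: str
    age_group: str
    mir: Mapping[str, float]
    censored: Mapping[str, str] = field(default_factory=dict)
    straight_liner: bool = False
    treated_previously: bool | None = None

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise WeightError(
                f"respondent {self.respondent_id!r}: age_group must be one of "
                f"{AGE_GROUPS}, got {self.age_group!r}")
        for name, value in self.mir.items():
            if not (value > 0 and math.isfinite(value)):
                raise WeightError(
                    f"respondent {self.respondent_id!r}: MIR for {name!r} "
                    f"must be positive and finite, got {value}")
        if not self.mir:
            raise WeightError(
                f"respondent {self.respondent_id!r} has no completed attribute")


@dataclass(frozen=True)
class WeightVector:
    """Raw (anchor = 1) and sum-100 normalized attribute weights."""

    raw: Mapping[str, float]
    normalized: Mapping[str, float]
    provenance: str = "individual"

    def __post_init__(self) -> None:
        total = sum(self.normalized.values())
        if abs(total - 100.0) > 1e-9:
            raise WeightError(f"normalized weights sum to {total}, not 100")
        for name, w in self.raw.items():
            if not w > 0:
                raise WeightError(f"weight for {name!r} must be > 0, got {w}")


def weight_from_mir(mir: float, attribute: Attribute) -> float:
    """Raw swing weight of ``attribute`` implied by an indifference amount.

    The procedure anchor bypasses the division and is 1 by definition.
    """
    if attribute.is_anchor:
        return 1.0
    if not (mir > 0 and math.isfinite(mir)):
        raise WeightError(
            f"MIR for {attribute.name!r} must be positive, got {mir}")
    return attribute.span / mir


def normalize(raw: Mapping[str, float], provenance: str = "individual") -> WeightVector:
    """Wrap raw weights with their sum-100 normalization."""
    for name, w in raw.items():
        if not (w > 0 and math.isfinite(w)):
            raise WeightError(f"raw weight for {name!r} must be positive "
                              f"and finite, got {w}")
    total = sum(raw.values())
    normalized = {name: 100.0 * w / total for name, w in raw.items()}
    return WeightVector(raw=dict(raw), normalized=normalized,
                        provenance=provenance)


def individual_weights(
    record: RespondentRecord,
    attributes: Sequence[Attribute],
    *,
    fill: Mapping[str, float] | None = None,
) -> WeightVector:
    """One respondent's weight vector; missing attributes filled from ``fill``.

    ``fill`` maps attribute name → raw weight (typically the group-mean
    weights); without it, a missing attribute raises.
    """
    raw: dict[str, float] = {}
    for attr in attributes:
        if attr.is_anchor:
            raw[attr.name] = 1.0
        elif attr.name in record.mir:
            raw[attr.name] = weight_from_mir(record.mir[attr.name], attr)
        elif fill is not None and attr.name in fill:
            raw[attr.name] = fill[attr.name]
        else:
            raise WeightError(
                f"respondent {record.respondent_id!r}: no MIR and no fill "
                f"weight for attribute {attr.name!r}")
    return normalize(raw, provenance="individual")


def filter_panel(
    panel: Iterable[RespondentRecord],
    group: str = "all",
    *,
    exclude_straight_liners: bool = False,
) -> list[RespondentRecord]:
    """Subset a panel by age group and optionally drop straight-liners."""
    if group not in ("all", *AGE_GROUPS):
        raise WeightError(f"unknown group {group!r}")
    out = [r for r in panel
           if (group == "all" or r.age_group == group)
           and not (exclude_straight_liners and r.straight_liner)]
    return out


def mean_mirs(
    panel: Sequence[RespondentRecord],
    attributes: Sequence[Attribute],
) -> dict[str, float]:
    """Per-attribute arithmetic mean MIR over respondents who completed it."""
    means: dict[str, float] = {}
    for attr in attributes:
        if attr.is_anchor:
            continue
        values = [r.mir[attr.name] for r in panel if attr.name in r.mir]
        if not values:
            raise WeightError(
                f"no observed MIR for attribute {attr.name!r} in this group")
        means[attr.name] = float(np.mean(values))
    return means


def group_weights(
    panel: Sequence[RespondentRecord],
    attributes: Sequence[Attribute],
    group: str = "all",
    *,
    exclude_straight_liners: bool = False,
) -> WeightVector:
    """Group-level weights: range divided by the group-mean MIR.

    Per-attribute n may differ (respondents completed different subsets of
    the elicitation exercises); each mean uses whoever completed that
    attribute.
    """
    subset = filter_panel(panel, group,
                          exclude_straight_liners=exclude_straight_liners)
    if not subset:
        raise WeightError(f"group {group!r} is empty")
    return weights_from_mean_mirs(mean_mirs(subset, attributes), attributes)


def weights_from_mean_mirs(
    means: Mapping[str, float],
    attributes: Sequence[Attribute],
) -> WeightVector:
    """Weights implied by group-mean indifference amounts (anchor = 1)."""
    raw: dict[str, float] = {}
    for attr in attributes:
        if attr.is_anchor:
            raw[attr.name] = 1.0
        else:
            if attr.name not in means:
                raise WeightError(f"no mean MIR for attribute {attr.name!r}")
            raw[attr.name] = weight_from_mir(means[attr.name], attr)
    return normalize(raw, provenance="group-mean")


def panel_summary(
    panel: Sequence[RespondentRecord],
    attributes: Sequence[Attribute],
    impacts: Mapping[str, float],
) -> pd.DataFrame:
    """Per attribute × group summary of elicited indifference amounts.

    Returns a tidy frame with columns ``attribute, group, mean_mir, sd_mir,
    n, prop_mir_exceeds_impact``. The SD uses the n−1 denominator. The
    proportion is the share of observed MIRs strictly greater than the
    absolute TAVR-vs-SAVR change on the attribute; on attributes where the
    less invasive option is also the better performer the change itself is
    acceptable to everyone, so the proportion is 100% by construction.
    """
    from .model import Direction

    attr_by_name = {a.name: a for a in attributes}
    rows = []
    for attr in attributes:
        if attr.is_anchor:
            continue
        impact = impacts.get(attr.name)
        for group in ("all", *AGE_GROUPS):
            subset = filter_panel(panel, group)
            values = np.array([r.mir[attr.name] for r in subset
                               if attr.name in r.mir], dtype=float)
            n = len(values)
            mean = float(values.mean()) if n else np.nan
            sd = float(values.std(ddof=1)) if n > 1 else np.nan
            prop = np.nan
            if impact is not None and n:
                attr_def = attr_by_name[attr.name]
                favors_tavr = (impact < 0 if attr_def.direction is Direction.RISK
                               else impact > 0)
                if favors_tavr:
                    prop = 1.0
                else:
                    prop = float(np.mean(values > abs(impact)))
            rows.append({"attribute": attr.name, "group": group,
                         "mean_mir": mean, "sd_mir": sd, "n": n,
                         "prop_mir_exceeds_impact": prop})
    return pd.DataFrame(rows)
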