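"""Additive multi-criteria value model for treatment benefit-risk analysis.

The model scores each treatment alternative as a weighted sum of linear
partial values, one per clinical attribute:

    U(x) = sum_i w_i * v_i(x_i)

where ``v_i`` maps the attribute's performance level onto [0, 1] (0 at the
worst end of the modelled range, 1 at the best) and ``w_i`` is the swing
weight of the attribute, anchored so that the binary type-of-procedure
attribute (invasive vs minimally invasive) has weight 1.

The module also implements the threshold analysis: for each attribute, the
performance level at which the two alternatives would have equal overall
value — the maximum acceptable risk (MAR) for risk attributes, or the
minimum acceptable benefit (MAB) for benefit attributes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .weights import WeightVector


class Direction(str, enum.Enum):
    """Orientation of an attribute: whether larger levels are better."""

    BENEFIT = "benefit"  # higher is better
    RISK = "risk"        # lower is better


#: Units marker for the binary invasiveness attribute that anchors the
#: swing-weight scale at 1.
PROCEDURE_UNITS = "binary-procedure"

_PROPORTION_UNITS = frozenset({"proportion", PROCEDURE_UNITS})


class ModelError(ValueError):
    """Base class for model configuration and domain errors."""


class RangeError(ModelError):
    """A performance level fell outside an attribute's modelled range."""


@dataclass(frozen=True)
class Attribute:
    """One criterion of the value model.

    Parameters
    ----------
    name:
        Identifier used throughout configs, panels and results.
    direction:
        ``benefit`` (higher levels better) or ``risk`` (lower better).
    worst, best:
        The endpoints of the modelled performance range, in attribute
        units. For risk attributes ``worst > best`` numerically.
    units:
        ``proportion`` (levels in [0, 1]), ``years``, or
        ``binary-procedure`` for the invasiveness anchor.
    """

    name: str
    direction: Direction
    worst: float
    best: float
    units: str = "proportion"

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction(self.direction))
        if self.worst == self.best:
            raise ModelError(f"attribute {self.name!r}: degenerate range "
                             f"[{self.worst}, {self.best}]")
        if self.direction is Direction.RISK and not self.worst > self.best:
            raise ModelError(
                f"attribute {self.name!r}: risk attributes need worst > best "
                f"numerically, got worst={self.worst}, best={self.best}")
        if self.direction is Direction.BENEFIT and not self.best > self.worst:
            raise ModelError(
                f"attribute {self.name!r}: benefit attributes need best > worst "
                f"numerically, got worst={self.worst}, best={self.best}")
        if self.units in _PROPORTION_UNITS:
            for bound in (self.worst, self.best):
                if not 0.0 <= bound <= 1.0:
                    raise ModelError(
                        f"attribute {self.name!r}: proportion bound {bound} "
                        "outside [0, 1]")

    @property
    def span(self) -> float:
        """Absolute width of the modelled range, in attribute units."""
        return abs(self.best - self.worst)

    @property
    def is_anchor(self) -> bool:
        """True for the binary procedure attribute (swing weight fixed at 1)."""
        return self.units == PROCEDURE_UNITS

    @property
    def lower(self) -> float:
        return min(self.worst, self.best)

    @property
    def upper(self) -> float:
        return max(self.worst, self.best)

    def feasible_bounds(self) -> tuple[float, float]:
        """Bounds a threshold level may physically take (clamping bounds)."""
        if self.units in _PROPORTION_UNITS:
            return (0.0, 1.0)
        # durations and other nonnegative scales
        return (0.0, math.inf)


@dataclass(frozen=True)
class PerformanceEstimate:
    """Mean and optional 95% CI of one alternative's level on one attribute."""

    mean: float
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if (self.ci_low is None) != (self.ci_high is None):
            raise ModelError("provide both CI bounds or neither")
        if self.ci_low is not None:
            if not self.ci_low <= self.mean <= self.ci_high:
                raise ModelError(
                    f"CI [{self.ci_low}, {self.ci_high}] does not bracket "
                    f"mean {self.mean}")

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None


@dataclass(frozen=True)
class AlternativeProfile:
    """One alternative's performance across all model attributes."""

    name: str
    performance: Mapping[str, PerformanceEstimate]

    def level(self, attribute: str) -> float:
        try:
            return self.performance[attribute].mean
        except KeyError:
            raise ModelError(
                f"profile {self.name!r} has no performance for attribute "
                f"{attribute!r}") from None

    def validate_against(self, attributes: Sequence[Attribute]) -> None:
        """Check every model attribute is present with an in-range proportion."""
        for attr in attributes:
            est = self.performance.get(attr.name)
            if est is None:
                raise ModelError(
                    f"profile {self.name!r} missing attribute {attr.name!r}")
            if attr.units in _PROPORTION_UNITS and not 0.0 <= est.mean <= 1.0:
                raise ModelError(
                    f"profile {self.name!r}, attribute {attr.name!r}: "
                    f"proportion mean {est.mean} outside [0, 1]")

    def replace_level(self, attribute: str, level: float) -> "AlternativeProfile":
        """Copy of the profile with one attribute's mean set to ``level``."""
        perf = dict(self.performance)
        perf[attribute] = PerformanceEstimate(mean=level)
        return AlternativeProfile(name=self.name, performance=perf)


@dataclass(frozen=True)
class ValueDecomposition:
    """Incremental overall value and its exact per-attribute split."""

    overall_increment: float
    per_attribute: Mapping[str, float]


class ThresholdKind(str, enum.Enum):
    MAR = "MAR"  # maximum acceptable risk
    MAB = "MAB"  # minimum acceptable benefit


@dataclass(frozen=True)
class ThresholdResult:
    """Indifference level on one attribute, with clamping bookkeeping.

    ``raw_level`` is the unclamped solution of the indifference equation;
    ``threshold_level`` is the reported value after clamping to the
    attribute's feasible bounds.
    """

    attribute: str
    threshold_level: float
    kind: ThresholdKind
    raw_level: float
    clamped: bool = False
    clamp_bound: float | None = None


def partial_value(level: float, attribute: Attribute, *, strict: bool = False) -> float:
    """Linear partial value of ``level`` on ``attribute``.

    Maps the worst end of the modelled range to 0 and the best end to 1,
    linearly in between. With ``strict=True``, levels outside the range
    raise :class:`RangeError`; otherwise the line is extrapolated (used by
    the threshold self-consistency identity, where the indifference level
    may exceed the modelled range before clamping).
    """
    if strict and not attribute.lower <= level <= attribute.upper:
        raise RangeError(
            f"level {level} outside range [{attribute.lower}, "
            f"{attribute.upper}] of attribute {attribute.name!r}")
    return (level - attribute.worst) / (attribute.best - attribute.worst)


def _raw_weights(weights: "WeightVector | Mapping[str, float]") -> Mapping[str, float]:
    raw = getattr(weights, "raw", None)
    return raw if raw is not None else weights


def overall_value(
    profile: AlternativeProfile,
    weights: "WeightVector | Mapping[str, float]",
    attributes: Sequence[Attribute],
) -> float:
    """Overall value U = sum_i w_i v_i(x_i) on the raw (anchor = 1) scale."""
    raw = _raw_weights(weights)
    total = 0.0
    for attr in attributes:
        if attr.name not in raw:
            raise ModelError(f"no weight for attribute {attr.name!r}")
        total += raw[attr.name] * partial_value(profile.level(attr.name), attr)
    return total


def incremental_value(
    profile_a: AlternativeProfile,
    profile_b: AlternativeProfile,
    weights: "WeightVector | Mapping[str, float]",
    attributes: Sequence[Attribute],
) -> ValueDecomposition:
    """U(a) − U(b) decomposed exactly into per-attribute contributions."""
    raw = _raw_weights(weights)
    per_attr: dict[str, float] = {}
    for attr in attributes:
        if attr.name not in raw:
            raise ModelError(f"no weight for attribute {attr.name!r}")
        va = partial_value(profile_a.level(attr.name), attr)
        vb = partial_value(profile_b.level(attr.name), attr)
        per_attr[attr.name] = raw[attr.name] * (va - vb)
    return ValueDecomposition(
        overall_increment=sum(per_attr.values()), per_attribute=per_attr)


def threshold(
    attribute: Attribute,
    profile_tavr: AlternativeProfile,
    profile_savr: AlternativeProfile,
    weights: "WeightVector | Mapping[str, float]",
    attributes: Sequence[Attribute],
    *,
    clamp_policy: str = "feasible",
) -> ThresholdResult:
    """Performance level on ``attribute`` that equalises the two alternatives.

    Starting from the first profile's level, its performance on the chosen
    attribute is displaced until the overall-value advantage is exactly
    consumed. A unit change in level is worth ``w_i / span_i`` raw value
    units, so the displacement is ``ΔU · span_i / w_i`` — risk attributes
    may worsen (level rises), benefit attributes may fall, before the
    patient is indifferent. The result is invariant to rescaling of the
    weight vector because ΔU and w_i scale together.

    ``clamp_policy``: ``"feasible"`` clamps to the attribute's physical
    bounds ([0, 1] for proportions, ≥0 for years) and flags the clamp;
    ``"none"`` reports the raw solution.
    """
    raw = _raw_weights(weights)
    w = raw.get(attribute.name)
    if w is None:
        raise ModelError(f"no weight for attribute {attribute.name!r}")
    if w == 0:
        raise ModelError(
            f"threshold undefined: attribute {attribute.name!r} has zero weight")

    delta_u = (overall_value(profile_tavr, raw, attributes)
               - overall_value(profile_savr, raw, attributes))
    displacement = delta_u * attribute.span / w
    base = profile_tavr.level(attribute.name)
    if attribute.direction is Direction.RISK:
        kind = ThresholdKind.MAR
        level = base + displacement   # risk may rise before indifference
    else:
        kind = ThresholdKind.MAB
        level = base - displacement   # benefit may fall before indifference

    clamped = False
    clamp_bound: float | None = None
    reported = level
    if clamp_policy == "feasible":
        lo, hi = attribute.feasible_bounds()
        if level < lo:
            reported, clamped, clamp_bound = lo, True, lo
        elif level > hi:
            reported, clamped, clamp_bound = hi, True, hi
    elif clamp_policy != "none":
        raise ModelError(f"unknown clamp_policy {clamp_policy!r}")

    return ThresholdResult(
        attribute=attribute.name, threshold_level=reported, kind=kind,
        raw_level=level, clamped=clamped, clamp_bound=clamp_bound)


def threshold_table(
    profile_tavr: AlternativeProfile,
    profile_savr: AlternativeProfile,
    weights: "WeightVector | Mapping[str, float]",
    attributes: Sequence[Attribute],
    *,
    clamp_policy: str = "feasible",
) -> dict[str, ThresholdResult]:
    """Thresholds for every non-anchor attribute (the anchor is binary)."""
    return {
        attr.name: threshold(attr, profile_tavr, profile_savr, weights,
                             attributes, clamp_policy=clamp_policy)
        for attr in attributes if not attr.is_anchor
    }
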