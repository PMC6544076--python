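"""Transforms from published clinical inputs to model attribute performance.

Covers the two measurement transformations the aortic-stenosis model
needs — the KCCQ health-status score to a symptom-relief proportion, and
all-stroke risk to non-fatal disabling stroke risk — plus CI handling and
the TAVR-vs-SAVR impact table.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from scipy.stats import norm

from .model import AlternativeProfile, Attribute, ModelError, PerformanceEstimate

# two-sided 95% normal quantile
_Z95 = norm.ppf(0.975)


def ci_to_se(estimate: PerformanceEstimate) -> float:
    """Standard error implied by a symmetric-normal 95% CI."""
    if not estimate.has_ci:
        raise ModelError("estimate has no CI")
    if estimate.ci_high < estimate.ci_low:
        raise ModelError(
            f"CI upper bound {estimate.ci_high} below lower {estimate.ci_low}")
    return (estimate.ci_high - estimate.ci_low) / (2.0 * _Z95)


def kccq_threshold_proportion(
    mean_score: float,
    sd_score: float,
    cutoff: float = 75.0,
) -> float:
    """Proportion of patients reaching a KCCQ total score of ``cutoff``.

    Treats the 0–100 KCCQ score as normal with the given mean and SD and
    returns the upper tail mass at the cutoff, clamped to [0, 1]. The
    independence attribute is defined as reaching 75 at one month.
    """
    if not sd_score > 0:
        raise ModelError(f"sd_score must be > 0, got {sd_score}")
    p = 1.0 - norm.cdf((cutoff - mean_score) / sd_score)
    return float(min(1.0, max(0.0, p)))


def nonfatal_stroke_adjust(
    all_stroke_risk: float,
    stroke_case_fatality: float,
) -> float:
    """Non-fatal disabling stroke risk from all-stroke risk.

    Multiplies by stroke-event survival: fatal strokes are already counted
    under mortality, so they are removed here to keep the attribute set
    non-overlapping. The case-fatality fraction is a configuration
    parameter (trial-derived, not part of this model).
    """
    for name, value in (("all_stroke_risk", all_stroke_risk),
                        ("stroke_case_fatality", stroke_case_fatality)):
        if not 0.0 <= value <= 1.0:
            raise ModelError(f"{name} must be in [0, 1], got {value}")
    return all_stroke_risk * (1.0 - stroke_case_fatality)


def impact_table(
    profile_tavr: AlternativeProfile,
    profile_savr: AlternativeProfile,
    attributes: Sequence[Attribute],
) -> dict[str, float]:
    """Signed mean performance difference (TAVR − SAVR) per attribute."""
    keys_t = set(profile_tavr.performance)
    keys_s = set(profile_savr.performance)
    if keys_t != keys_s:
        raise ModelError(
            f"profiles cover different attributes: {sorted(keys_t ^ keys_s)}")
    out: dict[str, float] = {}
    for attr in attributes:
        out[attr.name] = (profile_tavr.level(attr.name)
                          - profile_savr.level(attr.name))
    return out
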