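"""Monte Carlo propagation of performance and preference uncertainty.

Each iteration draws a performance level for every alternative × attribute
from the normal implied by its 95% CI (truncated to feasible bounds), and
a weight vector from the respondent panel, then ranks the alternatives by
overall value. The output is the probability that each alternative ranks
first, with its binomial Monte-Carlo standard error.

Two preference-resampling schemes are available: ``respondent-bootstrap``
(default) draws a whole respondent and uses their weight vector, keeping
within-person correlation across attributes; ``attribute-independent``
resamples each attribute's MIR independently from the panel's empirical
marginal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import (AlternativeProfile, Attribute, ModelError,
                    PerformanceEstimate, overall_value)
from .performance import ci_to_se
from .weights import (RespondentRecord, WeightVector, filter_panel,
                      group_weights, individual_weights, weight_from_mir)

SCHEMES = ("respondent-bootstrap", "attribute-independent")


@dataclass(frozen=True)
class MCSResult:
    """Outcome of one Monte Carlo simulation run."""

    n_iterations: int
    p_first: Mapping[str, float]
    mc_se: float
    seed: int | None
    scheme: str = "respondent-bootstrap"
    subgroup: str = "all"
    exclusions: str = "none"

    def __post_init__(self) -> None:
        total = sum(self.p_first.values())
        if abs(total - 1.0) > 1e-9:
            raise ModelError(f"p_first sums to {total}, not 1")

    def to_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "p_first": dict(self.p_first),
            "mc_se": self.mc_se,
            "seed": self.seed,
            "scheme": self.scheme,
            "subgroup": self.subgroup,
            "exclusions": self.exclusions,
        }


def sample_performance(
    estimate: PerformanceEstimate,
    attribute: Attribute,
    rng: np.random.Generator,
) -> float:
    """One draw of an attribute level: Normal(mean, se) within feasible bounds.

    Estimates without a CI (the proven-to-work duration and the binary
    procedure attribute) are point masses at the mean. Truncation is by
    rejection, which is exact; the CIs here sit well inside the bounds so
    rejections are rare.
    """
    if not estimate.has_ci:
        return estimate.mean
    se = ci_to_se(estimate)
    if se == 0.0:
        return estimate.mean
    lo, hi = attribute.feasible_bounds()
    while True:
        draw = rng.normal(estimate.mean, se)
        if lo <= draw <= hi:
            return float(draw)


def _panel_weight_vectors(
    panel: Sequence[RespondentRecord],
    attributes: Sequence[Attribute],
) -> list[WeightVector]:
    """Individual weight vectors, missing attributes filled from group means."""
    fill = group_weights(panel, attributes).raw
    return [individual_weights(r, attributes, fill=fill) for r in panel]


def sample_weights(
    panel: Sequence[RespondentRecord],
    attributes: Sequence[Attribute],
    rng: np.random.Generator,
    scheme: str = "respondent-bootstrap",
) -> WeightVector:
    """One draw of a weight vector under the chosen resampling scheme."""
    if scheme not in SCHEMES:
        raise ModelError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if not panel:
        raise ModelError("panel is empty")
    if scheme == "respondent-bootstrap":
        vectors = _panel_weight_vectors(panel, attributes)
        return vectors[rng.integers(len(vectors))]
    return _sample_weights_independent(panel, attributes, rng)


def _sample_weights_independent(
    panel: Sequence[RespondentRecord],
    attributes: Sequence[Attribute],
    rng: np.random.Generator,
) -> WeightVector:
    from .weights import normalize

    raw: dict[str, float] = {}
    for attr in attributes:
        if attr.is_anchor:
            raw[attr.name] = 1.0
            continue
        values = [r.mir[attr.name] for r in panel if attr.name in r.mir]
        if not values:
            raise ModelError(f"no observed MIR for attribute {attr.name!r}")
        raw[attr.name] = weight_from_mir(values[rng.integers(len(values))], attr)
    return normalize(raw, provenance="individual")


def run_mcs(
    profiles: Sequence[AlternativeProfile],
    panel: Sequence[RespondentRecord],
    attributes: Sequence[Attribute],
    n_iterations: int = 10_000,
    seed: int | None = None,
    *,
    scheme: str = "respondent-bootstrap",
    subgroup: str = "all",
    exclude_straight_liners: bool = False,
) -> MCSResult:
    """Probability each alternative ranks first under input uncertainty.

    Exact ties in overall value split first place equally (measure-zero
    under continuous sampling; relevant only in degenerate configurations).
    Reproducible: a fixed seed gives a bit-identical result.
    """
    if scheme not in SCHEMES:
        raise ModelError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if n_iterations < 1:
        raise ModelError("n_iterations must be >= 1")
    subset = filter_panel(panel, subgroup,
                          exclude_straight_liners=exclude_straight_liners)
    if not subset:
        raise ModelError(f"subgroup {subgroup!r} is empty after exclusions")

    rng = np.random.default_rng(seed)
    # Pre-computed per-respondent vectors make the bootstrap O(1) per draw.
    vectors = (_panel_weight_vectors(subset, attributes)
               if scheme == "respondent-bootstrap" else None)

    wins = {p.name: 0.0 for p in profiles}
    for _ in range(n_iterations):
        if vectors is not None:
            weights = vectors[rng.integers(len(vectors))]
        else:
            weights = _sample_weights_independent(subset, attributes, rng)
        sampled = []
        for profile in profiles:
            perf = {
                attr.name: PerformanceEstimate(mean=sample_performance(
                    profile.performance[attr.name], attr, rng))
                for attr in attributes
            }
            sampled.append(AlternativeProfile(name=profile.name,
                                              performance=perf))
        values = {p.name: overall_value(p, weights, attributes)
                  for p in sampled}
        top = max(values.values())
        winners = [name for name, u in values.items()
                   if u == top]
        for name in winners:
            wins[name] += 1.0 / len(winners)

    p_first = {name: count / n_iterations for name, count in wins.items()}
    p_ref = p_first[profiles[0].name]
    mc_se = math.sqrt(p_ref * (1.0 - p_ref) / n_iterations)
    return MCSResult(
        n_iterations=n_iterations, p_first=p_first, mc_se=mc_se, seed=seed,
        scheme=scheme, subgroup=subgroup,
        exclusions="straight-liners" if exclude_straight_liners else "none")
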