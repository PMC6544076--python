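"""Adaptive swing-weighting (ASW) choice ladder.

Each exercise pits an improvement in procedure invasiveness against an
improvement of a stated size on one clinical attribute, over three
iterations. The offered size follows a dyadic bisection of the interval
``(0, max_change]``: the first offer is half the maximum; a respondent who
picks the procedure improvement values the offered change less, so the
next offer grows by half the current step, otherwise it shrinks — the step
halving each iteration. Three answers pin the respondent's indifference
point to one of eight adjacent intervals of width ``max_change / 8``.

An explicit offer grid can replace the dyadic ladder (e.g. to reproduce a
published instrument with display-rounded levels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

N_ITERATIONS = 3


class ProtocolError(ValueError):
    """The response history violates the three-iteration protocol."""


@dataclass(frozen=True)
class ChoiceResponse:
    """One answer: did the respondent pick the procedure improvement?"""

    iteration: int
    chose_procedure_improvement: bool

    def __post_init__(self) -> None:
        if not 1 <= self.iteration <= N_ITERATIONS:
            raise ProtocolError(f"iteration must be 1..{N_ITERATIONS}, "
                                f"got {self.iteration}")


@dataclass(frozen=True)
class Ladder:
    """Offer schedule for one attribute's ASW exercise.

    ``max_change`` is the largest improvement the instrument can offer, in
    attribute units. ``grid``, if given, maps a tuple of previous
    procedure-choices (e.g. ``(True, False)``) to the next offered change,
    overriding the dyadic rule; it must cover all 7 histories of length
    0–2.
    """

    attribute: str
    max_change: float
    base_level: float | None = None
    grid: Mapping[tuple[bool, ...], float] | None = None

    def __post_init__(self) -> None:
        if not self.max_change > 0:
            raise ProtocolError(
                f"ladder for {self.attribute!r}: max_change must be > 0")
        if self.grid is not None:
            for hist, offer in self.grid.items():
                if not 0 < offer <= self.max_change:
                    raise ProtocolError(
                        f"ladder for {self.attribute!r}: grid offer {offer} "
                        f"for history {hist} outside (0, {self.max_change}]")


@dataclass(frozen=True)
class IndifferenceEstimate:
    """Interval-censored indifference point recovered from one exercise."""

    attribute: str
    point: float
    interval: tuple[float, float]
    censored: str = "none"   # none | at_max | at_min

    def __post_init__(self) -> None:
        low, high = self.interval
        if not low <= self.point <= high:
            raise ProtocolError(
                f"point {self.point} outside interval [{low}, {high}]")


def _history_key(history: Sequence[ChoiceResponse]) -> tuple[bool, ...]:
    return tuple(r.chose_procedure_improvement for r in history)


def next_offer(ladder: Ladder, history: Sequence[ChoiceResponse]) -> float:
    """Offered attribute change for the next iteration given the history."""
    if len(history) >= N_ITERATIONS:
        raise ProtocolError(
            f"exercise already complete ({len(history)} responses)")
    if ladder.grid is not None:
        key = _history_key(history)
        if key not in ladder.grid:
            raise ProtocolError(
                f"ladder for {ladder.attribute!r}: grid missing history {key}")
        return ladder.grid[key]
    offer = ladder.max_change / 2.0
    step = ladder.max_change / 4.0
    for response in history:
        if response.chose_procedure_improvement:
            offer += step   # offered change undervalued: offer more
        else:
            offer -= step
        step /= 2.0
    return offer


def estimate_indifference(
    ladder: Ladder,
    responses: Sequence[ChoiceResponse],
) -> IndifferenceEstimate:
    """Map a completed exercise's response pattern to an interval estimate.

    The 8 patterns partition ``(0, max_change]`` into 8 adjacent intervals
    of width ``max_change / 8``; the point estimate is the interval
    midpoint. Boundary patterns are censored: always choosing the
    procedure improvement only bounds the indifference point from below
    (``at_max``, point reported at the ladder maximum); always choosing
    the attribute improvement only bounds it from above (``at_min``).
    """
    if len(responses) != N_ITERATIONS:
        raise ProtocolError(
            f"need exactly {N_ITERATIONS} responses, got {len(responses)}")
    low, high = 0.0, ladder.max_change
    for i, response in enumerate(responses):
        offer = next_offer(ladder, responses[:i])
        if response.chose_procedure_improvement:
            low = offer     # indifference point is above the offer
        else:
            high = offer    # at or below the offer
    pattern = _history_key(responses)
    if all(pattern):
        return IndifferenceEstimate(
            attribute=ladder.attribute, point=ladder.max_change,
            interval=(low, ladder.max_change), censored="at_max")
    if not any(pattern):
        return IndifferenceEstimate(
            attribute=ladder.attribute, point=(low + high) / 2.0,
            interval=(low, high), censored="at_min")
    return IndifferenceEstimate(
        attribute=ladder.attribute, point=(low + high) / 2.0,
        interval=(low, high))


def simulate_response(
    latent_mir: float,
    offer: float,
    *,
    iteration: int = 1,
    error_model: str = "deterministic",
    scale: float | None = None,
    rng: np.random.Generator | None = None,
) -> ChoiceResponse:
    """Simulated answer of a respondent with a known indifference point.

    Deterministic respondents pick the attribute improvement exactly when
    the offer exceeds their latent MIR (the offered change is worth more
    than the invasiveness reduction). The logistic model passes the same
    comparison through a logistic choice probability with the given scale
    (attribute units); as scale → 0 it recovers the deterministic rule.
    """
    if not latent_mir > 0:
        raise ValueError(f"latent_mir must be > 0, got {latent_mir}")
    if error_model == "deterministic":
        chose_attribute = offer > latent_mir
    elif error_model == "logistic":
        if scale is None or not scale > 0:
            raise ValueError(f"logistic error model needs scale > 0, got {scale}")
        if rng is None:
            raise ValueError("logistic error model needs an rng")
        from scipy.special import expit
        p_attribute = float(expit((offer - latent_mir) / scale))
        chose_attribute = bool(rng.random() < p_attribute)
    else:
        raise ValueError(f"unknown error_model {error_model!r}")
    return ChoiceResponse(iteration=iteration,
                          chose_procedure_improvement=not chose_attribute)


def run_exercise(
    latent_mir: float,
    ladder: Ladder,
    *,
    error_model: str = "deterministic",
    scale: float | None = None,
    rng: np.random.Generator | None = None,
) -> list[ChoiceResponse]:
    """Drive a simulated respondent through all three iterations."""
    responses: list[ChoiceResponse] = []
    for i in range(N_ITERATIONS):
        offer = next_offer(ladder, responses)
        responses.append(simulate_response(
            latent_mir, offer, iteration=i + 1, error_model=error_model,
            scale=scale, rng=rng))
    return responses


def is_straight_pattern(responses: Sequence[ChoiceResponse]) -> bool:
    """True if every answer in the exercise fell on the same side."""
    pattern = _history_key(responses)
    return all(pattern) or not any(pattern)


def classify_straight_liner(
    exercises: Iterable[Sequence[ChoiceResponse]],
) -> bool:
    """Straight-liner: every completed exercise is an all-same-side pattern.

    Such respondents never traded between invasiveness and the comparison
    attribute anywhere in the survey; their indifference points are only
    bounded, not located, by the ladder.
    """
    exercises = list(exercises)
    if not exercises:
        raise ProtocolError("respondent has no completed exercise")
    return all(is_straight_pattern(ex) for ex in exercises)
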