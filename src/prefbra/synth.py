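"""Synthetic respondent panels with the study's statistical structure.

The generator emulates the observable features of the elicitation survey:
per-attribute latent indifference points drawn from age-group-specific
truncated normals whose means/SDs default to the published summary, an age
shift (<60 vs ≥60), per-attribute item missingness matching the published
per-attribute n, and a configurable fraction of straight-liners —
respondents whose latent preference lies beyond the choice ladder on every
attribute, so every exercise is answered on one side.

Ladder maxima default to roughly twice the whole-sample mean indifference
amount. That keeps every published group mean interior to the offer range
and makes the (0, max] truncation symmetric about the mean, so the
truncated latent mean equals the configured mean; the truncated SD is
necessarily below the configured SD (see ``latent_moments`` for the
distribution's analytic ground truth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .datasets import load_study_preferences
from .elicitation import Ladder, run_exercise, estimate_indifference, \
    classify_straight_liner, ChoiceResponse
from .weights import AGE_GROUPS, RespondentRecord

#: Largest offerable change per attribute, in model units. Display-friendly
#: values near twice the whole-sample mean indifference amount.
DEFAULT_MAX_CHANGE: dict[str, float] = {
    "mortality": 0.08,
    "stroke": 0.14,
    "independence": 0.28,
    "pacemaker": 0.14,
    "dialysis": 0.12,
    "proven_to_work": 35.0,
}


class SpecError(ValueError):
    """Infeasible panel specification."""


@dataclass(frozen=True)
class LatentCell:
    """Mean/SD of the latent indifference distribution for one attribute × group."""

    mean: float
    sd: float


def _default_latents() -> dict[str, dict[str, LatentCell]]:
    summary = load_study_preferences()["mir_summary"]
    return {
        attr: {group: LatentCell(mean=cells[group]["mean"],
                                 sd=cells[group]["sd"])
               for group in AGE_GROUPS}
        for attr, cells in summary.items()
    }


def _default_missingness() -> dict[str, float]:
    prefs = load_study_preferences()
    n_total = prefs["n_total"]
    return {attr: 1.0 - cells["all"]["n"] / n_total
            for attr, cells in prefs["mir_summary"].items()}


@dataclass(frozen=True)
class PanelSpec:
    """Study conditions for one synthetic respondent panel.

    Defaults reproduce the survey as published: n=219 respondents, 60.3%
    under 60, latent means/SDs per attribute × age group from the study
    summary, per-attribute missingness implied by the published n, and an
    8.68% straight-liner fraction.
    """

    n_respondents: int = 219
    age_mix: float = 0.603                      # fraction under 60
    latents: Mapping[str, Mapping[str, LatentCell]] = field(
        default_factory=_default_latents)
    max_change: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MAX_CHANGE))
    straight_liner_fraction: float = 0.0868
    missingness: Mapping[str, float] = field(
        default_factory=_default_missingness)
    missingness_mode: str = "independent"       # independent | assignment
    family: str = "truncnorm"                   # truncnorm | lognormal
    error_model: str = "deterministic"          # respondent choice errors
    error_scale: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise SpecError("n_respondents must be >= 1")
        for name, frac in (("age_mix", self.age_mix),
                           ("straight_liner_fraction",
                            self.straight_liner_fraction)):
            if not 0.0 <= frac <= 1.0:
                raise SpecError(f"{name} must be in [0, 1], got {frac}")
        if self.family not in ("truncnorm", "lognormal"):
            raise SpecError(f"unknown latent family {self.family!r}")
        if self.missingness_mode not in ("independent", "assignment"):
            raise SpecError(
                f"unknown missingness_mode {self.missingness_mode!r}")
        bad: list[str] = []
        for attr, groups in self.latents.items():
            hi = self.max_change.get(attr)
            if hi is None or not hi > 0:
                raise SpecError(f"no positive max_change for {attr!r}")
            for group, cell in groups.items():
                if cell.sd < 0:
                    bad.append(f"{attr}/{group}: sd {cell.sd} < 0")
                if not 0.0 < cell.mean < hi:
                    bad.append(f"{attr}/{group}: mean {cell.mean} outside "
                               f"(0, {hi})")
        if bad:
            raise SpecError("infeasible latent cells: " + "; ".join(bad))
        for attr, rate in self.missingness.items():
            if not 0.0 <= rate <= 1.0:
                raise SpecError(
                    f"missingness for {attr!r} must be in [0, 1], got {rate}")

    @property
    def attributes(self) -> list[str]:
        return list(self.latents)

    def ladders(self) -> dict[str, Ladder]:
        return {attr: Ladder(attribute=attr, max_change=self.max_change[attr])
                for attr in self.latents}


def latent_moments(spec: PanelSpec) -> pd.DataFrame:
    """Analytic mean/SD of each latent cell after truncation to (0, max].

    This is the generator's ground truth for parameter-recovery checks:
    sample moments of large panels converge to these values, not to the
    pre-truncation parameters.
    """
    rows = []
    for attr, groups in spec.latents.items():
        hi = spec.max_change[attr]
        for group, cell in groups.items():
            if spec.family == "truncnorm" and cell.sd > 0:
                a = (0.0 - cell.mean) / cell.sd
                b = (hi - cell.mean) / cell.sd
                dist = truncnorm(a, b, loc=cell.mean, scale=cell.sd)
                mean, sd = float(dist.mean()), float(dist.std())
            elif spec.family == "lognormal" and cell.sd > 0:
                mean, sd = _lognormal_truncated_moments(cell, hi)
            else:
                mean, sd = cell.mean, 0.0
            rows.append({"attribute": attr, "group": group,
                         "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


def _lognormal_params(cell: LatentCell) -> tuple[float, float]:
    """Log-space (mu, sigma) matching the cell's arithmetic mean/SD."""
    cv2 = (cell.sd / cell.mean) ** 2
    sigma2 = math.log1p(cv2)
    mu = math.log(cell.mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _lognormal_truncated_moments(cell: LatentCell, hi: float) -> tuple[float, float]:
    from scipy.stats import lognorm
    mu, sigma = _lognormal_params(cell)
    dist = lognorm(s=sigma, scale=math.exp(mu))
    # moments conditional on X <= hi, via partial-expectation identities
    z = dist.cdf(hi)
    if z <= 0:
        raise SpecError(f"lognormal cell has no mass below {hi}")
    from scipy.stats import norm
    lh = math.log(hi)
    m1 = math.exp(mu + sigma ** 2 / 2) * norm.cdf((lh - mu - sigma ** 2) / sigma) / z
    m2 = math.exp(2 * mu + 2 * sigma ** 2) * norm.cdf(
        (lh - mu - 2 * sigma ** 2) / sigma) / z
    return m1, math.sqrt(max(m2 - m1 ** 2, 0.0))


def _draw_latent(cell: LatentCell, hi: float, family: str,
                 rng: np.random.Generator) -> float:
    if cell.sd == 0:
        return cell.mean
    if family == "truncnorm":
        a = (0.0 - cell.mean) / cell.sd
        b = (hi - cell.mean) / cell.sd
        return float(truncnorm.rvs(a, b, loc=cell.mean, scale=cell.sd,
                                   random_state=rng))
    mu, sigma = _lognormal_params(cell)
    while True:  # lognormal clipped to the ladder by rejection
        draw = float(rng.lognormal(mu, sigma))
        if draw <= hi:
            return draw


def generate_panel(
    spec: PanelSpec,
    seed: int | None = None,
) -> tuple[list[RespondentRecord], pd.DataFrame]:
    """Draw a respondent panel and its latent truth table.

    Returns the observable records (elicited indifference amounts, with
    straight-liners recorded at their censoring bounds) and a tidy latent
    truth frame (``respondent_id, age_group, straight_liner, liner_side,
    attribute, latent, observed``) for recovery tests. Respondent-major
    iteration order with a single seeded generator makes panels
    bit-reproducible.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    prefs_attrs = spec.attributes
    records: list[RespondentRecord] = []
    truth_rows: list[dict] = []

    for idx in range(spec.n_respondents):
        rid = f"r{idx:04d}"
        age_group = "under60" if rng.random() < spec.age_mix else "ge60"
        is_liner = rng.random() < spec.straight_liner_fraction
        liner_side = ""
        if is_liner:
            liner_side = "procedure" if rng.random() < 0.5 else "attribute"

        observed_attrs = _observed_attributes(spec, rng)
        mir: dict[str, float] = {}
        censored: dict[str, str] = {}
        for attr in prefs_attrs:
            hi = spec.max_change[attr]
            if is_liner:
                # latent beyond the ladder on every attribute
                if liner_side == "procedure":
                    latent = hi * (1.0 + rng.uniform(0.05, 0.5))
                    obs, cens = hi, "at_max"
                else:
                    latent = rng.uniform(0.0, hi / 16.0) or hi / 32.0
                    obs, cens = hi / 16.0, "at_min"
            else:
                latent = _draw_latent(spec.latents[attr][age_group], hi,
                                      spec.family, rng)
                obs, cens = latent, ""
            seen = attr in observed_attrs
            truth_rows.append({"respondent_id": rid, "age_group": age_group,
                               "straight_liner": is_liner,
                               "liner_side": liner_side, "attribute": attr,
                               "latent": latent, "observed": seen})
            if seen:
                mir[attr] = obs
                if cens:
                    censored[attr] = cens
        if not mir:
            # inclusion rule: at least one completed exercise; re-assign one
            attr = prefs_attrs[int(rng.integers(len(prefs_attrs)))]
            row = next(r for r in truth_rows
                       if r["respondent_id"] == rid and r["attribute"] == attr)
            row["observed"] = True
            mir[attr] = (spec.max_change[attr] if liner_side == "procedure"
                         else spec.max_change[attr] / 16.0
                         if liner_side == "attribute" else row["latent"])
            if is_liner:
                censored[attr] = ("at_max" if liner_side == "procedure"
                                  else "at_min")
        records.append(RespondentRecord(
            respondent_id=rid, age_group=age_group, mir=mir,
            censored=censored, straight_liner=is_liner))

    truth = pd.DataFrame(truth_rows)
    return records, truth


def _observed_attributes(spec: PanelSpec, rng: np.random.Generator) -> set[str]:
    attrs = spec.attributes
    if spec.missingness_mode == "independent":
        return {a for a in attrs
                if rng.random() >= spec.missingness.get(a, 0.0)}
    # assignment mode: each respondent completes 3 or 4 of the exercises,
    # drawn without replacement with inclusion odds matching the published n
    completion = np.array([1.0 - spec.missingness.get(a, 0.0) for a in attrs])
    mean_k = completion.sum()
    k = 3 + (rng.random() < (mean_k - 3.0)) if 3.0 <= mean_k <= 4.0 else \
        int(round(mean_k))
    k = max(1, min(k, len(attrs)))
    p = completion / completion.sum()
    chosen = rng.choice(len(attrs), size=k, replace=False, p=p)
    return {attrs[i] for i in chosen}


def generate_choice_logs(
    truth: pd.DataFrame,
    ladders: Mapping[str, Ladder],
    *,
    error_model: str = "deterministic",
    error_scale: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run every observed respondent × attribute through the choice ladder.

    Output is one row per iteration: ``respondent_id, age_group, attribute,
    iteration, offered_change, chose_procedure`` — the survey's raw choice
    log, which :func:`prefbra.io.panel_from_choice_logs` feeds back through
    the indifference estimator for round-trip testing.
    """
    rng = np.random.default_rng(seed)
    rows = []
    observed = truth[truth["observed"]]
    for _, rec in observed.iterrows():
        ladder = ladders.get(rec["attribute"])
        if ladder is None:
            raise SpecError(f"no ladder for attribute {rec['attribute']!r}")
        responses = run_exercise(rec["latent"], ladder,
                                 error_model=error_model, scale=error_scale,
                                 rng=rng)
        for i, resp in enumerate(responses):
            from .elicitation import next_offer
            offer = next_offer(ladder, responses[:i])
            rows.append({
                "respondent_id": rec["respondent_id"],
                "age_group": rec["age_group"],
                "attribute": rec["attribute"],
                "iteration": resp.iteration,
                "offered_change": offer,
                "chose_procedure": int(resp.chose_procedure_improvement),
            })
    return pd.DataFrame(rows)
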