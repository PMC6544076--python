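"""Synthetic respondent panels: structure, recovery, end-to-end round trips."""

import numpy as np
import pandas as pd
import pytest

import prefbra as pb
from prefbra.io import panel_from_choice_logs
from prefbra.synth import SpecError


@pytest.fixture(scope="module")
def default_panel():
    spec = pb.PanelSpec()
    panel, truth = pb.generate_panel(spec, seed=424242)
    return spec, panel, truth


@pytest.fixture(scope="module")
def big_panel():
    """n=2000 panel for moment-recovery checks."""
    spec = pb.PanelSpec(n_respondents=2000)
    panel, truth = pb.generate_panel(spec, seed=20260901)
    return spec, panel, truth


class TestPanelSpec:
    def test_defaults_mirror_study_conditions(self):
        spec = pb.PanelSpec()
        prefs = pb.load_study_preferences()
        assert spec.n_respondents == prefs["n_total"] == 219
        assert spec.straight_liner_fraction == pytest.approx(0.0868)
        assert spec.age_mix == pytest.approx(prefs["under60_fraction"])
        for attr, groups in spec.latents.items():
            for group, cell in groups.items():
                ref = prefs["mir_summary"][attr][group]
                assert cell.mean == ref["mean"] and cell.sd == ref["sd"]
                assert 0 < cell.mean < spec.max_change[attr]

    def test_infeasible_cells_listed(self):
        with pytest.raises(SpecError, match="mortality"):
            pb.PanelSpec(max_change={**pb.DEFAULT_MAX_CHANGE,
                                     "mortality": 0.01})

    def test_bad_fractions_rejected(self):
        with pytest.raises(SpecError):
            pb.PanelSpec(age_mix=1.5)
        with pytest.raises(SpecError):
            pb.PanelSpec(straight_liner_fraction=-0.1)


class TestGeneratePanel:
    def test_seed_reproducible(self):
        spec = pb.PanelSpec(n_respondents=30)
        p1, t1 = pb.generate_panel(spec, seed=5)
        p2, t2 = pb.generate_panel(spec, seed=5)
        assert p1 == p2
        pd.testing.assert_frame_equal(t1, t2)

    def test_zero_sd_no_missingness_gives_identical_respondents(self):
        latents = {attr: {g: pb.LatentCell(mean=cell.mean, sd=0.0)
                          for g, cell in groups.items()}
                   for attr, groups in pb.PanelSpec().latents.items()}
        spec = pb.PanelSpec(n_respondents=20, latents=latents,
                            straight_liner_fraction=0.0,
                            missingness={a: 0.0 for a in latents},
                            age_mix=1.0)
        panel, _ = pb.generate_panel(spec, seed=3)
        expected = {attr: groups["under60"].mean
                    for attr, groups in latents.items()}
        for rec in panel:
            assert rec.mir == pytest.approx(expected)
            assert not rec.straight_liner

    def test_sample_moments_recover_generator_truth(self, big_panel):
        """Sample mean/SD of non-liner latents match the analytic moments
        of the truncated latent distribution within 3 standard errors."""
        spec, _panel, truth = big_panel
        moments = pb.latent_moments(spec).set_index(["attribute", "group"])
        honest = truth[~truth["straight_liner"]]
        for (attr, group), row in moments.iterrows():
            cell = honest[(honest.attribute == attr)
                          & (honest.age_group == group)]["latent"]
            n = len(cell)
            se_mean = row["sd"] / np.sqrt(n)
            assert abs(cell.mean() - row["mean"]) < 3 * se_mean, (attr, group)
            # SD of the sample within 3 SE of the analytic SD (normal approx)
            se_sd = row["sd"] / np.sqrt(2 * (n - 1))
            assert abs(cell.std(ddof=1) - row["sd"]) < 3 * se_sd, (attr, group)

    def test_observed_means_near_study_summary(self, big_panel):
        """The observable panel (liners included at their censoring bounds)
        reproduces the study's mean indifference amounts: the symmetric
        ladder truncation preserves the configured means."""
        spec, panel, _truth = big_panel
        study = pb.study_mean_mirs("all")
        impacts = {a: 0.0 for a in spec.attributes}
        attrs, _, _ = pb.load_study_config()
        summary = pb.panel_summary(panel, attrs, impacts)
        whole = summary[summary.group == "all"].set_index("attribute")
        for attr, target in study.items():
            got = whole.loc[attr, "mean_mir"]
            assert got == pytest.approx(target, rel=0.08), attr

    def test_age_shift_preserved(self, big_panel):
        """Older respondents tolerate larger pacemaker/dialysis/mortality
        changes, as configured."""
        spec, panel, _ = big_panel
        attrs, _, _ = pb.load_study_config()
        summary = pb.panel_summary(panel, attrs, {a: 0.0 for a in spec.attributes})
        for attr in ("mortality", "pacemaker", "dialysis"):
            young = summary[(summary.attribute == attr)
                            & (summary.group == "under60")].iloc[0].mean_mir
            old = summary[(summary.attribute == attr)
                          & (summary.group == "ge60")].iloc[0].mean_mir
            assert old > young

    def test_missingness_matches_published_n(self, big_panel):
        spec, panel, _ = big_panel
        prefs = pb.load_study_preferences()
        for attr, cells in prefs["mir_summary"].items():
            target = cells["all"]["n"] / prefs["n_total"]
            observed = np.mean([attr in r.mir for r in panel])
            se = np.sqrt(target * (1 - target) / len(panel))
            assert abs(observed - target) < 4 * se, attr

    def test_straight_liner_fraction_zero(self):
        spec = pb.PanelSpec(n_respondents=60, straight_liner_fraction=0.0)
        panel, truth = pb.generate_panel(spec, seed=8)
        assert not any(r.straight_liner for r in panel)
        # deterministic elicitation classifies no one as straight-lining
        logs = pb.generate_choice_logs(truth, spec.ladders(), seed=8)
        rebuilt = panel_from_choice_logs(logs, spec.ladders())
        # interior latents may still one-side a single short exercise by
        # chance; respondents flagged must have every exercise one-sided
        flagged = [r for r in rebuilt if r.straight_liner]
        assert len(flagged) <= max(2, 0.05 * len(rebuilt))

    def test_straight_liner_fraction_recovered(self, big_panel):
        """Planted 8.68% one-siders are recovered after deterministic
        elicitation within binomial bounds."""
        spec, panel, truth = big_panel
        planted = np.mean([r.straight_liner for r in panel])
        f = spec.straight_liner_fraction
        bound = 3 * np.sqrt(f * (1 - f) / len(panel))
        assert abs(planted - f) < bound
        logs = pb.generate_choice_logs(truth, spec.ladders(), seed=1)
        rebuilt = {r.respondent_id: r for r in
                   panel_from_choice_logs(logs, spec.ladders())}
        for rec in panel:
            if rec.straight_liner:
                assert rebuilt[rec.respondent_id].straight_liner

    def test_assignment_mode_gives_three_or_four_exercises(self):
        spec = pb.PanelSpec(n_respondents=100, missingness_mode="assignment")
        panel, _ = pb.generate_panel(spec, seed=4)
        counts = {len(r.mir) for r in panel}
        assert counts <= {3, 4}

    def test_lognormal_family_runs_and_respects_bounds(self):
        spec = pb.PanelSpec(n_respondents=100, family="lognormal",
                            straight_liner_fraction=0.0)
        _, truth = pb.generate_panel(spec, seed=6)
        for attr, hi in spec.max_change.items():
            cell = truth[truth.attribute == attr]["latent"]
            assert (cell > 0).all() and (cell <= hi).all()


class TestChoiceLogs:
    def test_deterministic_round_trip_within_grid_resolution(self):
        """Estimated indifference amounts sit within one final-interval
        half-width of every respondent's latent value."""
        spec = pb.PanelSpec(n_respondents=150, straight_liner_fraction=0.0)
        panel, truth = pb.generate_panel(spec, seed=12)
        logs = pb.generate_choice_logs(truth, spec.ladders(), seed=12)
        rebuilt = {r.respondent_id: r for r in
                   panel_from_choice_logs(logs, spec.ladders())}
        checked = 0
        for _, row in truth[truth.observed].iterrows():
            est = rebuilt[row.respondent_id].mir[row.attribute]
            cens = rebuilt[row.respondent_id].censored.get(row.attribute)
            half = spec.max_change[row.attribute] / 16.0
            if not cens:
                assert abs(est - row.latent) <= half + 1e-12
                checked += 1
        assert checked > 300

    def test_fixed_seed_identical_bytes(self, tmp_path):
        spec = pb.PanelSpec(n_respondents=25, error_model="logistic",
                            error_scale=0.01)
        _, truth = pb.generate_panel(spec, seed=2)
        paths = []
        for i in range(2):
            logs = pb.generate_choice_logs(
                truth, spec.ladders(), error_model="logistic",
                error_scale=0.01, seed=99)
            p = tmp_path / f"logs{i}.csv"
            from prefbra.io import write_choice_logs
            write_choice_logs(p, logs)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_logistic_noise_stays_within_ladder(self):
        spec = pb.PanelSpec(n_respondents=40)
        panel, truth = pb.generate_panel(spec, seed=3)
        logs = pb.generate_choice_logs(truth, spec.ladders(),
                                       error_model="logistic",
                                       error_scale=10.0, seed=3)
        rebuilt = panel_from_choice_logs(logs, spec.ladders())
        for rec in rebuilt:
            for attr, value in rec.mir.items():
                assert 0 < value <= spec.max_change[attr]


class TestEndToEnd:
    def test_threshold_recovery_through_elicitation(self):
        """Panel → choice logs → indifference estimation → group weights →
        thresholds agrees with thresholds computed directly from the
        panel's elicited values: the grid only perturbs each mean MIR by
        at most one half-interval, and the threshold map is smooth."""
        spec = pb.PanelSpec(n_respondents=500, straight_liner_fraction=0.0)
        panel, truth = pb.generate_panel(spec, seed=14)
        logs = pb.generate_choice_logs(truth, spec.ladders(), seed=14)
        rebuilt = panel_from_choice_logs(logs, spec.ladders())
        attrs, profiles, _ = pb.load_study_config()
        tavr, savr = profiles["TAVR"], profiles["SAVR"]
        direct = pb.threshold_table(
            tavr, savr, pb.group_weights(panel, attrs), attrs,
            clamp_policy="none")
        via_ladder = pb.threshold_table(
            tavr, savr, pb.group_weights(rebuilt, attrs), attrs,
            clamp_policy="none")
        for name in direct:
            scale = spec.max_change.get(name, 1.0)
            # grid resolution propagated through the threshold formula:
            # generous linearised bound of one grid cell on the level
            assert abs(via_ladder[name].raw_level - direct[name].raw_level) \
                <= scale / 4.0, name

    def test_default_conditions_reproduce_study_thresholds(self):
        """Whole-sample thresholds from an n=2000 synthetic panel land
        within 1 percentage point (1 year) of the study's threshold table."""
        spec = pb.PanelSpec(n_respondents=2000)
        panel, _ = pb.generate_panel(spec, seed=2026)
        attrs, profiles, _ = pb.load_study_config()
        table = pb.threshold_table(profiles["TAVR"], profiles["SAVR"],
                                   pb.group_weights(panel, attrs), attrs)
        published = {"mortality": 0.126, "stroke": 0.207,
                     "independence": 0.065, "pacemaker": 0.330,
                     "dialysis": 0.216, "proven_to_work": 0.0}
        for name, target in published.items():
            tol = 1.0 if name == "proven_to_work" else 0.01
            assert abs(table[name].threshold_level - target) <= tol, name
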