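"""Behavioural statistics: annotation, bouts, regressions, goal analyses."""

import numpy as np
import pandas as pd
import pytest

from needscape.behavior_stats import (
    behavioral_needs,
    choice_predictor_comparison,
    choice_probability_vs_need,
    compare_phase_portraits,
    goal_switch_analysis,
    persistence_fit,
    phase_portrait,
    run_lengths,
    selectivity_index,
    self_transition_regression,
    stim_choice_density,
    transition_matrix_mle,
    transition_vs_interval,
)


def _table(outcomes, session="s1", t0=0.0, dt=10.0, labels=None):
    n = len(outcomes)
    return pd.DataFrame({
        "session_id": session,
        "trial_time_s": t0 + dt * np.arange(n),
        "label": labels if labels is not None else
        ["NoGo" if o == "nogo" else "Go" for o in outcomes],
        "outcome": outcomes,
    })


class TestBehavioralNeeds:
    def test_first_trial_of_median_session_has_unit_needs(self):
        df = _table(["water"] * 4 + ["food"] * 6)
        ann = behavioral_needs(df, median_totals=(4, 6))
        assert ann.loc[0, "thirst"] == pytest.approx(1.0)
        assert ann.loc[0, "hunger"] == pytest.approx(1.0)
        assert ann.loc[0, "relative_need"] == pytest.approx(0.0)

    def test_after_all_water_collected_relative_need_is_minus_one(self):
        df = _table(["water", "water", "food", "food"])
        ann = behavioral_needs(df, median_totals=(2, 2))
        # third trial: no water remains, one food reward still to come
        assert ann.loc[2, "thirst"] == pytest.approx(0.0)
        assert ann.loc[2, "relative_need"] == pytest.approx(-1.0)

    def test_hand_recount_of_toy_session(self):
        # independent spreadsheet-style recount of a 10-trial session
        outcomes = ["water", "food", "miss", "water", "nogo",
                    "food", "food", "water", "miss", "food"]
        df = _table(outcomes)
        ann = behavioral_needs(df, median_totals=(3, 4))
        # water collected before each trial: 0,1,1,1,2,2,2,2,3,3
        water_before = [0, 1, 1, 1, 2, 2, 2, 2, 3, 3]
        food_before = [0, 0, 1, 1, 1, 1, 2, 3, 3, 3]
        expect_T = [(3 - w) / 3 for w in water_before]
        expect_H = [(4 - f) / 4 for f in food_before]
        np.testing.assert_allclose(ann["thirst"], expect_T)
        np.testing.assert_allclose(ann["hunger"], expect_H)

    def test_last_water_trial_has_positive_thirst(self):
        df = _table(["water", "food", "water"])
        ann = behavioral_needs(df, median_totals=(2, 1))
        last_water = ann[ann["outcome"] == "water"].iloc[-1]
        assert last_water["thirst"] >= 1 / 2

    def test_undefined_relative_need_is_nan(self):
        df = _table(["water", "miss", "miss"])
        ann = behavioral_needs(df, median_totals=(1, 1))
        assert np.isnan(ann.loc[2, "relative_need"])


class TestSelectivity:
    @pytest.mark.parametrize("outcomes,expected", [
        (["water"] * 5, 1.0),
        (["food"] * 5, -1.0),
        (["water", "food", "water", "food"], 0.0),
        (["water", "water", "water", "food"], 0.5),
    ])
    def test_closed_form_values(self, outcomes, expected):
        idx = selectivity_index(_table(outcomes))
        assert idx["s1"] == pytest.approx(expected)


class TestPersistence:
    def test_run_length_decomposition(self):
        runs = run_lengths(["water", "water", "miss", "water", "food", "food"])
        # misses do not interrupt a run of identical rewarded choices
        np.testing.assert_array_equal(runs, [3, 2])

    def test_strict_alternation_gives_p_one(self):
        df = _table(["water", "food"] * 20)
        fit = persistence_fit(df, n_boot=50)
        assert fit.p_hat == pytest.approx(1.0)

    def test_recovers_geometric_parameter(self, rng):
        # sampling oracle: pooled counts drawn from geometric(p = 0.1)
        lengths = rng.geometric(0.1, size=10_000)
        outcomes = []
        cur = "water"
        for L in lengths:
            outcomes += [cur] * int(L)
            cur = "food" if cur == "water" else "water"
        frames = []
        chunk = len(outcomes) // 10
        for k in range(10):
            frames.append(_table(outcomes[k * chunk:(k + 1) * chunk],
                                 session=f"s{k}"))
        fit = persistence_fit(pd.concat(frames, ignore_index=True), n_boot=100)
        assert fit.p_hat == pytest.approx(0.1, abs=0.01)
        assert fit.ci[0] < fit.p_hat < fit.ci[1]

    def test_mle_equals_inverse_mean_everywhere(self, small_dataset):
        sessions, _ = small_dataset
        fit = persistence_fit(sessions, n_boot=10)
        assert fit.p_hat == pytest.approx(1.0 / fit.pooled.mean(), rel=1e-12)


class TestChoiceVsNeed:
    def test_permuted_need_gives_flat_slope(self, rng):
        # null case: destroying the trial/need pairing flattens the fit
        # (note the raw annotation is mechanically coupled to outcomes,
        # because behavioural need counts the future choices themselves)
        frames = []
        for k in range(6):
            outs = rng.choice(["water", "food"], size=300)
            frames.append(_table(list(outs), session=f"s{k}"))
        ann = behavioral_needs(pd.concat(frames, ignore_index=True))
        ann["relative_need"] = rng.permutation(ann["relative_need"].to_numpy())
        reg = choice_probability_vs_need(ann, n_boot=100)
        assert reg.slope_ci[0] < 0.05 and reg.slope_ci[1] > -0.05

    def test_deterministic_threshold_rule_gives_step(self):
        # subjects that always pick the currently larger remaining stock
        # produce a binned curve that is a step at zero relative need
        frames = []
        for k, (rw, rf) in enumerate([(220, 100), (100, 220),
                                      (260, 60), (60, 260)]):
            outs = []
            w, f = rw, rf
            while w + f > 0:
                if w / 160 > f / 160:
                    outs.append("water")
                    w -= 1
                else:
                    outs.append("food")
                    f -= 1
            frames.append(_table(outs, session=f"s{k}"))
        ann = behavioral_needs(pd.concat(frames, ignore_index=True),
                               median_totals=(160, 160))
        reg = choice_probability_vs_need(ann, n_boot=50)
        binned = reg.binned
        low = binned[binned["bin_hi"] < -0.05]["mle"]
        high = binned[binned["bin_lo"] > 0.05]["mle"]
        assert len(low) and len(high)
        assert low.mean() < 0.05 and high.mean() > 0.95

    def test_ols_matches_polyfit_oracle(self, assay_annotated):
        reg = choice_probability_vs_need(assay_annotated, n_boot=10)
        d = assay_annotated[
            assay_annotated["outcome"].isin(["water", "food"])].dropna(
            subset=["relative_need"])
        slope, intercept = np.polyfit(
            d["relative_need"], (d["outcome"] == "water").astype(float), 1)
        assert reg.slope == pytest.approx(slope, rel=1e-8)
        assert reg.intercept == pytest.approx(intercept, rel=1e-8)


class TestSelfTransition:
    def test_perfect_persistence_has_unit_intercept_zero_slope(self):
        # sessions that never switch give a constant repeat indicator
        df = pd.concat([
            _table(["water"] * 80, session="a"),
            _table(["food"] * 80, session="b"),
        ], ignore_index=True)
        ann = behavioral_needs(df)
        regs = self_transition_regression(ann, min_remaining=0, n_boot=20)
        # relative need is constant within each single-choice session, so
        # intercept and slope are only identified jointly; the fitted
        # repeat probability at the observed need is exactly 1
        for choice, x in (("water", 1.0), ("food", -1.0)):
            reg = regs[choice]
            assert reg.intercept + reg.slope * x == pytest.approx(1.0,
                                                                  abs=1e-9)

    def test_mirror_symmetry_of_slopes(self, rng):
        # relabeling water<->food flips the sign of the slope
        frames = []
        for k in range(8):
            p = rng.random(200)
            outs = np.where(p < 0.5, "water", "food")
            frames.append(_table(list(outs), session=f"s{k}"))
        df = pd.concat(frames, ignore_index=True)
        ann = behavioral_needs(df)
        regs = self_transition_regression(ann, min_remaining=0, n_boot=20)
        sw = {"water": "food", "food": "water"}
        mirrored = df.assign(outcome=df["outcome"].map(lambda o: sw.get(o, o)))
        ann_m = behavioral_needs(mirrored)
        regs_m = self_transition_regression(ann_m, min_remaining=0, n_boot=20)
        assert regs["water"].slope == pytest.approx(-regs_m["food"].slope,
                                                    abs=1e-9)

    def test_hand_counted_ols_oracle(self):
        # 20 annotated pairs against an independent least-squares fit
        rng = np.random.default_rng(3)
        outs = list(rng.choice(["water", "food"], size=21, p=[0.6, 0.4]))
        ann = behavioral_needs(_table(outs))
        regs = self_transition_regression(ann, min_remaining=0, n_boot=10)
        r = ann[ann["outcome"].isin(["water", "food"])].copy()
        r["prev"] = r["outcome"].shift(1)
        sub = r[r["prev"] == "water"].dropna(subset=["relative_need"])
        if len(sub) >= 3 and sub["relative_need"].nunique() > 1:
            slope, _ = np.polyfit(sub["relative_need"],
                                  (sub["outcome"] == "water").astype(float), 1)
            assert regs["water"].slope == pytest.approx(slope, rel=1e-8)


class TestTransitionMatrixMLE:
    def test_counting_example(self):
        # W W F F W within the window gives all entries 0.5
        ann = behavioral_needs(
            _table(["water", "water", "food", "food", "water"]))
        ann["relative_need"] = 0.0     # force everything inside the window
        mat, lo, hi = transition_matrix_mle(ann, n_boot=10)
        np.testing.assert_allclose(mat.to_numpy(), 0.5)

    def test_rows_sum_to_one(self, assay_annotated):
        mat, _, _ = transition_matrix_mle(assay_annotated, n_boot=10)
        np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-12)


class TestTransitionVsInterval:
    def test_switch_probability_grows_with_elapsed_time(self, assay_annotated,
                                                        geom, fitted_params):
        out = transition_vs_interval(assay_annotated, geom, fitted_params,
                                     bin_edges=(0, 8, 16, 32, 64))
        assert len(out) >= 3
        p = out["p_switch"].to_numpy()
        assert p[-1] > p[0]
        # theory switch probability vanishes as the interval shrinks
        assert out["p_theory"].iloc[0] < out["p_theory"].iloc[-1]


class TestChoicePredictor:
    def _sticky_markov(self, rng, n=400, stay=0.92):
        outs = ["water"]
        for _ in range(n - 1):
            if rng.random() < stay:
                outs.append(outs[-1])
            else:
                outs.append("food" if outs[-1] == "water" else "water")
        return outs

    def test_sticky_markov_favours_previous_choice(self, rng):
        frames = [
            _table(self._sticky_markov(rng), session=f"s{k}") for k in range(4)]
        ann = behavioral_needs(pd.concat(frames, ignore_index=True))
        res = choice_predictor_comparison(ann, seed=1)
        assert res["auc_previous"].median() > res["auc_needs"].median()

    def test_memoryless_threshold_favours_needs(self, rng):
        frames = []
        for k in range(4):
            # choice driven purely by the remaining-reward balance
            n_w, n_f = 150, 150
            outs = []
            rw, rf = n_w, n_f
            for _ in range(n_w + n_f):
                p_w = rw / max(rw + rf, 1)
                if rng.random() < p_w:
                    outs.append("water")
                    rw -= 1
                else:
                    outs.append("food")
                    rf -= 1
            frames.append(_table(outs, session=f"s{k}"))
        ann = behavioral_needs(pd.concat(frames, ignore_index=True))
        res = choice_predictor_comparison(ann, seed=2)
        assert res["auc_needs"].median() > res["auc_previous"].median()

    def test_label_permutation_gives_chance_aucs(self, rng):
        frames = [
            _table(list(rng.choice(["water", "food"], 400)), session=f"s{k}")
            for k in range(6)]
        df = pd.concat(frames, ignore_index=True)
        ann = behavioral_needs(df)
        # permute outcomes within session to destroy both signals
        ann["outcome"] = rng.permutation(ann["outcome"].to_numpy())
        res = choice_predictor_comparison(ann, seed=3)
        assert abs(res["auc_needs"].median() - 0.5) < 0.12
        assert abs(res["auc_previous"].median() - 0.5) < 0.12


class TestStimChoiceDensity:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(4)
        onsets = 60.0 * np.arange(1, 11)
        t = np.sort(rng.uniform(0, 660, 200))
        df = pd.DataFrame({
            "session_id": "s", "trial_time_s": t, "label": "Go",
            "outcome": rng.choice(["water", "food"], t.size)})
        dens = stim_choice_density(df, onsets)
        for choice, d in dens.items():
            area = np.trapezoid(d["density"], d["offset_s"])
            assert area == pytest.approx(1.0, abs=0.1)

    def test_no_events_near_onsets_is_empty(self):
        df = pd.DataFrame({
            "session_id": "s", "trial_time_s": [5000.0], "label": ["Go"],
            "outcome": ["water"]})
        dens = stim_choice_density(df, [100.0], window=(-30, 30))
        assert dens == {}


class TestGoalSwitchAnalysis:
    def _trials_with_goal(self, goal, outcomes, session="s"):
        return pd.DataFrame({
            "session_id": session, "outcome": outcomes, "goal": goal})

    def test_instant_jumps_keep_predictiveness_maximal(self):
        # degenerate control: goal is constant within bouts
        outs = ["water"] * 20 + ["food"] * 20 + ["water"] * 20
        goal = [5.0] * 20 + [-5.0] * 20 + [5.0] * 20
        res = goal_switch_analysis(self._trials_with_goal(goal, outs))
        assert res.auc_all == pytest.approx(1.0)
        assert (res.auc_by_distance["auc"] == 1.0).all()

    def test_permuted_switch_labels_give_chance_auc(self, rng):
        n = 600
        goal = rng.normal(0, 3, n)
        outs = list(rng.choice(["water", "food"], n))
        res = goal_switch_analysis(self._trials_with_goal(goal, outs))
        assert abs(res.switch_auc - 0.5) < 0.08

    def test_diffusion_switches_are_preceded_by_midpoint_approach(
            self, assay_dataset):
        # predictiveness of the pre-cue baseline goal value dips at and
        # just before switches relative to all trials
        sessions, gt = assay_dataset
        frames = []
        for k, res in enumerate(gt["results"]):
            r = res.trials
            # baseline goal: position on the goal axis 1 s before the cue
            idx = np.clip(np.searchsorted(
                res.traj_times, r["trial_time_s"].to_numpy() - 1.0),
                0, len(res.traj_times) - 1)
            frames.append(pd.DataFrame({
                "session_id": f"x{k}", "outcome": r["outcome"].to_numpy(),
                "goal": res.traj[idx, 1]}))
        trials = pd.concat(frames, ignore_index=True)
        out = goal_switch_analysis(trials)
        near = out.auc_by_distance.set_index("trials_to_switch")["auc"]
        assert near.loc[0] < out.auc_all          # switch trials are ambiguous
        assert near.loc[0] < near.max()
        assert out.switch_auc > 0.55              # |goal| predicts switches


class TestPhasePortrait:
    def test_all_stay_data_has_zero_switch_density(self):
        df = pd.DataFrame({
            "session_id": "s", "outcome": ["water"] * 50,
            "goal": np.linspace(5, 7, 50)})
        pp = phase_portrait(df, n_resample=10)
        assert pp.switch_density.sum() == 0.0

    def test_densities_normalized(self, assay_dataset):
        sessions, gt = assay_dataset
        res = gt["results"][0]
        df = pd.DataFrame({"session_id": "s", "outcome": res.trials["outcome"],
                           "goal": res.trials["y"]})
        pp = phase_portrait(df, n_resample=50)
        assert pp.stay_density.sum() == pytest.approx(1.0)
        assert pp.switch_density.sum() == pytest.approx(1.0)

    def test_forced_and_diffusion_models_distinguishable(self, geom,
                                                         fitted_params):
        from needscape.dynamics import (
            SimConfig,
            simulate_forced_transition,
            simulate_session,
        )
        from needscape.session_gen import ScheduleSpec, generate_trial_schedule

        frames_d, frames_f = [], []
        for k in range(4):
            sched = generate_trial_schedule(
                ScheduleSpec(duration=3600.0, seed=50 + k))
            cfg = SimConfig(duration=3600.0, T0=2.0, H0=2.0,
                            rng_seed=60 + k, miss_termination=None)
            d = simulate_session(cfg, sched, geom, fitted_params)
            f = simulate_forced_transition(cfg, sched, geom,
                                           force_rate=1 / 120.0)
            for res, acc in ((d, frames_d), (f, frames_f)):
                acc.append(pd.DataFrame({
                    "session_id": f"s{k}", "outcome": res.trials["outcome"],
                    "goal": res.trials["y"]}))
        pp_d = phase_portrait(pd.concat(frames_d, ignore_index=True),
                              n_resample=100)
        pp_f = phase_portrait(pd.concat(frames_f, ignore_index=True),
                              n_resample=100)
        stat, p = compare_phase_portraits(pp_d, pp_f)
        assert p < 0.01
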