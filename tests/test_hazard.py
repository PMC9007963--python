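import warnings

import numpy as np
import pandas as pd
import pytest

import evacnet as ev
from evacnet.engine import RoundResult, SessionLog
from evacnet.hazard import ConvergenceError, _pl_parts

from conftest import make_handcrafted_log


# ---------------------------------------------------------------------------
# counting-process construction
# ---------------------------------------------------------------------------

class TestBuildCountingProcess:
    def test_idle_isolated_player_single_censored_row(self):
        log = make_handcrafted_log([], duration=75.0)
        cp = ev.build_counting_process(log)
        rows = cp[cp.player_id == 3]
        assert len(rows) == 1
        r = rows.iloc[0]
        assert (r.start, r.stop, bool(r.event)) == (0.0, 75.0, False)
        assert r.x_safe == 0 and r.x_danger == 0

    def test_rows_split_at_followee_display_window(self):
        # followee 1 presses safe at t=10; ego 0 follows 1
        log = make_handcrafted_log([(10.0, 1, "press_safe")], edges=[(0, 1)],
                                   duration=75.0)
        cp = ev.build_counting_process(log)
        rows = cp[cp.player_id == 0].reset_index(drop=True)
        assert list(rows.start) == [0.0, 10.0, 15.0]
        assert list(rows.stop) == [10.0, 15.0, 75.0]
        assert list(rows.x_safe) == [0, 1, 0]

    def test_event_row_at_evacuation_no_rows_after(self):
        log = make_handcrafted_log([(40.0, 2, "evacuate")], duration=75.0)
        cp = ev.build_counting_process(log)
        rows = cp[cp.player_id == 2]
        assert rows.stop.max() == 40.0
        assert bool(rows.iloc[-1].event)

    def test_first_signal_terminal_censors_at_evacuation(self):
        log = make_handcrafted_log(
            [(20.0, 0, "evacuate"), (30.0, 1, "press_safe")], duration=75.0)
        cp = ev.build_counting_process(log, terminal="first_signal")
        r0 = cp[cp.player_id == 0]
        assert r0.stop.max() == 20.0 and not r0.event.any()
        r1 = cp[cp.player_id == 1]
        assert r1.stop.max() == 30.0 and bool(r1.iloc[-1].event)

    def test_own_press_increments_y_left_continuously(self):
        log = make_handcrafted_log([(10.0, 0, "press_danger")], duration=75.0)
        cp = ev.build_counting_process(log)
        rows = cp[cp.player_id == 0].reset_index(drop=True)
        assert list(rows.y_danger) == [0, 1]
        assert list(rows.start) == [0.0, 10.0]

    def test_covariate_path_reconstructs_exposure(self, dynamic_dddd_log):
        """Row covariates agree with an independent re-count of followee
        displays at interval midpoints, for every player-round."""
        from evacnet.diffusion import display_intervals
        cp = ev.build_counting_process(dynamic_dddd_log)
        for r in (1, 4):
            net = dynamic_dddd_log.network_snapshots[r - 1]
            wins = display_intervals(dynamic_dddd_log, r)
            sub = cp[cp["round"] == r]
            for _, row in sub.iterrows():
                m = 0.5 * (row.start + row.stop)
                expect = {"safe": 0, "danger": 0}
                for j in net.followees(row.player_id):
                    for s, e, k in wins.get(j, []):
                        if s <= m < e:
                            expect[k] += 1
                assert row.x_safe == expect["safe"]
                assert row.x_danger == expect["danger"]

    def test_intervals_partition_followup(self, mixed_logs):
        cp = ev.build_counting_process(mixed_logs[0])
        for (_, pid, rnd), grp in cp.groupby(["session_id", "player_id", "round"]):
            g = grp.sort_values("start")
            assert (g.start < g.stop).all()
            assert np.allclose(g.stop.to_numpy()[:-1], g.start.to_numpy()[1:])
            assert g.event.sum() <= 1
            if g.event.any():
                assert bool(g.iloc[-1].event)

    def test_experience_covariates_track_prior_rounds(self, dynamic_dddd_log):
        cp = ev.build_counting_process(dynamic_dddd_log)
        r4 = cp[cp["round"] == 4]
        assert (r4.rounds_played == 3).all()
        assert (r4.disasters_experienced == 3).all()
        assert (r4.disasters_struck_by <= 3).all()


# ---------------------------------------------------------------------------
# partial-likelihood fitting
# ---------------------------------------------------------------------------

def simple_df(rows):
    return pd.DataFrame(rows, columns=["subject", "start", "stop", "event", "x"])


class TestFit:
    def test_symmetric_groups_give_zero_coefficient(self):
        rows = []
        for g in (0, 1):
            for i, (t, e) in enumerate([(1.0, True), (2.0, True), (3.0, False)]):
                rows.append((f"{g}{i}", 0.0, t, e, g))
        res = ev.EvacuationHazardModel(simple_df(rows), covariates=["x"]).fit()
        assert res.params["x"] == pytest.approx(0.0, abs=1e-8)

    def test_matches_bisection_on_score_equation(self, rng):
        """On untied single-covariate data the Newton estimate equals the
        root of an independently coded score function found by bisection."""
        n = 60
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / np.exp(0.5 * x))
        t += rng.uniform(0, 1e-6, n)  # break ties
        event = t < np.quantile(t, 0.8)
        stop = np.minimum(t, np.quantile(t, 0.8))
        df = simple_df([(i, 0.0, stop[i], bool(event[i]), x[i]) for i in range(n)])

        def score(beta):
            s = 0.0
            for i in np.where(event)[0]:
                risk = stop >= stop[i]
                w = np.exp(beta * x[risk])
                s += x[i] - (w * x[risk]).sum() / w.sum()
            return s

        lo, hi = -5.0, 5.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if score(mid) > 0:
                lo = mid
            else:
                hi = mid
        res = ev.EvacuationHazardModel(df, covariates=["x"]).fit()
        assert res.params["x"] == pytest.approx((lo + hi) / 2, abs=1e-6)

    def test_hand_computed_breslow_likelihood(self):
        """4 subjects, 2 events: partial likelihood matches the Breslow
        formula evaluated by hand."""
        df = simple_df([
            ("a", 0.0, 2.0, True, 1.0),
            ("b", 0.0, 3.0, True, 0.0),
            ("c", 0.0, 4.0, False, 1.0),
            ("d", 0.0, 5.0, False, 0.0),
        ])
        beta = np.array([0.3])
        X = df[["x"]].to_numpy(float)
        ll, *_ = _pl_parts(df.start.to_numpy(), df.stop.to_numpy(),
                           df.event.to_numpy(bool), X, beta)
        e = np.exp(0.3)
        # event 1 (t=2, x=1): risk {a,b,c,d}; event 2 (t=3, x=0): risk {b,c,d}
        hand = (0.3 - np.log(2 * e + 2)) + (0.0 - np.log(e + 2))
        assert ll == pytest.approx(hand, abs=1e-12)

    def test_agrees_with_lifelines_time_varying(self, mixed_logs):
        """Cross-check against an independent Cox implementation on the
        package's own counting-process data (tied event times, Efron)."""
        from lifelines import CoxTimeVaryingFitter
        cp = ev.build_counting_process(mixed_logs[0])
        cov = ["x_safe", "x_danger", "disasters_struck_by"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ev.EvacuationHazardModel(cp, covariates=cov).fit(ties="efron")
        keep = cp[["subject", "start", "stop", "event"] + res.params.index.tolist()]
        ctv = CoxTimeVaryingFitter()
        ctv.fit(keep.assign(event=keep.event.astype(int)), id_col="subject",
                start_col="start", stop_col="stop", event_col="event")
        for c in res.params.index:
            assert res.params[c] == pytest.approx(ctv.params_[c], abs=1e-6)
            assert res.bse[c] == pytest.approx(ctv.standard_errors_[c], rel=1e-4)

    def test_constant_covariate_dropped_with_warning(self):
        df = simple_df([("a", 0, 2, True, 1), ("b", 0, 3, True, 1),
                        ("c", 0, 4, False, 1)])
        df["z"] = [0.0, 1.0, 2.0]
        with pytest.warns(UserWarning, match="constant"):
            m = ev.EvacuationHazardModel(df, covariates=["x", "z"])
        assert m.covariates == ["z"]

    def test_separation_detected(self):
        # perfect separation: all events in one group, none in the other
        rows = [(i, 0.0, 1.0 + 0.1 * i, True, 1.0) for i in range(5)]
        rows += [(5 + i, 0.0, 10.0 + i, False, 0.0) for i in range(5)]
        with pytest.raises(ConvergenceError):
            ev.EvacuationHazardModel(simple_df(rows), covariates=["x"]).fit()

    def test_no_events_rejected(self):
        df = simple_df([("a", 0, 2, False, 1), ("b", 0, 3, False, 0)])
        with pytest.raises(ValueError):
            ev.EvacuationHazardModel(df, covariates=["x"])

    def test_cluster_robust_errors_differ_but_estimate_agrees(self, mixed_logs):
        cp = pd.concat([ev.build_counting_process(l) for l in mixed_logs[:4]],
                       ignore_index=True)
        cov = ["x_danger", "disasters_struck_by"]
        m = ev.EvacuationHazardModel(cp, covariates=cov)
        plain = m.fit()
        robust = m.fit(robust_cluster="session_id")
        assert np.allclose(plain.params, robust.params)
        assert not np.allclose(plain.bse, robust.bse)
        assert (robust.bse > 0).all()


class TestFrailty:
    def test_null_frailty_variance_estimated_near_zero(self):
        """Simulated from a frailty-free model, the estimated frailty
        variance is <= 0.05 in at least 90% of replicates."""
        hits = 0
        reps = 10
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            n = 80
            x = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(1 / (0.05 * np.exp(0.5 * x)))
            stop = np.minimum(t, 40.0)
            event = t < 40.0
            df = simple_df([(i, 0.0, stop[i], bool(event[i]), x[i])
                            for i in range(n)])
            res = ev.EvacuationHazardModel(df, covariates=["x"]).fit(frailty=True)
            if res.frailty_variance <= 0.05:
                hits += 1
        assert hits >= 9

    def test_frailty_detected_when_present(self):
        """Strong subject heterogeneity yields a positive variance estimate."""
        rng = np.random.default_rng(7)
        n = 120
        x = rng.integers(0, 2, n).astype(float)
        frail = rng.gamma(0.5, 2.0, n)  # variance 2
        rows = []
        for i in range(n):
            for rep in range(3):  # recurrent intervals per subject
                t = rng.exponential(1 / (0.08 * frail[i] * np.exp(0.3 * x[i])))
                stop = min(t, 30.0)
                rows.append((i, 0.0 + 40 * rep, 40 * rep + stop,
                             bool(t < 30.0), x[i]))
        res = ev.EvacuationHazardModel(simple_df(rows),
                                       covariates=["x"]).fit(frailty=True)
        assert res.frailty_variance > 0.05


@pytest.fixture(scope="module")
def fit(mixed_logs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = ev.EvacuationHazardModel.from_logs(
            mixed_logs, covariates=["x_safe", "x_danger", "disasters_struck_by"])
        return m.fit()


class TestCumulativeProbability:

    def test_mean_scenario_equals_baseline(self, fit):
        scen = fit.covariate_means.to_dict()
        curve = fit.cumulative_action_probability(scen)
        base = 1 - np.exp(-fit.baseline_cumhazard["cum_hazard"])
        assert np.allclose(curve["prob"], base)

    def test_monotone_nondecreasing(self, fit):
        scen = {"x_safe": 1, "x_danger": 1, "disasters_struck_by": 1}
        probs = fit.cumulative_action_probability(scen)["prob"].to_numpy()
        assert (np.diff(probs) >= -1e-12).all()
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_struck_by_orders_curves_when_coefficient_positive(self, fit):
        assert fit.params["disasters_struck_by"] > 0
        curves = [fit.cumulative_action_probability(
            {"x_safe": 1, "x_danger": 1, "disasters_struck_by": k})["prob"].to_numpy()
            for k in range(4)]
        for lo, hi in zip(curves, curves[1:]):
            assert (hi >= lo - 1e-12).all()

    def test_horizon_truncation_warns(self, fit):
        last = fit.baseline_cumhazard["t"].iloc[-1]
        with pytest.warns(UserWarning, match="truncated"):
            curve = fit.cumulative_action_probability(
                {"x_safe": 0, "x_danger": 0, "disasters_struck_by": 0},
                horizon=last + 100)
        assert curve["t"].iloc[-1] <= last + 100

    def test_missing_scenario_covariate_rejected(self, fit):
        with pytest.raises(ValueError):
            fit.cumulative_action_probability({"x_safe": 1})

    def test_summary_table_shape(self, fit):
        s = fit.summary()
        assert {"coef", "exp(coef)", "se(coef)", "z", "p"} <= set(s.columns)
        assert (s["se(coef)"] > 0).all()


# ---------------------------------------------------------------------------
# conditional evacuation rates
# ---------------------------------------------------------------------------

def two_round_log(cond, d1, evacuators_r2, n=12, informant=0, seed=0):
    cfg = ev.GameConfig(n_players=n, condition=cond,
                        disaster_pattern=[d1, False], n_rounds=2, seed=seed)
    def rr(idx, disaster, evacs):
        per = {}
        for pid in range(n):
            evac = pid in evacs
            per[pid] = {"action": "evacuated" if evac else "stayed",
                        "correct": evac == disaster,
                        "struck": disaster and not evac,
                        "safe_display_seconds": 0.0,
                        "danger_display_seconds": 0.0, "round_bonus": 0.0}
        return RoundResult(idx, 75.0, disaster, per)
    nets = [ev.DirectedNetwork.from_edges(range(n), [])] * 2
    return SessionLog(cfg, [], nets, [rr(1, d1, set()), rr(2, False, evacuators_r2)],
                      informants=[informant, informant], session_id=f"{cond}{d1}{seed}")


class TestConditionalEvacuationTable:
    def test_all_evacuate_rate_one_wilson_upper_one(self):
        logs = [two_round_log("static_network", True, set(range(12))),
                two_round_log("static_network", False, set())]
        df = ev.conditional_evacuation_table(logs)
        row = df[(df.round1_disaster) & (df.condition == "static_network")].iloc[0]
        assert row["rate"] == 1.0 and row["ci_upper"] == pytest.approx(1.0)
        assert row["n"] == 11  # informant excluded

    def test_zero_evacuations_wilson_lower_zero(self):
        logs = [two_round_log("independent", False, set()),
                two_round_log("independent", True, set())]
        df = ev.conditional_evacuation_table(logs)
        assert (df["rate"] == 0).all()
        assert (df["ci_lower"] == 0).all()

    def test_equal_proportions_z_zero(self):
        evacs = set(range(1, 6))  # 5 of 11 non-informants in both strata
        logs = [two_round_log("independent", True, evacs),
                two_round_log("independent", False, evacs)]
        df = ev.conditional_evacuation_table(logs)
        assert df["z_vs_other_stratum"].abs().max() == pytest.approx(0.0)
        assert df["p_vs_other_stratum"].min() == pytest.approx(1.0)

    def test_single_round_log_rejected(self):
        log = make_handcrafted_log([])
        with pytest.raises(ValueError):
            ev.conditional_evacuation_table([log])
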