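import numpy as np
import pytest
from scipy.integrate import solve_ivp

from organchip.errors import ArgumentError
from organchip.pharm import percent_change
from organchip.pkpd import (K_H_DEFAULT, CytokineConfig, ExperimentProtocol,
                            PDParams, PKParams, beat_rate_response,
                            calibrate_pd_defaults, default_pd_params,
                            default_pk_params, simulate_clearance,
                            simulate_cytokine_challenge,
                            simulate_three_tissue_scenario,
                            simulate_two_tissue_experiment)

DUAL_DRUG_EVENTS = [(0.0, "propranolol", 0.1), (18.0, "epinephrine", 0.5)]


class TestClearance:
    def test_initial_condition(self):
        pk = PKParams(C0_uM=0.1)
        assert simulate_clearance(pk, 0.0) == pytest.approx(0.1)

    def test_threefold_decrease_over_48h(self):
        pk = PKParams(C0_uM=0.1)
        assert simulate_clearance(pk, 48.0) == pytest.approx(0.1 / 3.0, rel=0.005)

    def test_matches_ode_oracle(self):
        pk = PKParams(k_h=0.07, C0_uM=2.5)
        ts = np.linspace(0.0, 60.0, 7)
        sol = solve_ivp(lambda t, c: -pk.k_h * c, (0.0, 60.0), [pk.C0_uM],
                        t_eval=ts, rtol=1e-10, atol=1e-14)
        closed = simulate_clearance(pk, ts)
        np.testing.assert_allclose(closed, sol.y[0], rtol=1e-6)

    def test_monotone_decreasing(self):
        pk = PKParams(C0_uM=1.0)
        ts = np.linspace(0, 100, 50)
        c = simulate_clearance(pk, ts)
        assert np.all(np.diff(c) < 0) and np.all(c > 0)

    def test_negative_time_rejected(self):
        with pytest.raises(ArgumentError):
            simulate_clearance(PKParams(C0_uM=1.0), -1.0)

    def test_modes_without_liver_do_not_clear(self):
        assert default_pk_params(mode="cardiac_only").k_h == 0.0
        assert default_pk_params(mode="hepatocyte_2d").k_h == 0.0
        assert default_pk_params(mode="liver_cardiac").k_h == K_H_DEFAULT


class TestBeatRateResponse:
    def test_null_input_returns_intrinsic_rate(self):
        p = PDParams(B0_bpm=60.0, E_basal_uM=0.0)
        assert beat_rate_response(0.0, 0.0, p) == pytest.approx(60.0)

    def test_massive_antagonist_restores_intrinsic_rate(self):
        p = default_pd_params()
        assert beat_rate_response(0.5, 1e9, p) == pytest.approx(p.B0_bpm, rel=1e-4)

    def test_grid_monotonicity(self):
        p = default_pd_params()
        E = np.linspace(0, 5, 20)
        P = np.linspace(0, 20, 20)
        grid = np.array([[beat_rate_response(e, pp, p) for e in E] for pp in P])
        assert np.all(np.diff(grid, axis=1) >= -1e-9)  # increasing in agonist
        assert np.all(np.diff(grid, axis=0) <= 1e-9)   # decreasing in antagonist

    def test_basal_tone_raises_baseline(self):
        with_tone = PDParams(E_basal_uM=0.02)
        without = PDParams(E_basal_uM=0.0)
        assert (beat_rate_response(0, 0, with_tone)
                > beat_rate_response(0, 0, without))


class TestCalibration:
    def test_single_anchor_matches_closed_form_ec50(self):
        # with Rmax, n, Ki, E_basal fixed, the +40% anchor gives
        # EC50 = A * ((Rmax - r) / r)^(1/n) with r = 0.40 and A = 0.5 + E_basal
        fixed = {"Rmax": 0.8, "hill_n": 2.0, "Ki_uM": 0.01, "E_basal_uM": 1e-9}
        anchors = [{"name": "epi", "E_uM": 0.5, "P_uM": 0.0, "target_pct": 40.0}]
        params, report = calibrate_pd_defaults(anchors=anchors, fixed=fixed)
        a = 0.5 + fixed["E_basal_uM"]
        expected = a * ((fixed["Rmax"] - 0.4) / 0.4) ** (1.0 / fixed["hill_n"])
        assert params.EC50_uM == pytest.approx(expected, rel=1e-4)
        assert report["rss"] < 1e-10

    def test_shipped_defaults_hit_reported_percent_changes(self):
        p = default_pd_params()
        base = beat_rate_response(0.0, 0.0, p)
        epi = percent_change(base, beat_rate_response(0.5, 0.0, p))
        prop = percent_change(base, beat_rate_response(0.0, 0.1, p))
        assert epi == pytest.approx(40.0, abs=2.0)
        assert prop == pytest.approx(-10.0, abs=2.0)

    def test_recalibration_reproduces_shipped_anchor_behaviour(self):
        params, report = calibrate_pd_defaults()
        assert report["rss"] < 1e-6
        base = beat_rate_response(0.0, 0.0, params)
        assert percent_change(base, beat_rate_response(0.5, 0.0, params)) == \
            pytest.approx(40.0, abs=0.1)


class TestTwoTissueExperiment:
    def test_cardiac_only_blockade_suppresses_agonist(self):
        proto = ExperimentProtocol(mode="cardiac_only", duration_h=20.0,
                                   events=DUAL_DRUG_EVENTS)
        res = simulate_two_tissue_experiment(proto)
        assert res.ground_truth["markers"]["pct_change_after_epinephrine"] < 10.0

    def test_liver_clearance_restores_agonist_response(self):
        blocked = simulate_two_tissue_experiment(
            ExperimentProtocol(mode="cardiac_only", duration_h=20.0,
                               events=DUAL_DRUG_EVENTS))
        recovered = simulate_two_tissue_experiment(
            ExperimentProtocol(mode="liver_cardiac", duration_h=20.0,
                               events=DUAL_DRUG_EVENTS))
        pct_blocked = blocked.ground_truth["markers"]["pct_change_after_epinephrine"]
        pct_recovered = recovered.ground_truth["markers"]["pct_change_after_epinephrine"]
        assert pct_recovered > pct_blocked

    def test_2d_hepatocytes_match_cardiac_only(self):
        a = simulate_two_tissue_experiment(
            ExperimentProtocol(mode="cardiac_only", duration_h=20.0,
                               events=DUAL_DRUG_EVENTS))
        b = simulate_two_tissue_experiment(
            ExperimentProtocol(mode="hepatocyte_2d", duration_h=20.0,
                               events=DUAL_DRUG_EVENTS))
        np.testing.assert_allclose(a.timeseries["bpm"], b.timeseries["bpm"],
                                   rtol=0.01)

    def test_agonist_is_not_cleared(self):
        proto = ExperimentProtocol(mode="liver_cardiac", duration_h=10.0,
                                   events=[(0.0, "epinephrine", 0.5)])
        res = simulate_two_tissue_experiment(proto)
        e = res.timeseries["E_uM"].to_numpy()
        assert np.all(e[res.timeseries["t_h"] >= 0.0] == pytest.approx(0.5))

    def test_antagonist_decays_only_with_liver(self):
        proto = ExperimentProtocol(mode="liver_cardiac", duration_h=48.0,
                                   events=[(0.0, "propranolol", 0.3)])
        res = simulate_two_tissue_experiment(proto)
        final = res.timeseries["P_uM"].iloc[-1]
        assert final == pytest.approx(0.1, rel=0.01)  # 3-fold drop over 48 h


class TestThreeTissueScenario:
    def test_bleomycin_run_ceases_by_day_nine(self):
        proto = ExperimentProtocol(mode="three_tissue", duration_h=216.0,
                                   events=[(72.0, "bleomycin", 10.0)])
        res = simulate_three_tissue_scenario(proto)
        ts = res.timeseries
        assert bool(ts["ceased"].iloc[-1])
        assert res.ground_truth["cessation_time_h"] <= 216.0

    def test_cardiac_only_is_unaffected(self):
        proto = ExperimentProtocol(mode="cardiac_only", duration_h=216.0,
                                   events=[(72.0, "bleomycin", 10.0)])
        res = simulate_three_tissue_scenario(proto)
        ts = res.timeseries
        assert not ts["ceased"].any()
        base = res.ground_truth["baseline_bpm"]
        assert np.all(np.abs(ts["bpm"] - base) / base < 0.05)
        assert ts["il1b_pg_ml"].max() == 0.0

    def test_cytokines_accumulate_after_exposure_only(self):
        proto = ExperimentProtocol(mode="three_tissue", duration_h=216.0,
                                   events=[(72.0, "bleomycin", 10.0)])
        ts = simulate_three_tissue_scenario(proto).timeseries
        pre = ts[ts["t_h"] <= 72.0]
        post = ts[ts["t_h"] > 96.0]
        assert pre["il8_pg_ml"].max() == 0.0
        assert post["il8_pg_ml"].is_monotonic_increasing
        assert post["il1b_pg_ml"].iloc[-1] > 0

    def test_missing_bleomycin_event_rejected(self):
        proto = ExperimentProtocol(mode="three_tissue", duration_h=216.0, events=[])
        with pytest.raises(ArgumentError):
            simulate_three_tissue_scenario(proto)


class TestCytokineChallenge:
    def test_il1b_pattern_and_magnitude(self):
        series = simulate_cytokine_challenge("il1b")
        as_dict = dict(series)
        assert as_dict[24.0] == pytest.approx(60.0)
        assert as_dict[144.0] < 0.0
        from organchip.pharm import classify_timecourse

        assert classify_timecourse(series) == "increase_then_decrease"

    @pytest.mark.parametrize("arm", ["control", "il8"])
    def test_inert_arms_are_flat(self, arm):
        series = simulate_cytokine_challenge(arm)
        assert all(pct == 0.0 for _, pct in series)

    def test_unknown_cytokine_rejected(self):
        with pytest.raises(ArgumentError):
            simulate_cytokine_challenge("tnf")
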