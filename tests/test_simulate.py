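import re

import numpy as np
import pandas as pd
import pytest

import tempoprep as tp
from tempoprep.design import DEFAULT_BOUNDS
from tempoprep.prep_models import PreparationModel
from tempoprep.simulate import (
    block_distributions,
    read_trial_table,
    simulate_eye_trace,
    write_trial_table,
)


class TestDesignPlan:
    def test_total_trial_count(self):
        plan = tp.build_design(42, 100, seed=1)
        assert len(plan) == 16800

    def test_block_order_regex_b_before_u(self):
        plan = tp.build_design(6, 2, seed=2)
        pattern = re.compile(r"B_(short|long) U_\1 B_(short|long) U_\2")
        for _, sub in plan.groupby("subject_id"):
            order = sub.sort_values("block_order_index")["block_label"].unique()
            assert pattern.fullmatch(" ".join(order))
            assert order[0][2:] != order[2][2:]  # the two pairs use different anchors

    def test_counterbalanced_start_anchor(self):
        plan = tp.build_design(2, 1, seed=3)
        starts = plan[plan["block_order_index"] == 0].groupby("subject_id")[
            "block_label"
        ].first()
        assert sorted(starts) == ["B_long", "B_short"]

    def test_odd_subjects_warns(self):
        with pytest.warns(UserWarning):
            tp.build_design(3, 1, seed=4)

    def test_fp_ranges_per_condition(self):
        plan = tp.build_design(8, 50, seed=5)
        b = plan[plan["block_label"].str.startswith("B")]
        short = b[b["block_label"] == "B_short"]["fp_n"]
        assert short.between(1600 - 15, 1600 + 15).all()  # anchor +- 3 jitter SD
        u = plan[plan["block_label"].str.startswith("U")]["fp_n"]
        assert u.between(*DEFAULT_BOUNDS).all()

    def test_target_side_balanced(self):
        plan = tp.build_design(10, 100, seed=6)
        frac = (plan["target_side"] == "left").mean()
        assert abs(frac - 0.5) < 0.03

    def test_history_columns(self):
        plan = tp.build_design(2, 5, seed=7)
        first = plan[plan["trial_index"] == 1]
        assert first["fp_prev"].isna().all()
        rest = plan[plan["trial_index"] > 1]
        assert rest["fp_prev"].notna().all()
        assert np.allclose(rest["sequence"], rest["fp_prev"] - rest["fp_n"])


class TestLatencies:
    def test_noiseless_latency_equals_model_curve(self):
        plan = tp.build_design(4, 30, seed=8)
        model = PreparationModel("linear_fp", a=300, b=-0.05)
        trials = tp.simulate_latencies(plan, model, subject_sd=0, resid_sd=0, seed=9)
        assert np.allclose(trials["latency"], 300 - 0.05 * trials["fp_n"])

    def test_grand_mean_matches_law_of_total_expectation(self):
        plan = tp.build_design(42, 100, seed=10)
        model = PreparationModel("hr_classic", a=217.924, b=0.371)
        trials = tp.simulate_latencies(plan, model, seed=11)
        u = trials[trials["block_label"] == "U_short"]
        d = block_distributions()["U_short"]
        hrec = tp.hazard_reciprocal(tp.hazard_classic(d))
        _, mass = __import__("tempoprep.hazard", fromlist=["_binned_pmf"])._binned_pmf(d, 50)
        expected = 217.924 + 0.371 * np.sum(mass[mass > 0] * hrec.values)
        # subject and residual noise are zero-mean; SE of the mean ~ 1 ms
        assert abs(u["latency"].mean() - expected) < 6.0

    def test_scalar_noise_sd_ratio(self):
        plan = tp.build_design(20, 200, seed=12)
        model = PreparationModel("scalar_noise", a=250, k=0.1, c=0.0)
        trials = tp.simulate_latencies(plan, model, subject_sd=0, seed=13)
        sd_short = trials[trials["block_label"] == "B_short"]["latency"].std()
        sd_long = trials[trials["block_label"] == "B_long"]["latency"].std()
        assert sd_long / sd_short == pytest.approx(1.5, rel=0.08)  # 240/160

    def test_latency_window_flags(self):
        plan = tp.build_design(2, 50, seed=14)
        model = PreparationModel("linear_fp", a=90, b=0.0)
        trials = tp.simulate_latencies(plan, model, subject_sd=0, resid_sd=30, seed=15)
        assert trials.loc[trials["latency"] < 100, "anticipatory"].all()
        assert (~trials.loc[trials["latency"] >= 100, "anticipatory"]).all()


class TestDropout:
    def test_zero_rate_no_flags(self):
        plan = tp.build_design(2, 10, seed=16)
        out = tp.apply_dropout(plan, 0.0, seed=17)
        assert not out["artifact"].any()

    def test_rate_matches_binomial_expectation(self):
        plan = tp.build_design(42, 100, seed=18)
        out = tp.apply_dropout(plan, 0.0507, seed=19)
        expected = 16800 - 15948  # published artifact loss
        sd = np.sqrt(16800 * 0.0507 * (1 - 0.0507))
        assert abs(out["artifact"].sum() - expected) < 2 * sd

    def test_reproducible_under_seed(self):
        plan = tp.build_design(4, 20, seed=20)
        a = tp.apply_dropout(plan, 0.1, seed=21)
        b = tp.apply_dropout(plan, 0.1, seed=21)
        assert a["artifact"].equals(b["artifact"])

    def test_invalid_rate_rejected(self):
        plan = tp.build_design(2, 2, seed=22)
        with pytest.raises(ValueError):
            tp.apply_dropout(plan, 1.0, seed=23)


class TestEyeTraces:
    def test_event_order_and_fp_geometry(self):
        tr = simulate_eye_trace(1700, 230, "left", seed=24)
        ev = tr.events
        assert ev["fixation_onset"] < ev["pre_fp_onset"] < ev["ws_onset"] < ev["is_onset"]
        assert ev["is_onset"] - ev["ws_onset"] == pytest.approx(1700)
        assert np.all(np.diff(tr.t) > 0)

    def test_clean_trial_lands_in_target_box(self):
        tr = simulate_eye_trace(1600, 250, "right", seed=25)
        assert abs(tr.x[-1] - 9.5) < 1.5 and abs(tr.y[-1]) < 1.5

    def test_blink_trial_has_long_gap(self):
        tr = simulate_eye_trace(1600, 250, "right", seed=26, blink=True)
        gap = np.isnan(tr.x)
        runs = np.diff(np.flatnonzero(np.diff(np.concatenate([[0], gap, [0]]))))
        assert max(runs) * 2.0 >= 100.0  # 2 ms per sample

    def test_fixation_only_trial_stays_at_origin(self):
        tr = simulate_eye_trace(1600, None, "right", seed=27, fixation_only=True)
        assert np.nanmax(np.hypot(tr.x, tr.y)) < 1.0

    def test_trace_roundtrip(self, tmp_path):
        tr = simulate_eye_trace(1600, 250, "right", seed=28)
        tr.to_csv(tmp_path / "trace.csv")
        tr.events_to_json(tmp_path / "trace.json")
        back = tp.EyeTrace.from_csv(tmp_path / "trace.csv", tmp_path / "trace.json")
        assert np.allclose(back.x, tr.x, equal_nan=True)
        assert back.events["is_onset"] == tr.events["is_onset"]


def test_trial_table_roundtrip(tmp_path):
    plan = tp.build_design(2, 5, seed=29)
    path = tmp_path / "trials.csv"
    write_trial_table(plan, path)
    back = read_trial_table(path)
    pd.testing.assert_frame_equal(back, plan, check_dtype=False)
    # write -> read -> write is byte-identical
    path2 = tmp_path / "trials2.csv"
    write_trial_table(back, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_parameter_recovery_smoke():
    """Simulated slope is recovered inside its CI for a single large replicate."""
    rng = np.random.default_rng(30)
    d = tp.make_uncertain(1600, 120)
    rows = []
    for subj in range(1, 21):
        fps = tp.sample_foreperiods(d, 100, rng)
        rows.append(pd.DataFrame({"subject_id": subj, "fp_n": fps}))
    table = pd.concat(rows, ignore_index=True)
    table["latency"] = (
        300.0
        - 0.054 * table["fp_n"]
        + np.repeat(rng.normal(0, 33.6, 20), 100)
        + rng.normal(0, 51.9, len(table))
    )
    res = tp.fit_latency_mixed(table, "fp_n")
    lo, hi = res.slope_ci()
    assert lo < -0.054 < hi
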