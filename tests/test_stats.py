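import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import tempoprep as tp
from tempoprep.stats import (
    SESOI_DZ,
    bin_latency_stats,
    paired_sd_test,
    sd_vs_hazard_regression,
    select_structure,
    tost_coefficient,
    tost_paired,
    weber_slope_analysis,
)


def _linear_table(rng, n_subjects=10, n_trials=80, slope=-0.05, intercept=300,
                  subject_sd=0.0, resid_sd=0.0):
    d = tp.make_uncertain(1600, 120)
    rows = []
    offsets = rng.normal(0, subject_sd, n_subjects) if subject_sd else np.zeros(n_subjects)
    for s in range(n_subjects):
        fps = tp.sample_foreperiods(d, n_trials, rng)
        lat = intercept + slope * fps + offsets[s] + rng.normal(0, resid_sd, n_trials)
        rows.append(pd.DataFrame({"subject_id": s + 1, "fp_n": fps, "latency": lat}))
    return pd.concat(rows, ignore_index=True)


class TestMixedModel:
    def test_noiseless_data_recovers_exact_slope(self):
        table = _linear_table(np.random.default_rng(1))
        res = tp.fit_latency_mixed(table, "fp_n")
        assert res.slope == pytest.approx(-0.05, abs=1e-8)
        assert res.slope_se < 1e-6
        assert res.random_sd["residual"] < 1e-3

    def test_matches_ols_when_no_subject_heterogeneity(self):
        # with zero between-subject variance the mixed fit collapses onto OLS
        rng = np.random.default_rng(2)
        table = _linear_table(rng, subject_sd=0.0, resid_sd=20.0)
        res = tp.fit_latency_mixed(table, "fp_n")
        import statsmodels.api as sm

        ols = sm.OLS(table["latency"], sm.add_constant(table["fp_n"])).fit()
        assert res.slope == pytest.approx(ols.params["fp_n"], abs=5e-4)
        assert res.random_sd["subject"] < 2.0

    def test_hr_generated_data_gives_positive_hrrec_slope(self, clean_trials):
        u = clean_trials[(clean_trials["block_label"] == "U_short") & clean_trials["valid"]]
        res = tp.fit_latency_mixed(u, "hr_rec")
        assert res.slope > 0
        assert res.fixed_effects.loc["hr_rec", "p"] < 0.01

    def test_ci_brackets_estimate_and_random_sds_positive(self, clean_trials):
        u = clean_trials[(clean_trials["block_label"] == "U_long") & clean_trials["valid"]]
        res = tp.fit_latency_mixed(u, "fp_n")
        lo, hi = res.slope_ci()
        assert lo < res.slope < hi
        assert res.random_sd["residual"] > 0
        assert np.isfinite(res.bic)
        assert "fp_n" in res.summary()

    def test_history_predictors_drop_first_trials(self, clean_trials):
        u = clean_trials[(clean_trials["block_label"] == "U_short") & clean_trials["valid"]]
        res = tp.fit_latency_mixed(u, "sequence")
        assert res.n_obs == u["sequence"].notna().sum()
        assert res.metadata["sequence_convention"] == "sequence = fp_prev - fp_n"

    def test_unknown_predictor_rejected(self, clean_trials):
        with pytest.raises(ValueError):
            tp.fit_latency_mixed(clean_trials, "block_label")

    def test_matches_lme4_oracle(self, tmp_path):
        """Independent oracle: the same model fitted by lme4 through Rscript."""
        rng = np.random.default_rng(3)
        table = _linear_table(rng, n_subjects=8, n_trials=40, subject_sd=30, resid_sd=50)
        csv = tmp_path / "d.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(latency ~ fp_n + (1 | subject_id), data = d, REML = TRUE)
            cat(fixef(m)[["fp_n"]], sigma(m), sqrt(unlist(VarCorr(m))[[1]]), sep = "\\n")
        """))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        r_slope, r_sigma, r_subj = (float(v) for v in out.stdout.split())
        res = tp.fit_latency_mixed(table, "fp_n")
        assert res.slope == pytest.approx(r_slope, rel=1e-4)
        assert res.random_sd["residual"] == pytest.approx(r_sigma, rel=1e-3)
        assert res.random_sd["subject"] == pytest.approx(r_subj, rel=1e-2)


class TestStructureSelection:
    def test_main_only_preferred_without_trial_drift(self):
        rng = np.random.default_rng(4)
        table = _linear_table(rng, subject_sd=30, resid_sd=50)
        table["trial_index"] = np.tile(np.arange(1, 81), 10)
        sel = select_structure(table, "fp_n")
        assert sel.chosen_fixed == "main"
        assert sel.chosen_random == "rs1"

    def test_ledger_contains_all_candidates_once(self):
        rng = np.random.default_rng(5)
        table = _linear_table(rng, subject_sd=30, resid_sd=50)
        sel = select_structure(table, "fp_n")
        random_rows = sel.ledger[sel.ledger["stage"] == "random"]
        assert sorted(random_rows["candidate"]) == ["rs1", "rs2", "rs3", "rs4"]
        assert not random_rows["candidate"].duplicated().any()

    def test_zero_heterogeneity_still_estimable(self):
        rng = np.random.default_rng(6)
        table = _linear_table(rng, subject_sd=0.0, resid_sd=40.0)
        res = tp.fit_latency_mixed(table, "fp_n")
        assert res.random_sd["subject"] < 5.0


class TestBinnedLM:
    def test_exact_linear_bin_means_give_r2_one(self):
        # foreperiods placed exactly at bin centers so bin means are exactly linear
        rng = np.random.default_rng(7)
        centers = np.arange(1275.0, 2750.0, 50.0)
        fps = rng.choice(centers, size=2000)
        table = pd.DataFrame(
            {"subject_id": rng.integers(1, 6, 2000), "fp_n": fps,
             "latency": 300.0 - 0.05 * fps}
        )
        r = tp.fit_latency_lm_binned(table, "FPn")
        assert r.adj_r2 == pytest.approx(1.0, abs=1e-9)
        assert r.slope == pytest.approx(-0.05, abs=1e-9)

    def test_hr_generated_data_negative_fpn_slope(self, clean_trials):
        u = clean_trials[(clean_trials["block_label"] == "U_short") & clean_trials["valid"]]
        r = tp.fit_latency_lm_binned(u, "FPn")
        assert r.slope < 0

    def test_permuted_bins_kill_the_slope(self):
        rng = np.random.default_rng(8)
        table = _linear_table(rng, resid_sd=20.0)
        ps = []
        for _ in range(20):
            shuffled = table.copy()
            shuffled["latency"] = rng.permutation(shuffled["latency"].to_numpy())
            ps.append(tp.fit_latency_lm_binned(shuffled, "FPn").p)
        assert np.mean(ps) > 0.2  # uniform p-values under the permutation null

    def test_too_few_bins_rejected(self):
        table = pd.DataFrame(
            {"subject_id": [1, 1, 2, 2], "fp_n": [1600, 1600, 1610, 1610],
             "latency": [250, 260, 255, 252]}
        )
        with pytest.raises(ValueError):
            tp.fit_latency_lm_binned(table, "FPn")


class TestWeberSlope:
    def test_inverts_scalar_noise_generator(self):
        rng = np.random.default_rng(9)
        fps = np.arange(1275.0, 2750.0, 50.0)
        variances = [
            rng.normal(0, np.sqrt(0.01 * f**2 + 900), 4000).var(ddof=1) for f in fps
        ]
        r = weber_slope_analysis(fps, variances)
        assert r.k_squared == pytest.approx(0.01, rel=0.15)
        assert r.weber_obeyed

    def test_constant_sd_not_scalar(self):
        rng = np.random.default_rng(10)
        fps = np.arange(1275.0, 2750.0, 50.0)
        variances = [rng.normal(0, 50, 2000).var(ddof=1) for _ in fps]
        r = weber_slope_analysis(fps, variances)
        assert abs(r.k_squared) < 1e-3
        assert r.p > 0.01

    def test_decreasing_sd_rejects_webers_law(self, u_long):
        # SD mapped affinely down from the classic hazard, as observed empirically
        rng = np.random.default_rng(11)
        h = tp.hazard_classic(u_long)
        keep = h.values < 1  # drop the terminal bin for a smooth map
        sds = 80.0 - 23.0 * h.values[keep]
        variances = [rng.normal(0, sd, 2000).var(ddof=1) for sd in sds]
        r = weber_slope_analysis(h.support[keep], variances)
        assert r.k_squared < 0
        assert not r.weber_obeyed

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            weber_slope_analysis([1300, 1400], [100, 120, 130])


class TestSDRegressions:
    def test_recovers_affine_sd_hazard_map(self, u_short):
        h = tp.hazard_classic(u_short)
        sd = 80.0 - 23.0 * h.values
        r = sd_vs_hazard_regression(sd, h.values)
        assert r.slope == pytest.approx(-23.0, abs=1e-9)
        assert r.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_sd_gives_zero_slope(self, u_short):
        h = tp.hazard_classic(u_short)
        r = sd_vs_hazard_regression(np.full_like(h.values, 60.0), h.values)
        assert abs(r.slope) < 1e-9

    def test_misaligned_bins_rejected(self, u_short):
        h = tp.hazard_classic(u_short)
        with pytest.raises(ValueError):
            sd_vs_hazard_regression(np.ones(3), h.values)


class TestPairedSD:
    def test_identical_vectors_give_t_zero(self):
        a = np.array([50.0, 60.0, 55.0, 52.0])
        with pytest.raises(ValueError):
            paired_sd_test(a, a)  # zero-variance differences: t undefined

    def test_null_data_rarely_significant(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(200):
            a = rng.normal(50, 5, 42)
            b = rng.normal(50, 5, 42)
            t, df, p = paired_sd_test(a, b)
            assert df == 41
            hits += abs(t) > sps.t.ppf(0.975, 41)
        assert hits / 200 < 0.12  # ~5% nominal

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            paired_sd_test([1.0, 2.0], [2.0, 1.0])


class TestTOST:
    def test_null_diffs_accept_equivalence(self):
        rng = np.random.default_rng(13)
        r = tost_paired(rng.normal(0, 1, 42), SESOI_DZ)
        assert r.equivalent
        assert r.bounds == (-SESOI_DZ, SESOI_DZ)
        assert r.ci[0] > -SESOI_DZ and r.ci[1] < SESOI_DZ

    def test_zero_bounds_never_equivalent(self):
        rng = np.random.default_rng(14)
        r = tost_paired(rng.normal(0, 1, 42), 0.0)
        assert not r.equivalent

    def test_p_value_matches_simulation_oracle(self):
        # brute-force oracle: the upper one-sided p is the probability, under
        # a true standardized effect exactly at the bound, of observing a
        # d_z*sqrt(n) at most as large as the one seen
        rng = np.random.default_rng(15)
        d = rng.normal(0.55, 1.0, 30)  # effect near the bound: p well off the tails
        n, sesoi = len(d), 0.8
        ours = tost_paired(d, sesoi)
        sims = rng.normal(sesoi, 1.0, size=(100_000, n))
        t_sim = sims.mean(axis=1) / sims.std(axis=1, ddof=1) * np.sqrt(n)
        p_mc = np.mean(t_sim <= ours.t_upper)
        se = np.sqrt(ours.p_upper * (1 - ours.p_upper) / 1e5)
        assert ours.p_upper == pytest.approx(p_mc, abs=3 * se)

    def test_agrees_with_pingouin_on_large_samples(self):
        # with n large the central-t raw-bound procedure (pingouin) and the
        # noncentral-t standardized-bound procedure converge
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(150)
        d = rng.normal(0.1, 1.0, 2000)
        sesoi = 0.2
        ours = tost_paired(d, sesoi)
        theirs = pg.tost(d, y=0, bound=sesoi * d.std(ddof=1))
        assert ours.p == pytest.approx(float(theirs["pval"].iloc[0]), abs=0.01)

    def test_widening_bounds_is_monotone(self):
        rng = np.random.default_rng(16)
        d = rng.normal(0.5, 1.0, 30)
        flags = [tost_paired(d, s).equivalent for s in (0.2, 0.6, 1.0, 1.5)]
        assert flags == sorted(flags)  # once equivalent, stays equivalent

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            tost_paired(np.ones(10), 0.5)


class TestTOSTCoefficient:
    @staticmethod
    def _fit(rng, slope):
        table = _linear_table(rng, n_subjects=20, n_trials=100, slope=slope,
                              subject_sd=30, resid_sd=50)
        return tp.fit_latency_mixed(table, "fp_n")

    def test_null_coefficient_is_equivalent(self):
        res = self._fit(np.random.default_rng(17), slope=0.0)
        r = tost_coefficient(res, sesoi_f2=0.09)
        assert r.equivalent
        assert r.effect_size_type == "cohen_f2"

    def test_large_effect_not_equivalent(self):
        res = self._fit(np.random.default_rng(18), slope=-0.3)
        r = tost_coefficient(res, sesoi_f2=0.02)
        assert not r.equivalent

    def test_bound_widening_monotone(self):
        res = self._fit(np.random.default_rng(19), slope=-0.05)
        flags = [tost_coefficient(res, s).equivalent for s in (0.001, 0.01, 0.09, 0.5)]
        assert flags == sorted(flags)


def test_bin_latency_stats_counts(clean_trials):
    u = clean_trials[(clean_trials["block_label"] == "U_short") & clean_trials["valid"]]
    b = bin_latency_stats(u)
    assert b["n"].sum() <= len(u)
    assert (b["n"] >= 2).all()
    assert set(["fp_bin", "mean", "sd", "var"]).issubset(b.columns)


def test_family_diagnostics_report_all_families(clean_trials):
    u = clean_trials[(clean_trials["block_label"] == "U_short") & clean_trials["valid"]]
    diag = tp.stats.family_residual_diagnostics(u)
    assert len(diag) == 4
    assert np.isfinite(diag["skewness"]).all()
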