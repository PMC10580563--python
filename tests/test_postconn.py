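import numpy as np
import pandas as pd
import pytest

import neuropda as npd
from neuropda import postconn
from neuropda.bold_sim import AcquisitionParams, MotionTrace, Run4D

from conftest import make_records


def quiet_run(phantom, n_volumes=250, seed=0, **sig_kwargs):
    sig = npd.SignalSpec(seed=seed, **sig_kwargs)
    acq = AcquisitionParams(n_volumes=n_volumes,
                            baseline_volumes=min(25, n_volumes - 1))
    return npd.simulate_run(phantom, acq, sig)


class TestCleanRun:
    def test_zero_motion_noiseless_run_cleans_to_near_zero(self, phantom, templates):
        run = quiet_run(phantom, seed=1, noise_sd=0.0, dmn_amplitude=0,
                        fpn_amplitude=0, drift_slope=0.02)
        run = Run4D(data=run.data, params=run.params,
                    motion=MotionTrace(params=np.zeros((250, 6))),
                    affine=run.affine)
        cleaned, censor = postconn.clean_run(run, templates["WM"],
                                             templates["CSF"],
                                             templates["whole_brain"])
        assert not censor.any()
        assert np.abs(cleaned.data.mean(axis=3)).max() < 1e-8

    def test_wm_principal_component_confound_removed(self, phantom, templates):
        # the confound IS the dominant WM principal component: WM carries it
        # noise-free, gray matter carries it plus noise.  aCompCor recovers
        # it exactly, so regression strips all of it from gray matter.
        rng = np.random.default_rng(2)
        run = quiet_run(phantom, seed=2, noise_sd=0.0, dmn_amplitude=0,
                        fpn_amplitude=0)
        confound = rng.standard_normal(250)
        gray = templates["whole_brain"] & ~templates["WM"] & ~templates["CSF"]
        data = run.data.copy()
        data[templates["WM"]] += 3.0 * confound
        data[gray] += 1.0 * confound
        data[gray] += rng.standard_normal((int(gray.sum()), 250))
        run = run.copy_with(data)
        params = postconn.CleaningParams(bandpass_hz=(1e-4, 0.41))
        before = np.corrcoef(run.data[gray].mean(axis=0), confound)[0, 1]
        cleaned, _ = postconn.clean_run(run, templates["WM"], templates["CSF"],
                                        templates["whole_brain"], params)
        after = np.corrcoef(cleaned.data[gray].mean(axis=0), confound)[0, 1]
        assert before > 0.9
        assert abs(after) < 0.02  # residual is filter edge leakage only

    def test_gsr_attenuates_planted_global_signal(self, phantom, templates):
        rng = np.random.default_rng(3)
        run = quiet_run(phantom, seed=3, noise_sd=0.5, dmn_amplitude=0,
                        fpn_amplitude=0)
        global_sig = rng.standard_normal(250)
        data = run.data.copy()
        # plant the shared signal in gray matter only, out of aCompCor's
        # reach, so only the GSR column can remove it
        gray = templates["whole_brain"] & ~templates["WM"] & ~templates["CSF"]
        data[gray] += 2.0 * global_sig
        run = run.copy_with(data)
        out = {}
        for gsr in (False, True):
            params = postconn.CleaningParams(gsr=gsr, bandpass_hz=(1e-4, 0.41))
            cleaned, _ = postconn.clean_run(run, templates["WM"],
                                            templates["CSF"],
                                            templates["whole_brain"], params)
            series = cleaned.data[templates["mPFC"]].mean(axis=0)
            out[gsr] = abs(np.corrcoef(series, global_sig)[0, 1])
        assert out[True] < 0.2
        assert out[True] < out[False] / 2

    def test_high_motion_volumes_censored(self, phantom, templates):
        run = quiet_run(phantom, seed=4, outlier_volumes=frozenset({100}),
                        motion_spike_mm=2.0)
        _, censor = postconn.clean_run(run, templates["WM"], templates["CSF"],
                                       templates["whole_brain"])
        assert censor[100]

    def test_too_few_volumes_rejected(self, phantom, templates):
        run = quiet_run(phantom, n_volumes=20, seed=5)
        with pytest.raises(ValueError, match="design"):
            postconn.clean_run(run, templates["WM"], templates["CSF"],
                               templates["whole_brain"])


class TestRoiConnectivity:
    def _run_from_series(self, a, b, phantom, templates):
        n = len(a)
        data = np.zeros(phantom.grid_shape + (n,))
        data[templates["mPFC"]] = a
        data[templates["PCC"]] = b
        return Run4D(data=data,
                     params=AcquisitionParams(n_volumes=n, baseline_volumes=0),
                     motion=MotionTrace(params=np.zeros((n, 6))))

    def test_scaled_series_give_r_one_with_finite_fisher_z(self, phantom,
                                                           templates):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(100)
        run = self._run_from_series(a, 2.0 * a, phantom, templates)
        out = postconn.roi_connectivity(run, templates["mPFC"], templates["PCC"])
        assert out["r"] == pytest.approx(1.0)
        assert np.isfinite(out["fisher_z"])

    def test_independent_noise_rois_near_zero(self, phantom, templates):
        rng = np.random.default_rng(1)
        run = self._run_from_series(rng.standard_normal(250),
                                    rng.standard_normal(250),
                                    phantom, templates)
        out = postconn.roi_connectivity(run, templates["mPFC"], templates["PCC"])
        assert abs(out["r"]) < 0.2

    def test_small_personalized_roi_substituted_by_template(self, phantom,
                                                            templates):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(60)
        run = self._run_from_series(a, a + rng.standard_normal(60), phantom,
                                    templates)
        small = np.zeros_like(templates["mPFC"])
        idx = np.argwhere(templates["mPFC"])[:150]
        small[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        out = postconn.roi_connectivity(run, small, templates["PCC"],
                                        template_a=templates["mPFC"])
        assert out["substituted"] == ["roi_a"]

    def test_censored_volumes_excluded(self, phantom, templates):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(100)
        run = self._run_from_series(a, a, phantom, templates)
        censor = np.zeros(100, bool)
        censor[:30] = True
        out = postconn.roi_connectivity(run, templates["mPFC"],
                                        templates["PCC"], censor=censor)
        assert out["n_volumes_used"] == 70

    def test_constant_series_rejected(self, phantom, templates):
        run = self._run_from_series(np.ones(50), np.ones(50), phantom, templates)
        with pytest.raises(ValueError, match="constant"):
            postconn.roi_connectivity(run, templates["mPFC"], templates["PCC"])


def test_fisher_z_monotone_and_always_finite():
    rs = np.linspace(-1, 1, 41)
    zs = [postconn.fisher_z(r) for r in rs]
    assert all(np.isfinite(zs))
    assert all(a < b for a, b in zip(zs, zs[1:]))
    assert postconn.fisher_z(0.0) == 0.0


class TestPrimaryModel:
    def test_time_effect_recovered(self):
        recs = make_records(n=76, effect=-0.2, seed=10)
        fit = postconn.fit_primary_model(recs)
        c = fit.coef("time")
        assert c["estimate"] == pytest.approx(-0.2, abs=0.06)
        assert c["estimate"] < 0 and c["p"] < 0.05
        assert c["ci_low"] < c["estimate"] < c["ci_high"]

    def test_random_structure_chosen_by_aic(self):
        # strong per-subject slope variance should favor the random slope
        recs = make_records(n=60, effect=-0.2, slope_sd=0.3, res_sd=0.05, seed=11)
        fit = postconn.fit_primary_model(recs)
        assert fit.aic_slope < fit.aic_intercept
        assert fit.random_structure == "intercept+slope"

    def test_degenerate_identical_records_flagged_not_fatal(self):
        rows = []
        for i in range(4):
            for t in (0, 0, 1, 1):
                rows.append(dict(id=f"s{i}", time=t, fisher_z=0.5,
                                 mean_fd=0.1, age=15.0))
        fit = postconn.fit_primary_model(pd.DataFrame(rows))
        assert fit.fallback_used or fit.notes

    def test_insufficient_participants_rejected(self):
        recs = make_records(n=1)
        with pytest.raises(ValueError):
            postconn.fit_primary_model(recs)

    def test_outlier_triggers_robust_estimation(self):
        recs = make_records(n=40, effect=-0.2, seed=12)
        fit = postconn.fit_primary_model(recs)
        assert not fit.robust_used
        recs.loc[0, "fisher_z"] = 10.0  # gross outlier, > 3 SD from mean
        fit2 = postconn.fit_primary_model(recs)
        assert fit2.robust_used


class TestDoseModel:
    def test_interaction_sign_recovered(self):
        recs = make_records(n=60, effect=-0.05, dose_extra=-0.15, seed=20)
        fit = postconn.fit_dose_model(recs)
        c = fit.coef("dose:time")
        assert c["estimate"] < 0
        assert c["ci_low"] <= -0.15 <= c["ci_high"]

    def test_single_dose_dataset_rejected(self):
        recs = make_records(n=20, seed=21)
        recs["dose"] = 0
        with pytest.raises(ValueError, match="dose"):
            postconn.fit_dose_model(recs)

    def test_sensitivity_variant_drops_dose_main_effect(self):
        recs = make_records(n=40, dose_extra=-0.15, seed=22)
        fit = postconn.fit_dose_model(recs, include_dose_main=False)
        assert "dose:time" in fit.params.index
        assert "dose" not in fit.params.index


class TestBenjaminiHochberg:
    def test_all_ones_reject_nothing(self):
        assert not postconn.bh_adjust([1.0, 1.0, 1.0]).any()

    def test_matches_brute_force_step_up(self):
        def brute(p, alpha=0.05):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p)
            k_star = 0
            for k in range(1, m + 1):
                if p[order[k - 1]] <= alpha * k / m:
                    k_star = k
            rej = np.zeros(m, bool)
            rej[order[:k_star]] = True
            return rej
        cases = [[0.001, 0.02, 0.03, 0.9], [0.04, 0.04, 0.04, 0.04],
                 [0.9, 0.8, 0.7], [0.012, 0.051, 0.049]]
        rng = np.random.default_rng(0)
        cases += [rng.uniform(size=7).tolist() for _ in range(20)]
        for p in cases:
            assert np.array_equal(postconn.bh_adjust(p), brute(p)), p

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = rng.uniform(size=9)
            ours = postconn.bh_adjust(p)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(ours, ref)

    def test_families_partition_applied_separately(self):
        # protocol families: 4 depression tests and 3 rumination tests
        p = [0.001, 0.02, 0.03, 0.9, 0.01, 0.04, 0.5]
        fam = [[0, 1, 2, 3], [4, 5, 6]]
        rej = postconn.bh_adjust(p, families=fam)
        lone = postconn.bh_adjust(p[:4])
        assert np.array_equal(rej[:4], lone)

    def test_null_simulation_controls_fdr(self):
        rng = np.random.default_rng(2)
        fdr = []
        for _ in range(1000):
            p = rng.uniform(size=7)
            rej = postconn.bh_adjust(p)
            fdr.append(rej.any())  # all nulls: any rejection is a false one
        assert np.mean(fdr) <= 0.05 + 0.02

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            postconn.bh_adjust([0.5, 1.2])


class TestMnarSensitivity:
    def test_complete_data_gives_identity_row(self):
        recs = make_records(n=30, seed=30)
        tbl = postconn.mnar_sensitivity(recs)
        assert len(tbl) == 1
        assert tbl.iloc[0]["replaced"] == 0
        fit = postconn.fit_primary_model(recs)
        assert tbl.iloc[0]["estimate"] == pytest.approx(
            fit.coef("time")["estimate"])

    def test_zero_shift_equals_mean_imputation(self):
        recs = make_records(n=30, seed=31)
        recs.loc[recs.sample(12, random_state=0).index, "fisher_z"] = np.nan
        tbl = postconn.mnar_sensitivity(recs, shift_grid=np.array([0.0]))
        mean_imp = recs.copy()
        mean_imp["fisher_z"] = mean_imp["fisher_z"].fillna(
            recs["fisher_z"].mean())
        direct = postconn.fit_primary_model(mean_imp)
        assert tbl.iloc[0]["estimate"] == pytest.approx(
            direct.coef("time")["estimate"], abs=1e-10)

    def test_estimates_move_monotonically_when_missing_in_one_arm(self):
        recs = make_records(n=40, effect=-0.2, seed=32)
        post = recs[recs["time"] == 1].index
        recs.loc[post[:20], "fisher_z"] = np.nan  # missing concentrated post
        tbl = postconn.mnar_sensitivity(recs,
                                        shift_grid=np.linspace(-2, 2, 5))
        est = tbl["estimate"].to_numpy()
        assert np.all(np.diff(est) > 0)  # higher replacement -> weaker drop


class TestItemImpute:
    def test_complete_rows_are_plain_sums(self):
        items = pd.DataFrame(np.ones((3, 13)))
        assert (postconn.item_impute(items) == 13).all()

    def test_ten_percent_rule(self):
        row_ok = [1.0] * 12 + [np.nan]       # 1/13 = 7.7% -> impute
        row_bad = [1.0] * 11 + [np.nan] * 2  # 2/13 = 15.4% -> missing
        items = pd.DataFrame([row_ok, row_bad])
        scores = postconn.item_impute(items)
        assert scores[0] == pytest.approx(13.0)  # person mean 1.0 imputed
        assert np.isnan(scores[1])

    def test_all_missing_row_scores_missing(self):
        items = pd.DataFrame([[np.nan] * 5])
        assert np.isnan(postconn.item_impute(items)[0])


class TestEndToEndRecords:
    def test_session_records_reflect_planted_connectivity_drop(self, phantom):
        scen = npd.ScenarioSpec(mpfc_pcc_corr_pre=0.7, mpfc_pcc_corr_post=0.4)
        log = npd.run_session(phantom, "min15", scenario=scen, seed=9)
        recs = postconn.records_from_sessions([log], phantom, ages=[15.0])
        assert len(recs) == 4
        assert set(recs["time"]) == {0, 1}
        pre = recs[recs["time"] == 0]["fisher_z"].mean()
        post = recs[recs["time"] == 1]["fisher_z"].mean()
        assert pre > post
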