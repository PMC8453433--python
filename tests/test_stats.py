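import numpy as np
import pandas as pd
import pytest

from prelesion import normalize, rois, stats
from prelesion.cohort import PhantomConfig, generate_ms_subject
from prelesion.lesions import find_lesion_events
from prelesion.pipeline import RunConfig, analyse_subject
from prelesion.stats import (
    adjust_multiplicity,
    build_sample_table,
    fit_weighted_lmm,
    ls_means,
    simulate_lmm_data,
)

EFFECTS = {-24: -0.2, -20: -0.2, -16: -0.2, -12: -0.2, -8: -0.2}


def dense_covariance(blocks, n, sp2, sl2, s2, rho):
    """Brute-force marginal covariance over all rows."""
    V = np.zeros((n, n))
    for rows, sizes, lag, w in zip(
        blocks.patient_rows, blocks.lesion_sizes, blocks.lags, blocks.weights
    ):
        V[np.ix_(rows, rows)] += sp2
        pos = 0
        for size in sizes:
            rr = rows[pos : pos + size]
            t = lag[pos : pos + size]
            V[np.ix_(rr, rr)] += sl2 + (s2 / w) * rho ** np.abs(
                t[:, None] - t[None, :]
            )
            pos += size
    return V


class TestRemlLikelihood:
    @pytest.mark.parametrize(
        "params",
        [
            (0.31, 0.12, 0.05, 0.4),
            (0.05, 0.5, 0.2, -0.3),
            (1.0, 1e-4, 0.01, 0.0),
        ],
    )
    def test_matches_dense_mvn_oracle(self, params):
        df = simulate_lmm_data(6, EFFECTS, mean_lesions=2, seed=4)
        df, blocks = stats.make_blocks_for_oracle(df)
        X, _ = stats.build_design_for_oracle(df)
        y = df["value"].to_numpy()
        n, p = X.shape
        sp2, sl2, s2, rho = params
        V = dense_covariance(blocks, n, sp2, sl2, s2, rho)
        Vi = np.linalg.inv(V)
        XtVX = X.T @ Vi @ X
        beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
        r = y - X @ beta
        ll_oracle = -0.5 * (
            (n - p) * np.log(2 * np.pi)
            + np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(XtVX)[1]
            + float(r @ Vi @ r)
        )
        ll = stats.reml_loglik(y, X, blocks, sp2, sl2, s2, rho)
        assert ll == pytest.approx(ll_oracle, abs=1e-8)


class TestFit:
    def test_degenerate_limit_equals_wls(self):
        # data with iid errors and balanced visits: beta from the mixed
        # model matches plain weighted least squares
        df = simulate_lmm_data(
            20, EFFECTS, mean_lesions=2, sigma_p=0.0, sigma_l=0.0,
            sigma=0.3, rho=0.0, seed=8,
        )
        fit = fit_weighted_lmm(df)
        X, _ = stats.build_design_for_oracle(df.sort_values(
            ["subject_id", "lesion_id", "week"]).reset_index(drop=True))
        dfs = df.sort_values(["subject_id", "lesion_id", "week"]).reset_index(
            drop=True
        )
        w = dfs["weight"].to_numpy()
        y = dfs["value"].to_numpy()
        wls = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        np.testing.assert_allclose(fit.beta, wls, atol=1e-6)

    def test_parameter_recovery_single_large_fit(self):
        truth = dict(sigma_p=0.4, sigma_l=0.3, sigma=0.2, rho=0.6)
        df = simulate_lmm_data(120, EFFECTS, mean_lesions=2, seed=21, **truth)
        fit = fit_weighted_lmm(df)
        assert fit.sigma_p2 == pytest.approx(truth["sigma_p"] ** 2, rel=0.5)
        assert fit.sigma_l2 == pytest.approx(truth["sigma_l"] ** 2, rel=0.5)
        assert fit.rho == pytest.approx(truth["rho"], abs=0.15)
        np.testing.assert_allclose(fit.beta[:5], -0.2, atol=0.12)

    def test_fitted_residual_correlation_decreases_with_gap(self):
        df = simulate_lmm_data(60, EFFECTS, rho=0.6, seed=5)
        fit = fit_weighted_lmm(df)
        R = fit.residual_correlation(5)
        gaps = np.abs(np.subtract.outer(np.arange(5), np.arange(5)))
        for g in range(1, 4):
            assert R[0, g + 1] < R[0, g]
        assert np.all(np.diag(R) == 1.0)
        assert R.shape == tuple([5, 5]) and gaps.max() == 4

    def test_weight_rescaling_leaves_beta_unchanged(self):
        df = simulate_lmm_data(25, EFFECTS, seed=10)
        fit1 = fit_weighted_lmm(df)
        df2 = df.copy()
        df2["weight"] = df2["weight"] * 7.5
        fit2 = fit_weighted_lmm(df2)
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-4)
        lsm1 = ls_means(fit1)["estimate"].to_numpy()
        lsm2 = ls_means(fit2)["estimate"].to_numpy()
        np.testing.assert_allclose(lsm1, lsm2, atol=1e-4)

    def test_duplicating_lesions_with_halved_weight_keeps_grand_mean(self):
        df = simulate_lmm_data(10, EFFECTS, seed=12)
        target = df[df["subject_id"] == "s000"]
        dup = target.copy()
        dup["lesion_id"] = dup["lesion_id"] + "-dup"
        out = pd.concat([df, dup], ignore_index=True)
        out.loc[out["subject_id"] == "s000", "weight"] /= 2.0
        gm1 = np.average(df["value"], weights=df["weight"])
        gm2 = np.average(out["value"], weights=out["weight"])
        assert gm1 == pytest.approx(gm2, abs=1e-12)

    def test_collinear_covariates_named_in_error(self):
        df = simulate_lmm_data(6, EFFECTS, seed=3)
        df["a"] = df["weight"] * 2.0
        df["b"] = df["a"]
        with pytest.raises(ValueError, match="collinear"):
            fit_weighted_lmm(df, covariates=("a", "b"))

    def test_too_few_time_levels_error(self):
        df = simulate_lmm_data(6, {-8: 0.0}, seed=3)
        with pytest.raises(ValueError, match="time levels"):
            fit_weighted_lmm(df)


class TestLsMeans:
    def test_degenerate_model_level_means(self):
        df = simulate_lmm_data(
            40, {-8: 0.3, -4: 0.3}, sigma_p=0.0, sigma_l=0.0, sigma=0.05,
            rho=0.0, seed=6,
        )
        fit = fit_weighted_lmm(df)
        lsm = ls_means(fit)
        for _, row in lsm.iterrows():
            sub = df[df["weeks_before_onset"] == row["level"]]
            expected = np.average(sub["value"], weights=sub["weight"])
            assert row["estimate"] == pytest.approx(expected, abs=1e-6)

    def test_absent_level_is_error(self):
        df = simulate_lmm_data(6, EFFECTS, seed=3)
        fit = fit_weighted_lmm(df)
        with pytest.raises(ValueError, match="absent"):
            ls_means(fit, time_levels=(-999,))

    def test_known_simulation_within_ci(self):
        df = simulate_lmm_data(80, EFFECTS, seed=14)
        fit = fit_weighted_lmm(df)
        lsm = ls_means(fit)
        for _, row in lsm.iterrows():
            assert abs(row["estimate"] - (-0.2)) < 4 * row["se"]

    def test_covariate_fill_values(self):
        df = simulate_lmm_data(30, EFFECTS, seed=15)
        rng = np.random.default_rng(0)
        subs = sorted(df["subject_id"].unique())
        age = {s: rng.uniform(25, 55) for s in subs}
        sex = {s: ("F" if rng.random() < 0.5 else "M") for s in subs}
        df["age"] = df["subject_id"].map(age)
        df["sex"] = df["subject_id"].map(sex)
        fit = fit_weighted_lmm(df, covariates=("age", "sex", "age:sex"))
        design = fit.design
        w = df.sort_values(["subject_id", "lesion_id", "week"])["weight"]
        a = df.sort_values(["subject_id", "lesion_id", "week"])["age"]
        assert design.lsmean_fill["age"] == pytest.approx(
            np.average(a, weights=w)
        )
        assert design.lsmean_fill["sex[M]"] == pytest.approx(0.5)
        lsm = ls_means(fit)
        assert len(lsm) == 5


class TestMultiplicity:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_multiplicity([0.03]), [0.03])

    def test_bonferroni_definition(self):
        np.testing.assert_allclose(
            adjust_multiplicity([0.01, 0.04], method="bonferroni"),
            [0.02, 0.08],
        )

    def test_holm_dominates_bonferroni(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 8)
        holm = adjust_multiplicity(p, method="holm")
        bonf = adjust_multiplicity(p, method="bonferroni")
        assert np.all(holm <= bonf + 1e-12)
        assert np.all(holm >= p - 1e-12)
        assert np.all(holm <= 1.0)

    def test_invalid_p_error(self):
        with pytest.raises(ValueError, match="0, 1"):
            adjust_multiplicity([0.5, 1.2])


@pytest.fixture(scope="module")
def analysis():
    cfg = PhantomConfig(
        noise_sd=0.0, lesion_rate=0.5, seed=1, prelesion_delta_nmtr=0.2,
        prelesion_delta_nt2=0.3,
    )
    sub = generate_ms_subject(cfg, "scanner00", seed=7)
    sub.covariates = {"age": 40.0, "sex": "F", "treatment_group": "active"}
    from prelesion.cohort import generate_healthy_control

    hc = generate_healthy_control(cfg, "scanner00", seed=5)
    cal = normalize.calibrate_mtr_from_series(hc)
    run_cfg = RunConfig(phantom=cfg)
    return analyse_subject(sub, cal, run_cfg)


class TestSampleTable:
    def test_injected_noiseless_contrast_values(self, analysis):
        table = build_sample_table([analysis], exclude_final_interval=True)
        nt2 = table[table["channel"] == "nt2"]
        pvo = nt2[nt2["contrast"] == "pre_vs_overall"]["value"]
        pvc = nt2[nt2["contrast"] == "pre_vs_contra"]["value"]
        cvo = nt2[nt2["contrast"] == "contra_vs_overall"]["value"]
        np.testing.assert_allclose(pvo, 0.3, atol=1e-6)
        np.testing.assert_allclose(pvc, 0.3, atol=1e-6)
        np.testing.assert_allclose(cvo, 0.0, atol=1e-6)

    def test_nmtr_contrast_not_exact_with_gradient_but_close(self, analysis):
        # the periventricular gradient perturbs pre_vs_overall for nMTR;
        # pre_vs_contra controls it exactly by mirror symmetry
        table = build_sample_table([analysis], exclude_final_interval=True)
        nmtr = table[table["channel"] == "nmtr"]
        pvc = nmtr[nmtr["contrast"] == "pre_vs_contra"]["value"]
        np.testing.assert_allclose(pvc, -0.2, atol=1e-9)

    def test_weights_inverse_of_accepted_lesion_count(self, analysis):
        table = build_sample_table([analysis], exclude_final_interval=True)
        n_acc = sum(p.accepted for p in analysis.pairs)
        assert n_acc >= 1
        np.testing.assert_allclose(table["weight"], 1.0 / n_acc)

    def test_final_interval_visit_excluded(self, analysis):
        table = build_sample_table([analysis], exclude_final_interval=True)
        assert (table["weeks_before_onset"] != -4).all()
        table2 = build_sample_table([analysis], exclude_final_interval=False)
        assert (table2["weeks_before_onset"] == -4).any()

    def test_constant_volume_gives_zero_contrasts(self, analysis):
        import copy

        an = copy.deepcopy(analysis)
        an.normalized = {
            "nmtr": [np.full(v.shape, 3.14) for v in an.normalized["nmtr"]]
        }
        table = build_sample_table([an], exclude_final_interval=True)
        np.testing.assert_allclose(table["value"], 0.0, atol=1e-12)
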