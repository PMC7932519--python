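"""Multilevel lagged estimation: likelihood internals, oracle
cross-checks, ladder behaviour, and network assembly."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import esmnet as en
from esmnet.estimate import (
    ModelSpec, EstimationError, fit_lagged_model, _tridiag_inverse_pieces,
    _design_arrays, _build_blocks, _ProfiledML, _ladder,
)
from esmnet.preprocess import LAG_COLS
from esmnet.simulate import NODES


@pytest.fixture(scope="module")
def no_re_design():
    """Cohort generated with zero random effects and no missingness."""
    cfg = en.stable_config(
        n_families=15, observe="continuous", missing_rate=0.0,
        person_sd=(0.0,) * 6, family_sd=(0.0,) * 6, slope_sd=0.0)
    panel, _, truth = en.simulate_cohort([cfg], seed=31)
    design, _ = en.make_lag_design(panel)
    return design, truth["Stable"]


@pytest.fixture(scope="module")
def re_design():
    """Default-dynamics cohort (random effects, missingness, Likert)."""
    panel, meta, truth = en.simulate_cohort(
        [en.stable_config(n_families=15)], seed=32)
    kept, _ = en.filter_by_missingness(panel, scheduled_beeps=60)
    design, _ = en.make_lag_design(kept)
    return design, truth["Stable"]


class TestTridiagonalAR1Inverse:
    @pytest.mark.parametrize("phi", [0.1, 0.5, 0.9])
    def test_matches_dense_inverse(self, phi):
        rng = np.random.default_rng(0)
        gaps = np.full(12, np.nan)
        gaps[1:6] = rng.uniform(0.5, 3.0, 5)     # person 1: rows 0-5
        gaps[7:] = rng.uniform(0.5, 3.0, 5)      # person 2: rows 6-11
        diag, off, logdet = _tridiag_inverse_pieces(gaps, phi)
        r = np.array([0.0 if np.isnan(g) else phi ** g for g in gaps])
        R = np.eye(12)
        for i in range(12):
            prod = 1.0
            for j in range(i + 1, 12):
                prod *= r[j]
                R[i, j] = R[j, i] = prod
        Rinv = np.diag(diag)
        Rinv += np.diag(off, 1) + np.diag(off, -1)
        np.testing.assert_allclose(Rinv, np.linalg.inv(R), atol=1e-10)
        assert logdet == pytest.approx(np.linalg.slogdet(R)[1], abs=1e-10)


class TestDegenerateLimit:
    def test_fixed_effects_match_pooled_ols(self, no_re_design):
        design, B = no_re_design
        fit = fit_lagged_model(design, ModelSpec("down"))
        X = np.column_stack([
            np.ones(len(design)),
            design[LAG_COLS].to_numpy(),
            design["time"].to_numpy() / 60.0,
        ])
        ols = sm.OLS(design["y_down"].to_numpy(), X).fit()
        np.testing.assert_allclose(
            fit.coef[LAG_COLS].to_numpy(), ols.params[1:7], atol=1e-2)

    def test_recovers_known_row_within_tolerance(self, no_re_design):
        design, B = no_re_design
        fit = fit_lagged_model(design, ModelSpec("cheerful"))
        dev = np.abs(fit.coef[LAG_COLS].to_numpy() - B[0])
        assert dev.mean() < 0.05


class TestMixedModelCrossCheck:
    def test_intercept_only_rung_matches_statsmodels_mixedlm(self, re_design):
        design, _ = re_design
        spec = ModelSpec("down", ar1=False, random_slopes=False,
                         family_intercept=False, aic_select=False)
        fit = fit_lagged_model(design, spec)
        df = design.copy()
        df["time_scaled"] = df["time"] / spec.scheduled_beeps
        md = sm.MixedLM.from_formula(
            "y_down ~ " + " + ".join(LAG_COLS) + " + time_scaled",
            groups="person_id", data=df)
        res = md.fit(reml=False)
        ours = fit.coef[LAG_COLS].to_numpy()
        theirs = np.array([res.params[c] for c in LAG_COLS])
        np.testing.assert_allclose(ours, theirs, atol=2e-3)
        assert fit.varcomps["person_intercept"] == pytest.approx(
            float(res.cov_re.iloc[0, 0]), rel=0.05, abs=5e-3)

    def test_loglik_matches_statsmodels(self, re_design):
        design, _ = re_design
        spec = ModelSpec("down", ar1=False, random_slopes=False,
                         family_intercept=False, aic_select=False)
        fit = fit_lagged_model(design, spec)
        df = design.copy()
        df["time_scaled"] = df["time"] / spec.scheduled_beeps
        md = sm.MixedLM.from_formula(
            "y_down ~ " + " + ".join(LAG_COLS) + " + time_scaled",
            groups="person_id", data=df)
        res = md.fit(reml=False)
        assert fit.loglik == pytest.approx(float(res.llf), abs=0.05)


class TestNlmeOracle:
    def test_full_model_matches_r_nlme(self, tmp_path):
        """The full fit (diagonal random effects, continuous AR(1)
        residuals, ML) must agree with an independent R nlme::lme fit."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable for the nlme cross-check")
        panel, _, _ = en.simulate_cohort(
            [en.stable_config(n_families=8, resid_phi=0.25)], seed=55)
        kept, _ = en.filter_by_missingness(panel, scheduled_beeps=60)
        design, _ = en.make_lag_design(kept)
        fit = fit_lagged_model(design, ModelSpec("down", aic_select=False))

        df = design.copy()
        df["time_scaled"] = df["time"] / 60.0
        df["time_hr"] = df["time_min"] / 60.0
        df.to_csv(tmp_path / "fixture.csv", index=False)
        lags = " + ".join(LAG_COLS)
        rscript = f"""
        suppressMessages(library(nlme))
        d <- read.csv("fixture.csv")
        d$person_id <- factor(d$person_id); d$family_id <- factor(d$family_id)
        m <- lme(y_down ~ {lags} + time_scaled, data = d,
                 random = list(family_id = pdIdent(~1),
                               person_id = pdDiag(~ {lags} + time_scaled)),
                 correlation = corCAR1(form = ~ time_hr | family_id/person_id),
                 method = "ML",
                 control = lmeControl(maxIter=200, msMaxIter=200,
                                      niterEM=50, returnObject=TRUE))
        co <- fixef(m)
        cat(paste(co, collapse=","), "\\n")
        cat(as.numeric(logLik(m)), "\\n")
        cat(coef(m$modelStruct$corStruct, unconstrained=FALSE), "\\n")
        """
        (tmp_path / "check.R").write_text(rscript)
        out = subprocess.run(["Rscript", "check.R"], cwd=tmp_path,
                             capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        lines = [ln for ln in out.stdout.strip().splitlines() if ln.strip()]
        r_coef = np.array([float(v) for v in lines[-3].split(",")])
        r_loglik = float(lines[-2])
        r_phi = float(lines[-1])
        np.testing.assert_allclose(fit.coef[LAG_COLS].to_numpy(),
                                   r_coef[1:7], atol=1e-3)
        assert fit.loglik == pytest.approx(r_loglik, abs=0.02)
        assert fit.phi == pytest.approx(r_phi, abs=5e-3)


class TestLadder:
    def test_full_spec_builds_five_rungs(self):
        names = [n for n, _ in _ladder(ModelSpec("down"))]
        assert names == ["full", "no_ar1", "no_slopes", "no_family", "pooled"]

    def test_aic_selection_prefers_simpler_model_when_phi_absent(self, re_design):
        design, _ = re_design
        chosen = fit_lagged_model(design, ModelSpec("cheerful", aic_select=True))
        full = fit_lagged_model(design, ModelSpec("cheerful", aic_select=False))
        no_ar1 = fit_lagged_model(
            design, ModelSpec("cheerful", ar1=False, aic_select=False))
        best = min([full, no_ar1], key=lambda f: f.aic)
        assert chosen.rung == best.rung
        assert chosen.aic == pytest.approx(best.aic, abs=0.5)

    def test_pooled_rung_has_cluster_robust_errors(self, re_design):
        design, _ = re_design
        spec = ModelSpec("down", ar1=False, random_slopes=False,
                         family_intercept=False, person_intercept=False)
        fit = fit_lagged_model(design, spec)
        assert fit.rung == "pooled"
        assert fit.converged and (fit.se[LAG_COLS] > 0).all()

    def test_too_few_rows_raises(self):
        panel, _, _ = en.simulate_cohort(
            [en.stable_config(n_families=2, n_days=1, beeps_per_day=3,
                              missing_rate=0.0)], seed=0)
        design, _ = en.make_lag_design(panel)
        with pytest.raises(EstimationError):
            fit_lagged_model(design, ModelSpec("down"))


class TestErrorPaths:
    def test_duplicated_predictor_is_singular(self, re_design):
        design, _ = re_design
        broken = design.copy()
        broken["lag_relaxed"] = broken["lag_cheerful"]
        with pytest.raises(EstimationError, match="lag_"):
            fit_lagged_model(broken, ModelSpec("down"))

    def test_constant_predictor_named(self, re_design):
        design, _ = re_design
        broken = design.copy()
        broken["lag_lonely"] = 0.0
        with pytest.raises(EstimationError, match="lag_lonely"):
            fit_lagged_model(broken, ModelSpec("down"))

    def test_missing_cells_rejected(self, re_design):
        design, _ = re_design
        broken = design.copy()
        broken.loc[broken.index[0], "lag_down"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_lagged_model(broken, ModelSpec("down"))

    def test_empty_group_rejected(self, re_design):
        design, _ = re_design
        with pytest.raises(EstimationError, match="no rows"):
            en.estimate_group_network(design, group_label="ghost", persons=[])


class TestSignificantSubnetwork:
    def test_all_p_one_zeroes_everything(self):
        net = en.AffectNetwork(nodes=NODES, weights=np.full((6, 6), 0.3),
                               se=np.ones((6, 6)), pvalues=np.ones((6, 6)))
        filt = en.significant_subnetwork(net)
        assert np.all(filt.weights == 0.0)
        assert np.all(filt.unfiltered == 0.3)

    def test_all_p_zero_keeps_everything(self):
        W = np.random.default_rng(0).normal(size=(6, 6))
        net = en.AffectNetwork(nodes=NODES, weights=W, se=np.ones((6, 6)),
                               pvalues=np.zeros((6, 6)))
        filt = en.significant_subnetwork(net)
        np.testing.assert_array_equal(filt.weights, W)

    def test_random_p_matches_thresholding_oracle(self):
        rng = np.random.default_rng(1)
        W = rng.normal(size=(6, 6))
        P = rng.random((6, 6))
        net = en.AffectNetwork(nodes=NODES, weights=W, se=np.ones((6, 6)),
                               pvalues=P)
        filt = en.significant_subnetwork(net, alpha=0.3)
        np.testing.assert_array_equal(filt.weights, np.where(P < 0.3, W, 0.0))


class TestFastTier:
    def test_level_shift_leaves_fast_coefficients_unchanged(self, no_re_design):
        design, _ = no_re_design
        pid = design["person_id"].iloc[0]
        shifted = design.copy()
        mask = shifted["person_id"] == pid
        for n in NODES:                          # shift that person's outcomes
            shifted.loc[mask, f"y_{n}"] += 0.7
        a = en.fast_group_network(design, group_label="g")
        b = en.fast_group_network(shifted, group_label="g")
        np.testing.assert_allclose(a.weights, b.weights, atol=1e-10)

    def test_level_shift_barely_moves_full_fit(self, no_re_design):
        design, _ = no_re_design
        pid = design["person_id"].iloc[0]
        shifted = design.copy()
        mask = shifted["person_id"] == pid
        for n in NODES:
            shifted.loc[mask, f"y_{n}"] += 0.7
        a = fit_lagged_model(design, ModelSpec("down", aic_select=False))
        b = fit_lagged_model(shifted, ModelSpec("down", aic_select=False))
        np.testing.assert_allclose(a.coef[LAG_COLS].to_numpy(),
                                   b.coef[LAG_COLS].to_numpy(), atol=5e-3)

    def test_fast_and_full_agree_without_random_effects(self, no_re_design):
        # elementwise agreement is Op(1/sqrt(n_persons)) at this cohort
        # size; the tighter 0.02 check on metric differences at larger n
        # lives in the comparison tests
        design, _ = no_re_design
        fast = en.fast_group_network(design, group_label="g")
        full = en.estimate_group_network(design, group_label="g", tier="full")
        np.testing.assert_allclose(fast.weights, full.weights, atol=0.08)

    def test_persons_below_min_rows_skipped(self, no_re_design):
        design, _ = no_re_design
        coefs = en.person_coefficient_matrices(design, min_rows=10**6)
        assert coefs == {}


class TestNetworkAssembly:
    def test_network_orientation_and_shapes(self, no_re_design):
        design, B = no_re_design
        net = en.estimate_group_network(design, group_label="Stable",
                                        tier="fast")
        assert net.weights.shape == (6, 6)
        # strongest recovered entries should sit where truth is strongest
        j, k = np.unravel_index(np.argmax(np.abs(B)), B.shape)
        assert abs(net.weights[j, k] - B[j, k]) < 0.1

    def test_edge_list_round_trip(self, no_re_design):
        design, _ = no_re_design
        net = en.estimate_group_network(design, group_label="g", tier="fast")
        edges = net.edge_list(alpha=0.05)
        assert len(edges) == 36
        row = edges[(edges["from"] == "down") & (edges["to"] == "cheerful")]
        assert row["b"].iloc[0] == pytest.approx(
            net.weights[0, IDX_DOWN], abs=1e-12)

    def test_dot_export_styles_by_sign(self):
        W = np.zeros((6, 6))
        W[1, 0], W[4, 0] = 0.3, -0.2
        net = en.AffectNetwork(nodes=NODES, weights=W, se=np.ones((6, 6)),
                               pvalues=np.zeros((6, 6)))
        dot = net.to_dot()
        assert '"cheerful" -> "relaxed" [style=solid' in dot
        assert '"cheerful" -> "down" [style=dashed' in dot


IDX_DOWN = NODES.index("down")
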