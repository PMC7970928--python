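"""Per-pass evaluation and the pass-outcome statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from pitchspace import (
    MotionParams,
    NormalFit,
    PassEvent,
    SimConfig,
    ValidationError,
    bayes_sigmoid_from_normals,
    empirical_success_curve,
    evaluate_pass,
    filter_pre_shot,
    fit_class_normals,
    fit_sigmoid,
    gen_labeled_z1,
    gen_outcome_passes,
    gen_pass_with_tracking,
    team_min_arrival,
    z_transform,
)
from pitchspace.errors import NumericalError
from pitchspace.formation import r_tilde
from pitchspace.pass_stats import PassFeature

from conftest import player, two_team_snapshot


def snapshot_with_keepers(home_xy, away_xy, possession="home"):
    """Ad-hoc snapshot with 10 outfield players plus a goalkeeper per side."""
    snap = two_team_snapshot(home_xy, away_xy, possession=possession)
    snap.players.append(player(-50.0, 0.0, team="home", pid="gk_h", gk=True))
    snap.players.append(player(50.0, 0.0, team="away", pid="gk_a", gk=True))
    return snap


def frame(z1, q, **extra):
    return pd.DataFrame({"z1": z1, "q": q, **extra})


def log_likelihood(a, b, z1, q):
    p = expit(a * z1 + b)
    return np.sum(q * np.log(p) + (1 - q) * np.log1p(-p))


def grid_search_mle(z1, q, half_width=6.0, n_grid=41, n_zoom=8):
    """Zooming grid-search maximiser of the logistic log-likelihood (oracle)."""
    a0, b0, w = 0.0, 0.0, half_width
    for _ in range(n_zoom):
        a_grid = np.linspace(a0 - w, a0 + w, n_grid)
        b_grid = np.linspace(b0 - w, b0 + w, n_grid)
        ll = np.array([[log_likelihood(a, b, z1, q) for b in b_grid] for a in a_grid])
        ia, ib = np.unravel_index(np.argmax(ll), ll.shape)
        a0, b0 = a_grid[ia], b_grid[ib]
        w *= 2.5 / (n_grid - 1) * 2  # keep a couple of grid cells of slack
    return a0, b0


def full_pass_fixture(seed=21):
    cfg = SimConfig(seed=seed)
    rng = cfg.rng()
    return cfg, gen_pass_with_tracking(cfg, rng)


class TestEvaluatePass:
    def test_offense_player_on_end_point(self, params):
        snap = snapshot_with_keepers(
            [(5.0, 5.0)] + [(-20.0, 0.0)] * 9,
            [(15.0, 5.0)] + [(20.0, 0.0)] * 9,
        )
        event = PassEvent(t_o=0.0, x_o=(0, 0), t_e=1.0, x_e=(5.0, 5.0), q=1, possession="home")
        feat = evaluate_pass(event, snap, params)
        assert feat.z1 > 0 and feat.z1 == pytest.approx(feat.z2)

    def test_defense_player_on_end_point(self, params):
        snap = snapshot_with_keepers(
            [(-15.0, 5.0)] + [(-20.0, 0.0)] * 9,
            [(5.0, 5.0)] + [(20.0, 0.0)] * 9,
        )
        event = PassEvent(t_o=0.0, x_o=(0, 0), t_e=1.0, x_e=(5.0, 5.0), q=0, possession="home")
        feat = evaluate_pass(event, snap, params)
        assert feat.z1 < 0 <= feat.z2

    def test_composes_public_calls(self, params):
        _, (snap, event) = full_pass_fixture()
        feat = evaluate_pass(event, snap, params)
        tau_of = team_min_arrival(snap, event.possession, event.x_e, params)
        tau_df = team_min_arrival(
            snap, "home" if event.possession == "away" else "away", event.x_e, params
        )
        z1, z2 = z_transform(tau_of, tau_df)
        assert feat.z1 == pytest.approx(z1, abs=1e-12)
        assert feat.z2 == pytest.approx(z2, abs=1e-12)
        assert feat.r_tilde == pytest.approx(r_tilde(event, snap), abs=1e-12)
        assert feat.q == event.q and feat.pre_shot == event.pre_shot

    def test_snapshot_time_mismatch(self, params):
        _, (snap, event) = full_pass_fixture()
        snap.time += 1.0
        with pytest.raises(ValidationError, match="snapshot"):
            evaluate_pass(event, snap, params)

    def test_possession_conflict(self, params):
        _, (snap, event) = full_pass_fixture()
        event.possession = "home" if snap.possession == "away" else "away"
        with pytest.raises(ValidationError, match="disagrees"):
            evaluate_pass(event, snap, params)


class TestFitClassNormals:
    def test_two_point_class(self):
        df = frame([0.0, 2.0, -1.0, 1.0], [1, 1, 0, 0])
        fit = fit_class_normals(df)
        assert fit.mu1 == pytest.approx(1.0) and fit.sigma1 == pytest.approx(1.0)
        assert fit.mu0 == pytest.approx(0.0) and fit.sigma0 == pytest.approx(1.0)
        assert (fit.n1, fit.n0) == (2, 2)

    def test_recovers_published_class_parameters(self):
        # large draw at the published class normals lands within 3 SE
        cfg = SimConfig(seed=8, n_passes=100000, prior1=0.5)
        z1, q = gen_labeled_z1(cfg, cfg.rng())
        fit = fit_class_normals(frame(z1, q))
        n1, n0 = fit.n1, fit.n0
        assert abs(fit.mu1 - 0.69) < 3 * 0.54 / np.sqrt(n1)
        assert abs(fit.sigma1 - 0.54) < 3 * 0.54 / np.sqrt(2 * n1)
        assert abs(fit.mu0 - (-0.25)) < 3 * 0.38 / np.sqrt(n0)
        assert abs(fit.sigma0 - 0.38) < 3 * 0.38 / np.sqrt(2 * n0)

    def test_matches_classwise_brute_force(self, rng):
        z1 = rng.normal(0, 1, 500)
        q = rng.integers(0, 2, 500)
        fit = fit_class_normals(frame(z1, q))
        assert fit.mu1 == pytest.approx(z1[q == 1].mean())
        assert fit.sigma0 == pytest.approx(z1[q == 0].std(ddof=0))

    def test_small_class_names_the_class(self):
        with pytest.raises(ValidationError, match="q=0"):
            fit_class_normals(frame([0.0, 1.0, 2.0, 0.5], [1, 1, 1, 0]))

    def test_zero_variance_class(self):
        with pytest.raises(ValidationError, match="variance"):
            fit_class_normals(frame([1.0, 1.0, 0.0, 0.5], [1, 1, 0, 0]))


class TestEmpiricalSuccessCurve:
    def test_all_successes(self):
        df = frame(np.linspace(-1, 1, 50), np.ones(50, dtype=int))
        curve = empirical_success_curve(df, bin_width=0.5, min_count=1)
        assert (curve["success_fraction"] == 1.0).all()

    def test_direct_counts(self):
        df = frame([0.01, 0.02, 0.03, 0.61, 0.62], [1, 1, 0, 0, 0])
        curve = empirical_success_curve(df, bin_width=0.1, min_count=1)
        np.testing.assert_allclose(curve["success_fraction"], [2 / 3, 0.0])
        np.testing.assert_allclose(curve["z1_bin_center"], [0.05, 0.65])

    def test_min_count_filters_bins(self):
        df = frame([0.01, 0.02, 0.61], [1, 0, 1])
        curve = empirical_success_curve(df, bin_width=0.1, min_count=2)
        assert len(curve) == 1 and curve["n"].iloc[0] == 2

    def test_fractions_track_generating_sigmoid(self):
        # binned fractions stay inside binomial 95% bands of the generator
        cfg = SimConfig(seed=17, n_passes=50000)
        feats = gen_outcome_passes(cfg, cfg.rng())
        curve = empirical_success_curve(feats, bin_width=0.1, min_count=100)
        p_true = expit(cfg.a * curve["z1_bin_center"].to_numpy() + cfg.b)
        n = curve["n"].to_numpy()
        band = 1.96 * np.sqrt(p_true * (1 - p_true) / n)
        inside = np.abs(curve["success_fraction"].to_numpy() - p_true) <= band + 1e-12
        assert inside.mean() >= 0.9

    def test_empty_input_raises(self):
        with pytest.raises(ValidationError):
            empirical_success_curve(frame([], []), 0.1, 1)


class TestFitSigmoid:
    def test_null_model(self, rng):
        # outcomes independent of z1: slope ~ 0, intercept ~ logit(p)
        n = 20000
        z1 = rng.uniform(-2, 3, n)
        q = (rng.random(n) < 0.7).astype(int)
        fit = fit_sigmoid(frame(z1, q))
        assert abs(fit.a) < 3 * fit.se_a
        assert abs(fit.b - np.log(0.7 / 0.3)) < 3 * fit.se_b

    def test_tiny_dataset_matches_grid_search(self):
        # both outcomes present at each z value, so the MLE is finite; the
        # saturated solution is a = log(2)/2, b = -log(2)/2
        z1 = np.array([-1.0, -1.0, -1.0, 1.0, 1.0])
        q = np.array([0, 0, 1, 1, 0])
        fit = fit_sigmoid(frame(z1, q))
        a_star, b_star = grid_search_mle(z1, q)
        assert fit.a == pytest.approx(a_star, abs=1e-4)
        assert fit.b == pytest.approx(b_star, abs=1e-4)

    def test_local_optimum_on_coarse_grid(self, rng):
        z1 = rng.uniform(-2, 3, 2000)
        q = (rng.random(2000) < expit(2.0 * z1 - 0.5)).astype(int)
        fit = fit_sigmoid(frame(z1, q))
        best = log_likelihood(fit.a, fit.b, z1, q)
        for da in np.linspace(-0.5, 0.5, 5):
            for db in np.linspace(-0.5, 0.5, 5):
                assert best >= log_likelihood(fit.a + da, fit.b + db, z1, q) - 1e-9

    def test_positive_slope_predicts_monotone_success(self, rng):
        z1 = rng.uniform(-2, 3, 5000)
        q = (rng.random(5000) < expit(3.0 * z1)).astype(int)
        fit = fit_sigmoid(frame(z1, q))
        grid = np.linspace(-3, 3, 50)
        assert np.all(np.diff(fit.predict(grid)) > 0)

    def test_perfect_separation_raises(self):
        df = frame([-2.0, -1.0, 1.0, 2.0], [0, 0, 1, 1])
        with pytest.raises(NumericalError, match="separation"):
            fit_sigmoid(df)

    def test_single_class_raises(self):
        with pytest.raises(ValidationError, match="classes"):
            fit_sigmoid(frame([0.0, 1.0], [1, 1]))

    def test_binned_route_agrees_roughly_with_mle(self):
        cfg = SimConfig(seed=3, n_passes=50000)
        feats = gen_outcome_passes(cfg, cfg.rng())
        mle = fit_sigmoid(feats)
        binned = fit_sigmoid(feats, method="binned")
        assert binned.a == pytest.approx(mle.a, rel=0.1)
        assert binned.b == pytest.approx(mle.b, abs=0.15)

    def test_recovers_generating_coefficients_across_replicates(self):
        # reduced version of the recovery sweep: most replicates within 3 SE
        master = np.random.default_rng(99)
        hits = 0
        for _ in range(10):
            a_true = master.uniform(0.5, 8.0)
            b_true = master.uniform(-2.0, 2.0)
            z1 = master.uniform(-2, 3, 20000)
            q = (master.random(20000) < expit(a_true * z1 + b_true)).astype(int)
            fit = fit_sigmoid(frame(z1, q))
            if abs(fit.a - a_true) < 3 * fit.se_a and abs(fit.b - b_true) < 3 * fit.se_b:
                hits += 1
        assert hits >= 9


class TestBayesSigmoid:
    def test_symmetric_closed_form(self):
        fit = NormalFit(mu1=1.0, sigma1=1.0, mu0=-1.0, sigma0=1.0, n1=10, n0=10)
        bayes = bayes_sigmoid_from_normals(fit, prior1=0.5)
        assert bayes.applicable
        assert bayes.a == pytest.approx(2.0) and bayes.b == pytest.approx(0.0)
        assert bayes.posterior(0.0) == pytest.approx(0.5)

    def test_equal_sigma_matches_logistic_mle(self):
        # data generated from equal-sigma class normals: the closed form and
        # the fitted logistic estimate the same posterior
        rng = np.random.default_rng(4)
        n = 100000
        prior1 = 0.6
        q = (rng.random(n) < prior1).astype(int)
        z1 = rng.normal(np.where(q == 1, 0.7, -0.3), 0.5)
        logistic = fit_sigmoid(frame(z1, q))
        normals = fit_class_normals(frame(z1, q))
        pooled = np.sqrt((normals.n1 * normals.sigma1**2 + normals.n0 * normals.sigma0**2)
                         / (normals.n1 + normals.n0))
        eq = NormalFit(mu1=normals.mu1, sigma1=pooled, mu0=normals.mu0, sigma0=pooled,
                       n1=normals.n1, n0=normals.n0)
        bayes = bayes_sigmoid_from_normals(eq)
        assert bayes.applicable
        assert abs(bayes.a - logistic.a) < 3 * logistic.se_a
        assert abs(bayes.b - logistic.b) < 3 * logistic.se_b

    def test_published_unequal_sigmas_flagged(self):
        # the published class sigmas differ, so the pure reduction is refused
        fit = NormalFit(mu1=0.69, sigma1=0.54, mu0=-0.25, sigma0=0.38, n1=100, n0=50)
        bayes = bayes_sigmoid_from_normals(fit)
        assert not bayes.applicable
        assert bayes.a is None and "quadratic" in bayes.note
        assert 0.0 < bayes.posterior(0.0) < 1.0

    def test_quadratic_posterior_matches_direct_bayes(self):
        fit = NormalFit(mu1=0.69, sigma1=0.54, mu0=-0.25, sigma0=0.38, n1=60, n0=40)
        bayes = bayes_sigmoid_from_normals(fit)
        from scipy.stats import norm

        z = np.linspace(-2, 2, 9)
        num = norm.pdf(z, 0.69, 0.54) * 0.6
        den = num + norm.pdf(z, -0.25, 0.38) * 0.4
        np.testing.assert_allclose(bayes.posterior(z), num / den, atol=1e-12)

    def test_bad_prior_raises(self):
        fit = NormalFit(mu1=1.0, sigma1=1.0, mu0=0.0, sigma0=1.0, n1=5, n0=5)
        with pytest.raises(ValidationError):
            bayes_sigmoid_from_normals(fit, prior1=1.0)


class TestFilterPreShot:
    def test_counts_and_empty(self):
        feats = [
            PassFeature(z1=0.0, z2=1.0, r_tilde=1.0, q=1, pre_shot=(i % 3 == 0))
            for i in range(9)
        ]
        assert len(filter_pre_shot(feats)) == 3
        assert filter_pre_shot([f for f in feats if not f.pre_shot]) == []

    def test_dataframe_route(self):
        df = frame([0.0, 1.0, 2.0], [1, 0, 1], pre_shot=[1, 0, 1])
        assert len(filter_pre_shot(df)) == 2
        with pytest.raises(ValidationError, match="pre_shot"):
            filter_pre_shot(frame([0.0], [1]))

    def test_pre_shot_class_shifts_fitted_mean_down(self, rng):
        # construct pre-shot passes with a lower generating mean
        z_all = rng.normal(0.69, 0.5, 4000)
        z_pre = rng.normal(0.0, 0.5, 1000)
        feats = [PassFeature(z1=float(z), z2=abs(z) + 1, r_tilde=1.0, q=1) for z in z_all]
        feats += [
            PassFeature(z1=float(z), z2=abs(z) + 1, r_tilde=1.0, q=1, pre_shot=True)
            for z in z_pre
        ]
        feats += [PassFeature(z1=-0.2, z2=1.0, r_tilde=1.0, q=0)] * 50  # failures for the fit
        all_fit = fit_class_normals(feats)
        pre = filter_pre_shot(feats)
        pre_mean = np.mean([f.z1 for f in pre])
        assert pre_mean < all_fit.mu1
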