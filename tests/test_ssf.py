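import numpy as np
import pandas as pd
import pytest
import scipy.stats

import oracles
from conftest import make_trajectory
from lfmove.errors import DegenerateFitError, NonIdentifiableError, ValidationError
from lfmove.ssf import (
    GammaFit,
    annotate_choice_sets,
    fit_conditional_logistic,
    fit_gamma,
    fit_poisson_reformulation,
    generate_choice_sets,
    log_rss,
    rss,
    rss_interval,
    summary_table,
)


def simulate_choice_data(rng, n_strata, beta, n_alt=11, n_animals=1, p_x=0.3, covariate="road_cross"):
    """Direct discrete-choice simulation: used step drawn with prob ~ exp(beta*x)."""
    rows = []
    for s in range(n_strata):
        x = rng.random(n_alt) < p_x
        w = np.exp(beta * x)
        used_idx = rng.choice(n_alt, p=w / w.sum())
        for j in range(n_alt):
            rows.append(
                {
                    "stratum_id": f"s{s:05d}",
                    "animal_id": f"a{s % n_animals}",
                    "used": int(j == used_idx),
                    covariate: int(x[j]),
                }
            )
    return pd.DataFrame(rows)


class TestFitGamma:
    def test_parameter_recovery(self, rng):
        x = rng.gamma(2.0, 10.0, 10_000)
        fit = fit_gamma(x)
        assert fit.shape == pytest.approx(2.0, rel=0.05)
        assert fit.scale == pytest.approx(10.0, rel=0.05)

    def test_constant_lengths_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_gamma([5.0] * 10)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            fit_gamma([1.0, 2.0, -1.0, 3.0, 4.0])

    def test_too_few(self):
        with pytest.raises(ValidationError):
            fit_gamma([1.0, 2.0])

    def test_mle_matches_sample_mean(self, rng):
        x = rng.lognormal(2.0, 0.6, 500)
        fit = fit_gamma(x)
        assert fit.mean == pytest.approx(x.mean(), rel=0.01)


class TestGenerateChoiceSets:
    @pytest.fixture
    def traj12(self, rng):
        return make_trajectory(np.cumsum(rng.uniform(2, 10, (12, 2)), axis=0))

    def test_stratum_and_row_counts(self, traj12):
        sets = generate_choice_sets(traj12, GammaFit(2.0, 10.0), n_random=10, seed=0)
        # 12 unique locations -> 11 movement steps -> 10 strata (first step excluded)
        assert sets["stratum_id"].nunique() == 10
        assert sets.groupby("stratum_id").size().eq(11).all()
        assert sets.groupby("stratum_id")["used"].sum().eq(1).all()

    def test_deterministic_given_seed(self, traj12):
        a = generate_choice_sets(traj12, GammaFit(2.0, 10.0), seed=7)
        b = generate_choice_sets(traj12, GammaFit(2.0, 10.0), seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_random_steps_share_realized_start(self, traj12):
        sets = generate_choice_sets(traj12, GammaFit(2.0, 10.0), seed=0)
        for _, g in sets.groupby("stratum_id"):
            assert g["start_x"].nunique() == 1 and g["start_y"].nunique() == 1

    def test_too_short_trajectory_warns_empty(self):
        traj = make_trajectory([(0, 0), (10, 0)])
        with pytest.warns(UserWarning):
            sets = generate_choice_sets(traj, GammaFit(2.0, 10.0))
        assert len(sets) == 0

    def test_random_lengths_match_generating_gamma(self, rng):
        traj = make_trajectory(np.cumsum(rng.uniform(2, 10, (200, 2)), axis=0))
        fit = GammaFit(1.5, 20.0)
        sets = generate_choice_sets(traj, fit, n_random=10, seed=1)
        avail = sets[sets["used"] == 0]
        lengths = np.hypot(avail["end_x"] - avail["start_x"], avail["end_y"] - avail["start_y"])
        p = scipy.stats.kstest(lengths, scipy.stats.gamma(fit.shape, scale=fit.scale).cdf).pvalue
        assert p > 0.01


class TestAnnotateChoiceSets:
    def step_frame(self, segments):
        rows = []
        for i, (s, e) in enumerate(segments):
            rows.append(
                {
                    "stratum_id": f"s{i}",
                    "animal_id": "a",
                    "sex": "F",
                    "year": 2020,
                    "used": 1,
                    "start_x": s[0],
                    "start_y": s[1],
                    "end_x": e[0],
                    "end_y": e[1],
                }
            )
        return pd.DataFrame(rows)

    def test_step_outside_all_features(self, toy_landscape):
        out = annotate_choice_sets(self.step_frame([((30, 60), (40, 60))]), toy_landscape)
        assert out[["road_cross", "trail_cross", "end_in_powerline", "end_in_buffer"]].sum().sum() == 0

    def test_end_in_buffer_without_crossing(self, toy_landscape):
        # ends 3 m outside the road footprint edge (x=12): inside the 5 m buffer
        out = annotate_choice_sets(self.step_frame([((40, 20), (15, 20))]), toy_landscape)
        row = out.iloc[0]
        assert (row["road_cross"], row["trail_cross"]) == (0, 0)
        assert (row["end_in_powerline"], row["end_in_buffer"]) == (0, 1)

    def test_crossing_step(self, toy_landscape):
        out = annotate_choice_sets(self.step_frame([((5, 20), (20, 20))]), toy_landscape)
        assert out.iloc[0]["road_cross"] == 1

    def test_invariant_to_stratum_relabeling(self, toy_landscape, rng):
        segs = [((a, b), (c, d)) for a, b, c, d in rng.uniform(0, 100, (20, 4))]
        base = self.step_frame(segs)
        relabeled = base.assign(stratum_id=base["stratum_id"].str.replace("s", "zz"))
        a = annotate_choice_sets(base, toy_landscape)
        b = annotate_choice_sets(relabeled, toy_landscape)
        cols = ["road_cross", "trail_cross", "end_in_powerline", "end_in_buffer"]
        pd.testing.assert_frame_equal(a[cols], b[cols])


SIX_STRATA = pd.DataFrame(
    {
        "stratum_id": np.repeat([f"s{i}" for i in range(6)], 3),
        "animal_id": "a",
        "used": [1, 0, 0, 0, 1, 0, 1, 0, 0, 0, 0, 1, 1, 0, 0, 0, 1, 0],
        "road_cross": [1, 0, 0, 0, 1, 1, 0, 1, 0, 1, 0, 0, 1, 1, 0, 0, 0, 1],
    }
)


class TestFitConditionalLogistic:
    def test_matches_grid_search_oracle(self):
        fit = fit_conditional_logistic(SIX_STRATA, covariates=("road_cross",))
        X = SIX_STRATA["road_cross"].to_numpy().reshape(6, 3)
        used = np.argmax(SIX_STRATA["used"].to_numpy().reshape(6, 3), axis=1)
        oracle = oracles.grid_search_clogit(X, used)
        assert fit.beta["road_cross"] == pytest.approx(oracle, abs=1e-3)

    def test_non_identifiable_covariate_named(self):
        df = SIX_STRATA.assign(flat=1)
        with pytest.raises(NonIdentifiableError, match="flat"):
            fit_conditional_logistic(df, covariates=("flat",))

    def test_separation_warns_and_caps(self, rng):
        df = simulate_choice_data(rng, 40, beta=0.0)
        # covariate perfectly predicts the used step
        df["road_cross"] = df["used"]
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_conditional_logistic(df, covariates=("road_cross",))
        assert not fit.converged
        assert np.isfinite(fit.beta["road_cross"])

    def test_stratum_constant_shift_invariance(self, rng):
        df = simulate_choice_data(rng, 200, beta=-1.0)
        fit_a = fit_conditional_logistic(df, covariates=("road_cross",))
        shifted = df.copy()
        offsets = {sid: k % 3 for k, sid in enumerate(shifted["stratum_id"].unique())}
        shifted["road_cross"] = shifted["road_cross"] + shifted["stratum_id"].map(offsets)
        fit_b = fit_conditional_logistic(shifted, covariates=("road_cross",))
        assert fit_b.beta["road_cross"] == pytest.approx(fit_a.beta["road_cross"], abs=1e-6)

    def test_recovery_coverage_500_strata(self, rng):
        hits = 0
        for _ in range(50):
            df = simulate_choice_data(rng, 500, beta=-1.5)
            fit = fit_conditional_logistic(df, covariates=("road_cross",))
            if fit.ci_lower["road_cross"] <= -1.5 <= fit.ci_upper["road_cross"]:
                hits += 1
        assert hits >= 45  # >= 90% of 50 replicates

    @pytest.mark.parametrize("beta", [-1.5, 0.0, 0.6])
    def test_mean_estimate_near_truth(self, beta, rng):
        ests = []
        for _ in range(50):
            df = simulate_choice_data(rng, 500, beta=beta)
            ests.append(fit_conditional_logistic(df, covariates=("road_cross",)).beta["road_cross"])
        assert np.mean(ests) == pytest.approx(beta, abs=0.15)


class TestPoissonReformulation:
    def test_agrees_with_direct_maximizer(self, rng):
        df = simulate_choice_data(rng, 300, beta=-1.2)
        direct = fit_conditional_logistic(df, covariates=("road_cross",))
        pois = fit_poisson_reformulation(df, covariates=("road_cross",))
        assert pois.beta["road_cross"] == pytest.approx(direct.beta["road_cross"], abs=1e-3)
        assert pois.se["road_cross"] == pytest.approx(direct.se["road_cross"], rel=0.02)

    def test_insensitive_to_stratum_variance(self, rng):
        df = simulate_choice_data(rng, 200, beta=0.8)
        a = fit_poisson_reformulation(df, covariates=("road_cross",), stratum_variance=1e6)
        b = fit_poisson_reformulation(df, covariates=("road_cross",), stratum_variance=1e4)
        assert a.beta["road_cross"] == pytest.approx(b.beta["road_cross"], abs=1e-3)

    def test_multicovariate_agreement(self, small_sim, rng):
        df = simulate_choice_data(rng, 250, beta=-1.0)
        df["trail_cross"] = (rng.random(len(df)) < 0.3).astype(int)
        covs = ("road_cross", "trail_cross")
        direct = fit_conditional_logistic(df, covariates=covs)
        pois = fit_poisson_reformulation(df, covariates=covs)
        for c in covs:
            assert pois.beta[c] == pytest.approx(direct.beta[c], abs=1e-3)


class TestRandomEffects:
    def test_recovers_heterogeneous_slopes(self, rng):
        # 6 animals with animal-specific slopes around -1.0
        frames = []
        for a in range(6):
            beta_a = -1.0 + rng.normal(0, 0.5)
            df = simulate_choice_data(rng, 120, beta=beta_a)
            df["stratum_id"] = df["stratum_id"] + f"_a{a}"
            df["animal_id"] = f"animal{a}"
            frames.append(df)
        pooled = pd.concat(frames, ignore_index=True)
        fit = fit_conditional_logistic(pooled, covariates=("road_cross",), random_effects=True)
        assert fit.beta["road_cross"] == pytest.approx(-1.0, abs=0.45)
        assert fit.re_variance["road_cross"] >= 0.0

    def test_zero_heterogeneity_matches_fixed_fit(self, rng):
        df = simulate_choice_data(rng, 400, beta=-1.0, n_animals=4)
        fixed = fit_conditional_logistic(df, covariates=("road_cross",))
        mixed = fit_conditional_logistic(df, covariates=("road_cross",), random_effects=True)
        assert mixed.beta["road_cross"] == pytest.approx(fixed.beta["road_cross"], abs=0.05)


class TestRss:
    def test_reported_transforms(self):
        assert round(rss(-1.73), 2) == 0.18
        assert round(rss(0.87), 2) == 2.39

    def test_indifference(self):
        assert rss(0.0) == 1.0

    def test_reciprocal_symmetry(self, rng):
        for b in rng.normal(0, 2, 20):
            assert rss(-b) == pytest.approx(1.0 / rss(b), rel=1e-12)

    def test_log_rss_identity(self):
        assert log_rss(0.58) == 0.58

    def test_interval_transform(self):
        lo, hi = rss_interval(-2.50, -0.96)
        assert round(lo, 2) == 0.08
        assert round(hi, 2) == 0.38

    def test_summary_table_layout(self, rng):
        df = simulate_choice_data(rng, 100, beta=0.5)
        fit = fit_conditional_logistic(df, covariates=("road_cross",), sex="F")
        table = summary_table(fit)
        assert list(table.columns) == [
            "sex", "feature", "beta", "beta_lo", "beta_hi", "rss", "rss_lo", "rss_hi",
        ]
        assert table["rss"].iloc[0] == pytest.approx(np.exp(table["beta"].iloc[0]))
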