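"""Moving-window PCA, skew-signed direction, and the sign corrections."""
import dataclasses

import numpy as np
import pytest
from scipy import stats

from conftest import make_diary, make_indicator
from ewsdir.indicator import (
    AnalysisConfig,
    AnalysisError,
    DegenerateWindowError,
    analyze_matrix,
    analyze_sums,
    compute_indicator,
    correct_sign_flips,
    directional_vector,
    drop_nonsignificant_skews,
    first_component,
    projected_skewness,
    skew_pvalue,
    slide_windows,
)
from ewsdir.preprocess import ValenceSums, valence_sums
from ewsdir.synthetic import (
    INCREASE,
    NONE,
    SimulationConfig,
    render_items,
    simulate_latent_transition,
    strong_transition_config,
)


def two_by_two_pca_oracle(X):
    """Closed-form 2x2 covariance eigendecomposition via the quadratic formula."""
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / X.shape[0]
    a, b, d = C[0, 0], C[0, 1], C[1, 1]
    lam1 = (a + d) / 2 + np.sqrt(((a - d) / 2) ** 2 + b**2)
    lam2 = (a + d) / 2 - np.sqrt(((a - d) / 2) ** 2 + b**2)
    if abs(b) > 1e-300:
        v = np.array([b, lam1 - a])
    else:
        v = np.array([1.0, 0.0]) if a >= d else np.array([0.0, 1.0])
    v = v / np.linalg.norm(v)
    return lam1, lam2, v


class TestSlideWindows:
    def test_window_count_unit_step(self):
        values = np.random.default_rng(0).normal(size=(183, 2))
        cfg = AnalysisConfig(window_size=60)
        wins = list(slide_windows(values, cfg))
        assert len(wins) == 183 - 60 + 1 == 124
        assert wins[0][0] == 60 and wins[-1][0] == 183

    def test_exact_length_series_gives_one_window(self):
        values = np.random.default_rng(0).normal(size=(60, 2))
        wins = list(slide_windows(values, AnalysisConfig(window_size=60)))
        assert len(wins) == 1

    def test_half_missing_window_skipped_under_strict_threshold(self):
        values = np.random.default_rng(0).normal(size=(10, 2))
        values[::2] = np.nan  # 50% of occasions missing
        cfg = AnalysisConfig(window_size=10, min_complete=0.8)
        (end, win), = slide_windows(values, cfg)
        assert end == 10 and win is None

    def test_short_series_rejected(self):
        with pytest.raises(AnalysisError, match="exceeds series length"):
            list(slide_windows(np.zeros((5, 2)), AnalysisConfig(window_size=60)))


class TestFirstComponent:
    def test_perfectly_anticorrelated_pair_explains_everything(self):
        t = np.linspace(0, 1, 30)
        X = np.column_stack([t, 1 - t])
        _, R, _ = first_component(X)
        assert R == pytest.approx(1.0, abs=1e-12)

    def test_hand_matrix_matches_quadratic_formula_oracle(self):
        X = np.array([[1, 2], [2, 1], [3, 4], [4, 3], [5, 5]], dtype=float)
        lam1, lam2, v = two_by_two_pca_oracle(X)
        loadings, R, scores = first_component(X, neg_cols=[1])
        assert R == pytest.approx(lam1 / (lam1 + lam2), abs=1e-12)
        if v[1] < 0:
            v = -v
        np.testing.assert_allclose(loadings, v, atol=1e-12)
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(scores, Xc @ v, atol=1e-12)

    def test_isotropic_noise_splits_variance_evenly(self):
        rng = np.random.default_rng(123)
        Rs = [
            first_component(rng.normal(size=(20000, 2)))[1] for _ in range(30)
        ]
        spread = 3 * np.std(Rs)
        assert np.mean(Rs) == pytest.approx(0.5, abs=max(spread, 0.01))

    def test_orientation_pins_negative_valence_loading(self, rng):
        X = rng.normal(size=(50, 3))
        loadings, _, _ = first_component(X, neg_cols=[1, 2])
        ref = [1, 2][int(np.argmax(np.abs(loadings[[1, 2]])))]
        assert loadings[ref] >= 0

    def test_constant_window_flagged_degenerate(self):
        with pytest.raises(DegenerateWindowError):
            first_component(np.ones((10, 2)))

    def test_too_few_rows_rejected(self):
        with pytest.raises(AnalysisError):
            first_component(np.zeros((1, 2)))

    def test_matches_brute_force_eigendecomposition(self, rng):
        """Random small windows agree with an independent covariance eigh."""
        for _ in range(200):
            n = rng.integers(5, 40)
            p = rng.integers(2, 7)
            X = rng.normal(size=(n, p)) * rng.uniform(0.5, 3, size=p)
            loadings, R, _ = first_component(X)
            Xc = X - X.mean(axis=0)
            C = np.cov(Xc.T, bias=True)
            w, V = np.linalg.eigh(C)
            assert R == pytest.approx(w[-1] / w.sum(), abs=1e-10)
            v = V[:, -1]
            assert abs(abs(loadings @ v) - 1) < 1e-10


class TestProjectedSkewness:
    def test_symmetric_sample_has_zero_skew(self):
        assert projected_skewness(np.array([-1.0, 0.0, 1.0])) == pytest.approx(0.0)

    def test_hand_fixture_matches_central_moment_formula(self):
        # deviations (-3,-2,-1,0,6): m2 = 10, m3 = 36 -> g1 = 36/10^1.5
        g1 = projected_skewness(np.array([1.0, 2, 3, 4, 10]))
        assert g1 == pytest.approx(36 / 10**1.5, abs=1e-12)
        assert g1 == pytest.approx(1.1384, abs=1e-4)

    def test_mirrored_sample_negates_skew(self, rng):
        x = rng.normal(size=100) ** 2
        assert projected_skewness(-x) == pytest.approx(-projected_skewness(x))

    def test_degenerate_sample_returns_zero(self):
        assert projected_skewness(np.array([2.0, 2.0, 2.0])) == 0.0

    def test_too_few_scores_rejected(self):
        with pytest.raises(AnalysisError):
            projected_skewness(np.array([1.0, 2.0]))


class TestDirectionalVector:
    def test_positive_skew_points_along_negative_state_axis(self):
        sign, change = directional_vector(np.array([0.0, 1.0]), 1.0, 0.5)
        assert sign == 1
        np.testing.assert_allclose(change, [0.0, 1.0])

    def test_negative_skew_negates_the_vector(self):
        _, up = directional_vector(np.array([0.0, 1.0]), 1.0, 0.5)
        _, down = directional_vector(np.array([0.0, 1.0]), 1.0, -0.5)
        np.testing.assert_allclose(down, -up)

    def test_opposite_loadings_give_opposite_signed_changes(self):
        """A window whose component opposes the valences predicts an increase
        in negative states together with a larger decrease in positive ones."""
        loadings = np.array([-0.9, 0.7]) / np.hypot(0.9, 0.7)  # (pos, neg)
        _, change = directional_vector(loadings, 0.8, g1=0.6)
        pos_change, neg_change = change
        assert neg_change > 0 > pos_change
        assert abs(pos_change) > abs(neg_change)

    def test_zero_skew_inherits_previous_sign(self):
        sign, _ = directional_vector(np.array([0.0, 1.0]), 1.0, 0.0, prev_sign=-1)
        assert sign == -1
        sign, _ = directional_vector(np.array([0.0, 1.0]), 1.0, 0.0, prev_sign=None)
        assert sign == 1


class TestSignCorrections:
    def test_single_deviant_window_is_flipped(self):
        ind = make_indicator([0.5, 0.4, -0.3, 0.5, 0.6], signs=[1, 1, -1, 1, 1])
        out = correct_sign_flips(ind, AnalysisConfig(max_flip_run=1))
        np.testing.assert_array_equal(out.windows["sign"], [1, 1, 1, 1, 1])
        assert out.windows["neg_change"].iloc[2] == pytest.approx(0.3)
        assert out.windows["corrected"].tolist() == [False, False, True, False, False]

    def test_uniform_signs_unchanged(self):
        ind = make_indicator([0.5, 0.4, 0.3], signs=[1, 1, 1])
        out = correct_sign_flips(ind, AnalysisConfig())
        assert out.windows.equals(ind.windows)

    def test_run_longer_than_limit_not_flipped(self):
        ind = make_indicator([0.5, -0.4, -0.3, 0.5], signs=[1, -1, -1, 1])
        out = correct_sign_flips(ind, AnalysisConfig(max_flip_run=1))
        np.testing.assert_array_equal(out.windows["sign"], [1, -1, -1, 1])

    def test_boundary_runs_never_flipped(self):
        ind = make_indicator([-0.5, 0.4, 0.3, 0.5], signs=[-1, 1, 1, 1])
        out = correct_sign_flips(ind, AnalysisConfig(max_flip_run=1))
        np.testing.assert_array_equal(out.windows["sign"], [-1, 1, 1, 1])

    def test_alternating_signs_converge_to_majority(self):
        ind = make_indicator([0.1, -0.1, 0.1, -0.1, 0.1], signs=[1, -1, 1, -1, 1])
        out = correct_sign_flips(ind, AnalysisConfig(max_flip_run=1))
        np.testing.assert_array_equal(out.windows["sign"], [1, 1, 1, 1, 1])

    def test_zero_skew_window_dropped(self):
        ind = make_indicator([0.5, 0.4, 0.3], g1=[0.9, 0.0, 0.9])
        out = drop_nonsignificant_skews(ind, AnalysisConfig(alpha_skew=0.05))
        assert 2 not in out.windows["window_index"].tolist()
        assert any(reason == "nonsignificant_skew" for _, reason in out.skipped)

    def test_strong_skew_retained_per_dagostino(self):
        """g1 ~ 1.1 at n=60 is decisively non-zero under the published test."""
        scores = np.tile([1.0, 2.0, 3.0, 4.0, 10.0], 12)  # n=60, g1 ~ 1.14
        g1 = projected_skewness(scores)
        assert g1 == pytest.approx(36 / 10**1.5, abs=1e-12)
        ind = make_indicator([0.5], g1=[g1])
        ind.windows["n_used"] = 60
        out = drop_nonsignificant_skews(ind, AnalysisConfig(alpha_skew=0.05))
        assert len(out.windows) == 1

    def test_small_windows_removed_as_untestable(self):
        ind = make_indicator([0.5], g1=[2.0])
        ind.windows["n_used"] = 5
        out = drop_nonsignificant_skews(ind, AnalysisConfig())
        assert len(out.windows) == 0
        assert out.skipped[0][1] == "untestable_skew"

    def test_skew_pvalue_matches_scipy_skewtest(self, rng):
        for n in (8, 20, 60, 150):
            x = rng.normal(size=n) + rng.exponential(size=n)
            g1 = projected_skewness(x)
            expected = stats.skewtest(x).pvalue
            assert skew_pvalue(g1, n) == pytest.approx(expected, rel=1e-10)


class TestAnalyzePipelines:
    @pytest.fixture
    def sums_fixture(self, rng):
        cfg = SimulationConfig(n_occasions=183, seed=3)
        traj = simulate_latent_transition(cfg, INCREASE, rng=rng)
        series = render_items(traj, cfg, rng)
        vals = series.ratings.to_numpy()
        vals[rng.random(183) < 0.12] = np.nan
        series.ratings.iloc[:, :] = vals
        return valence_sums(series)

    def test_fast_path_agrees_with_reference_implementation(self, sums_fixture):
        cfg = AnalysisConfig(window_size=60, skew_correction="none")
        fast = analyze_sums(sums_fixture, cfg)
        ref = analyze_matrix(
            sums_fixture.matrix(),
            cfg,
            valences=["positive", "negative"],
            person_id=sums_fixture.person_id,
            occasions=sums_fixture.occasions,
        )
        assert fast.windows["window_index"].tolist() == ref.windows["window_index"].tolist()
        np.testing.assert_array_equal(fast.windows["n_used"], ref.windows["n_used"])
        np.testing.assert_allclose(fast.windows["R"], ref.windows["R"], atol=1e-9)
        np.testing.assert_allclose(fast.windows["g1"], ref.windows["g1"], atol=1e-7)
        np.testing.assert_array_equal(fast.windows["sign"], ref.windows["sign"])
        np.testing.assert_allclose(
            fast.windows["neg_change"], ref.windows["neg_change"], atol=1e-9
        )
        assert fast.skipped == ref.skipped

    def test_vector_length_equals_explained_variance(self, sums_fixture):
        cfg = AnalysisConfig(window_size=60, skew_correction="none")
        out = analyze_sums(sums_fixture, cfg)
        norms = np.sqrt((out.predicted**2).sum(axis=1))
        np.testing.assert_allclose(norms, out.windows["R"], atol=1e-10)

    def test_negated_data_negates_direction_but_not_length(self, sums_fixture):
        cfg = AnalysisConfig(window_size=60, skew_correction="none")
        base = analyze_sums(sums_fixture, cfg)
        flipped = ValenceSums(
            person_id=sums_fixture.person_id,
            occasions=sums_fixture.occasions,
            pos_sum=-sums_fixture.pos_sum,
            neg_sum=-sums_fixture.neg_sum,
            n_items_pos=sums_fixture.n_items_pos,
            n_items_neg=sums_fixture.n_items_neg,
        )
        neg = analyze_sums(flipped, cfg)
        np.testing.assert_allclose(neg.windows["R"], base.windows["R"], atol=1e-9)
        np.testing.assert_allclose(neg.windows["g1"], -base.windows["g1"], atol=1e-7)
        np.testing.assert_allclose(neg.predicted, -base.predicted, atol=1e-9)

    def test_noise_free_stationary_series_is_all_degenerate(self):
        cfg = SimulationConfig(
            n_occasions=183, sigma=0.0, item_noise_sd=0.0, missing_rate=0.0, seed=0
        )
        rng = np.random.default_rng(0)
        traj = simulate_latent_transition(cfg, NONE, rng=rng)
        series = render_items(traj, cfg, rng)
        out = compute_indicator(series, AnalysisConfig(window_size=60))
        assert out.n_windows == 0
        assert all(reason == "degenerate" for _, reason in out.skipped)

    def test_destabilizing_cohorts_show_rising_negative_change(self):
        """Approaching the high-symptom basin, late pre-transition windows
        predict a larger increase in negative states than early windows.

        Windows that end after the basin switch describe the settled new
        state rather than the destabilization, so the comparison is over
        windows ending at or before the switch.
        """
        cfg = AnalysisConfig(window_size=60)
        rises = []
        sim = strong_transition_config(n_persons=1, seed=0)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            traj = simulate_latent_transition(sim, INCREASE, rng=rng)
            series = render_items(traj, sim, rng)
            out = compute_indicator(series, cfg)
            w = out.windows
            cut = traj.transition_occasion or sim.n_occasions
            neg = w.loc[w["window_index"] <= cut, "neg_change"].to_numpy()
            q = len(neg) // 4
            assert q > 3
            rises.append(neg[-q:].mean() > neg[:q].mean())
        assert sum(rises) >= 9

    def test_empty_indicator_flows_to_undefined_trend(self):
        from ewsdir.trend import kendall_trend

        ind = make_indicator([0.5, 0.4], g1=[0.0, 0.0])
        out = drop_nonsignificant_skews(ind, AnalysisConfig())
        trend = kendall_trend(out)
        assert trend.trend_class == "none" and np.isnan(trend.tau)

    def test_items_granularity_runs_on_raw_diary(self, rng):
        sim = SimulationConfig(n_occasions=120, seed=2)
        traj = simulate_latent_transition(sim, INCREASE, rng=rng)
        series = render_items(traj, sim, rng)
        out = compute_indicator(
            series, AnalysisConfig(window_size=40, granularity="items")
        )
        assert out.n_windows == 120 - 40 + 1
        assert len(out.var_names) == 28
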