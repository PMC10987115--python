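import numpy as np
import pytest

from slugflow.design_space import DesignSpace, VariableBound
from slugflow.objectives import OBJECTIVE_SENSES
from slugflow.self_opt import (CampaignResult, fit_gp, hv_improvement,
                               hypervolume, make_pareto_set, pareto_front,
                               pareto_mask, random_campaign, reference_point,
                               run_campaign, select_next, thompson_sample,
                               _to_min)


class TestGPSurrogate:
    def test_constant_response_posterior_is_constant(self, rng):
        X = rng.uniform(-1, 1, size=(10, 2))
        y = np.full(10, 3.7)
        model = fit_gp(X, y, seed=0)
        Xq = rng.uniform(-1, 1, size=(20, 2))
        np.testing.assert_allclose(model.predict(Xq), 3.7, atol=1e-3)

    def test_noise_free_quadratic_interpolates(self):
        X = np.linspace(-1, 1, 8)[:, None]
        y = (X[:, 0] ** 2) * 2.0 - 0.5
        model = fit_gp(X, y, seed=0)
        mid = (X[:-1, 0] + X[1:, 0]) / 2
        pred = model.predict(mid[:, None])
        truth = 2.0 * mid ** 2 - 0.5
        assert np.max(np.abs(pred - truth)) < 1e-3

    def test_posterior_mean_near_observations(self, rng):
        X = rng.uniform(-1, 1, size=(15, 3))
        y = np.sin(2 * X[:, 0]) + 0.3 * X[:, 1]
        model = fit_gp(X, y, seed=0)
        pred = model.predict(X)
        tol = max(2 * model.noise_std, 1e-6)
        assert np.max(np.abs(pred - y)) < max(tol, 1e-3)

    def test_variance_smaller_at_training_point_than_far_away(self, rng):
        X = rng.uniform(-0.2, 0.2, size=(6, 2))
        y = X[:, 0] + X[:, 1]
        model = fit_gp(X, y, seed=0)
        _, s_train = model.predict(X[:1], return_std=True)
        _, s_far = model.predict(np.array([[1.0, -1.0]]), return_std=True)
        assert s_train[0] <= s_far[0]

    def test_degenerate_inputs_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="identical"):
            fit_gp(X, np.arange(5.0))
        with pytest.raises(ValueError):
            fit_gp(np.array([[0.0, 0.0]]), np.array([1.0]))


class TestThompsonSampling:
    def test_same_seed_identical_draw(self, rng):
        X = rng.uniform(-1, 1, size=(10, 2))
        y = X[:, 0] ** 2
        model = fit_gp(X, y, seed=0)
        cand = rng.uniform(-1, 1, size=(15, 2))
        d1 = thompson_sample(model, cand, seed=5)
        d2 = thompson_sample(model, cand, seed=5)
        np.testing.assert_array_equal(d1, d2)

    def test_near_zero_variance_draw_equals_posterior_mean(self, rng):
        X = np.linspace(-1, 1, 12)[:, None]
        y = 1.5 * X[:, 0]
        model = fit_gp(X, y, seed=0)
        draws = thompson_sample(model, X, seed=3)
        # at training points of a noise-free fit the posterior is pinned to
        # within the jitter scale
        assert np.max(np.abs(draws - model.predict(X))) < 0.05 * np.std(y)

    def test_moments_match_posterior(self, rng):
        """1000 seeded draws reproduce the posterior mean and variance
        within Monte-Carlo error."""
        X = rng.uniform(-1, 1, size=(8, 1))
        y = np.sin(3 * X[:, 0])
        model = fit_gp(X, y, seed=0)
        cand = np.array([[0.3], [0.9]])
        mean, std = model.predict(cand, return_std=True)
        draws = np.array([thompson_sample(model, cand, seed=s) for s in range(1000)])
        mc_se = std / np.sqrt(1000)
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 4 * mc_se + 1e-9)
        assert np.all(np.abs(draws.std(axis=0) - std) < 0.15 * std + 1e-3)

    def test_empty_candidates_rejected(self, rng):
        X = rng.uniform(-1, 1, size=(5, 2))
        model = fit_gp(X, X[:, 0], seed=0)
        with pytest.raises(ValueError):
            thompson_sample(model, np.empty((0, 2)), seed=1)


class TestParetoFront:
    def test_single_row_is_its_own_front(self):
        assert list(pareto_front(np.array([[1.0, 2.0, 3.0]]))) == [0]

    def test_hand_case_two_dimensional(self):
        F = np.array([[1.0, 2.0], [2.0, 1.0], [2.0, 2.0]])
        idx = pareto_front(F, senses=(-1, -1))
        assert sorted(idx) == [0, 1]

    def test_duplicate_optima_both_kept(self):
        F = np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 2.0]])
        assert sorted(pareto_front(F, senses=(-1, -1))) == [0, 1]

    def test_matches_pairwise_domination_oracle(self, rng):
        """O(n^2) brute-force dominance check on random 3-D instances."""
        for _ in range(5):
            F = rng.normal(size=(50, 3))
            senses = (1, 1, -1)
            got = set(pareto_front(F, senses))
            Fm = _to_min(F, senses)
            expected = set()
            for i in range(len(Fm)):
                dominated = any(
                    np.all(Fm[j] <= Fm[i]) and np.any(Fm[j] < Fm[i])
                    for j in range(len(Fm)) if j != i)
                if not dominated:
                    expected.add(i)
            assert got == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pareto_front(np.array([[np.nan, 1.0, 1.0]]))


class TestHypervolume:
    def test_unit_square(self):
        assert hypervolume(np.array([[0.0, 0.0]]), np.array([1.0, 1.0])) == pytest.approx(1.0)

    def test_dominated_point_adds_nothing(self):
        ref = np.array([1.0, 1.0])
        base = hypervolume(np.array([[0.0, 0.0]]), ref)
        aug = hypervolume(np.array([[0.0, 0.0], [0.5, 0.5]]), ref)
        assert aug == pytest.approx(base)

    def test_two_dimensional_hand_case(self):
        front = np.array([[0.0, 0.5], [0.5, 0.0]])
        # union of two rectangles: 1*0.5 + 0.5*1 - 0.5*0.5
        assert hypervolume(front, np.array([1.0, 1.0])) == pytest.approx(0.75)

    def test_point_not_dominating_reference_rejected(self):
        with pytest.raises(ValueError):
            hypervolume(np.array([[2.0, 0.0]]), np.array([1.0, 1.0]))

    def test_three_dimensional_matches_monte_carlo_oracle(self, rng):
        """Exact sweep vs 1e6-sample Monte-Carlo estimate within 3 SE."""
        pts = rng.uniform(0.0, 0.8, size=(8, 3))
        ref = np.ones(3)
        exact = hypervolume(pts, ref)
        samples = rng.uniform(0.0, 1.0, size=(1_000_000, 3))
        dominated = np.zeros(len(samples), dtype=bool)
        for p in pts:
            dominated |= np.all(samples >= p, axis=1)
        frac = dominated.mean()
        se = np.sqrt(frac * (1 - frac) / len(samples))
        assert abs(exact - frac) < 3 * se + 1e-9


class TestSelection:
    def test_single_candidate_selected(self, rng):
        X = rng.uniform(-1, 1, size=(6, 2))
        models = [fit_gp(X, X[:, 0] + j, seed=j) for j in range(3)]
        cand = np.array([[0.1, 0.2]])
        front = _to_min(rng.uniform(size=(4, 3)), (-1, -1, -1))
        ref = reference_point(front)
        assert select_next(models, cand, front, ref, seed=0) == 0

    def test_selection_matches_naive_hvi_scan(self, rng):
        """Exhaustive hypervolume-improvement scan over the same Thompson
        draws reproduces the selected index."""
        X = rng.uniform(-1, 1, size=(12, 2))
        models = [fit_gp(X, np.sin((j + 1) * X[:, 0]) + X[:, 1], seed=j)
                  for j in range(3)]
        cand = rng.uniform(-1, 1, size=(40, 2))
        front = rng.uniform(0.2, 0.8, size=(5, 3))
        front = front[pareto_mask(front)]
        ref = reference_point(front)
        seed = 17
        got = select_next(models, cand, front, ref, seed=seed)
        draws = np.column_stack([
            thompson_sample(m, cand, seed=seed + 7919 * j)
            for j, m in enumerate(models)])
        hvis = [hv_improvement(front, d, ref) for d in draws]
        assert got == int(np.argmax(hvis))


def _tiny_space():
    return DesignSpace(bounds=(
        VariableBound("t_res", 0.5, 12.0, "min"),
        VariableBound("temp", 80.0, 140.0, "degC"),
        VariableBound("cat_loading", 1.0, 6.0, "mol%"),
    ), fixed={"amine_equiv": 1.2, "conc": 0.33, "dbu_equiv": 1.3})


class TestCampaign:
    def test_pure_lhc_budget(self, stocks, true_params, noise):
        res = run_campaign(_tiny_space(), stocks, true_params, noise,
                           budget=(2, 0), seed=1, pool_size=10)
        assert len(res.training_records) == 2

    def test_bit_reproducible(self, stocks, true_params, noise, cfg):
        kw = dict(budget=(4, 3), checkpoint=cfg.checkpoint, checkpoint_period=2,
                  seed=9, pool_size=25, gp_restarts=0)
        a = run_campaign(_tiny_space(), stocks, true_params, noise, **kw)
        b = run_campaign(_tiny_space(), stocks, true_params, noise, **kw)
        assert [r.id for r in a.records] == [r.id for r in b.records]
        for ra, rb in zip(a.records, b.records):
            assert ra.measured == rb.measured
        assert a.pareto.hypervolume == b.pareto.hypervolume

    def test_checkpoints_logged_but_excluded_from_training(self, stocks,
                                                           true_params, noise, cfg):
        res = run_campaign(_tiny_space(), stocks, true_params, noise,
                           budget=(4, 5), checkpoint=cfg.checkpoint,
                           checkpoint_period=2, seed=2, pool_size=25,
                           gp_restarts=0)
        checkpoints = [r for r in res.records if r.is_checkpoint]
        assert len(checkpoints) == 2      # after guided iterations 2 and 4
        assert len(res.training_records) == 9
        assert all(r.setpoint == cfg.checkpoint for r in checkpoints)

    def test_hypervolume_trace_nondecreasing(self, stocks, true_params, noise, cfg):
        res = run_campaign(_tiny_space(), stocks, true_params, noise,
                           budget=(5, 4), checkpoint=None, seed=3,
                           pool_size=25, gp_restarts=0)
        trace = res.hypervolume_trace()
        assert np.all(np.diff(trace) >= -1e-12)

    def test_bad_budget_rejected(self, stocks, true_params, noise):
        with pytest.raises(ValueError):
            run_campaign(_tiny_space(), stocks, true_params, noise, budget=(1, 0))

    def test_parallel_coordinates_yield_filter(self, stocks, true_params, noise):
        from slugflow.self_opt import parallel_coordinates_frame

        res = run_campaign(_tiny_space(), stocks, true_params, noise,
                           budget=(6, 0), seed=4, pool_size=10)
        full = parallel_coordinates_frame(res.records)
        good = parallel_coordinates_frame(res.records, min_yield_pct=65.0)
        n_good = sum(1 for r in res.training_records
                     if r.objectives.yield_pct > 65.0)
        assert set(full["variable"]) == {"amine_equiv", "conc", "t_res", "temp",
                                         "dbu_equiv", "cat_loading",
                                         "yield_pct", "sty", "cost"}
        assert good["id"].nunique() == n_good


def test_reference_point_margin():
    F = np.array([[0.0, 10.0], [1.0, 0.0]])
    ref = reference_point(F, margin=0.1)
    np.testing.assert_allclose(ref, [1.1, 11.0])


def test_make_pareto_set_members_not_dominated(stocks, true_params, noise):
    res = random_campaign(_tiny_space(), stocks, true_params, noise,
                          n_runs=15, seed=5)
    ps = res.pareto
    member_ids = set(ps.member_ids)
    F = np.array([r.objectives.as_tuple() for r in res.records])
    idx = pareto_front(F, OBJECTIVE_SENSES)
    assert member_ids == {res.records[i].id for i in idx}
    assert ps.hypervolume >= 0
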