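"""Sparrow search optimizer: chaotic init, role updates, and the full loop.

Each vectorized phase update is checked bit-for-bit against a straight-line
scalar reimplementation that consumes an identically seeded random stream in
the same documented draw order.
"""

import numpy as np
import pytest
from numpy.testing import assert_array_equal

from capmoist.benchmarks import BENCHMARKS
from capmoist.ssa import (
    Population,
    SsaConfig,
    init_population,
    init_positions,
    logistic_sequence,
    optimize,
    update_finders,
    update_joiners,
    update_scouts,
)


def make_cfg(**kwargs):
    defaults = dict(dims=4, lower_bounds=-5.0, upper_bounds=5.0, pop_size=12, max_iters=20, seed=7)
    defaults.update(kwargs)
    return SsaConfig(**defaults)


def make_population(cfg, rng, objective=None):
    positions = init_positions(cfg, rng)
    if objective is None:
        objective = lambda x: float(np.sum(x**2))
    fitness = np.array([objective(p) for p in positions])
    return Population(positions=positions, fitness=fitness)


class TestLogisticSequence:
    def test_fully_chaotic_orbit_values(self):
        seq = logistic_sequence(0.3, 4.0, 4)
        assert seq == pytest.approx([0.3, 0.84, 0.5376, 0.99434496], abs=1e-12)

    def test_a_zero_collapse(self):
        seq = logistic_sequence(0.7, 0.0, 5)
        assert seq[0] == 0.7 and np.all(seq[1:] == 0.0)

    def test_fixed_point_preimage(self):
        # y0 = 0.5 maps to 1 then sticks at 0 forever: a degenerate orbit
        seq = logistic_sequence(0.5, 4.0, 5)
        assert seq[1] == 1.0 and np.all(seq[2:] == 0.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            logistic_sequence(0.0, 4.0, 3)
        with pytest.raises(ValueError):
            logistic_sequence(0.3, 4.5, 3)


class TestInitPopulation:
    @pytest.mark.parametrize("mode", ["uniform", "logistic"])
    def test_within_bounds(self, mode, rng):
        cfg = make_cfg(init_mode=mode, lower_bounds=np.array([0.0, -1, 2, -3.0]),
                       upper_bounds=np.array([1.0, 1, 3, 3.0]))
        pos = init_positions(cfg, rng)
        assert np.all(pos >= cfg.lower_bounds) and np.all(pos <= cfg.upper_bounds)

    @pytest.mark.parametrize("mode", ["uniform", "logistic"])
    def test_deterministic_given_seed(self, mode):
        cfg = make_cfg(init_mode=mode, seed=42)
        a = init_positions(cfg, np.random.default_rng(42))
        b = init_positions(cfg, np.random.default_rng(42))
        assert_array_equal(a, b)

    def test_chaotic_init_spreads_over_unit_interval(self):
        """The a=4 orbit follows the arcsine-shaped invariant density."""
        from scipy import stats

        cfg = make_cfg(dims=1, pop_size=500, init_mode="logistic",
                       lower_bounds=0.0, upper_bounds=1.0)
        sample = init_positions(cfg, np.random.default_rng(3)).ravel()
        counts, _ = np.histogram(sample, bins=10, range=(0, 1))
        assert np.all(counts > 0)
        ks_chaotic = stats.kstest(sample, stats.beta(0.5, 0.5).cdf).statistic
        degenerate = np.full(500, 0.75)  # fixed-point orbit of the map
        ks_degenerate = stats.kstest(degenerate, stats.beta(0.5, 0.5).cdf).statistic
        assert ks_chaotic < 0.1 < ks_degenerate


class TestFinderUpdate:
    def test_safe_branch_contracts_magnitudes(self, rng):
        cfg = make_cfg(safety_value=1.0)  # alarm draw < 1 always: safe branch
        pop = make_population(cfg, rng)
        before = pop.positions.copy()
        finders = update_finders(pop, t=1, cfg=cfg, rng=rng)
        after = pop.positions[finders]
        assert np.all(np.abs(after) <= np.abs(before[finders]) + 1e-15)

    def test_matches_scalar_oracle(self, rng):
        cfg = make_cfg(safety_value=0.5)  # both branches exercised over seeds
        for seed in range(6):
            pop = make_population(cfg, np.random.default_rng(seed))
            twin = Population(pop.positions.copy(), pop.fitness.copy())
            update_finders(pop, t=1, cfg=cfg, rng=np.random.default_rng(100 + seed))

            # --- independent scalar re-implementation ---
            r2 = np.random.default_rng(100 + seed)
            order = np.argsort(twin.fitness, kind="stable")
            k = cfg.n_finders
            alarm = r2.random()
            if alarm < cfg.safety_value:
                alphas = 1.0 - r2.random(k)
                for rank, idx in enumerate(order[:k], start=1):
                    for j in range(cfg.dims):
                        twin.positions[idx, j] *= np.exp(-rank / (alphas[rank - 1] * cfg.max_iters))
            else:
                q = r2.standard_normal((k, cfg.dims))
                for rank, idx in enumerate(order[:k], start=1):
                    for j in range(cfg.dims):
                        twin.positions[idx, j] += q[rank - 1, j]
            for idx in order[:k]:
                twin.positions[idx] = np.clip(twin.positions[idx], cfg.lower_bounds, cfg.upper_bounds)
            assert_array_equal(pop.positions, twin.positions)


class TestJoinerUpdate:
    def test_joiner_at_producer_stays(self, rng):
        cfg = make_cfg(pop_size=8, finder_fraction=0.25)
        pop = make_population(cfg, rng)
        order = pop.rank_order()
        # rank-3 joiner (i=3 <= n/2) placed exactly at the best position
        target = order[2]
        pop.positions[target] = pop.positions[order[0]].copy()
        x_p = pop.positions[order[0]].copy()
        update_joiners(pop, cfg, rng)
        assert_array_equal(pop.positions[target], x_p)

    def test_matches_scalar_oracle(self):
        cfg = make_cfg()
        for seed in range(6):
            pop = make_population(cfg, np.random.default_rng(seed))
            twin = Population(pop.positions.copy(), pop.fitness.copy())
            update_joiners(pop, cfg, rng=np.random.default_rng(200 + seed))

            r2 = np.random.default_rng(200 + seed)
            order = np.argsort(twin.fitness, kind="stable")
            n, d, k = cfg.pop_size, cfg.dims, cfg.n_finders
            x_p = twin.positions[order[0]].copy()
            x_l = twin.positions[order[-1]].copy()
            for rank, idx in enumerate(order[k:], start=k + 1):
                x = twin.positions[idx].copy()
                if rank > 0.5 * n:
                    q = r2.standard_normal(d)
                    new = q * np.exp((x_l - x) / rank**2)
                else:
                    a = r2.integers(0, 2, size=d) * 2.0 - 1.0
                    new = x_p + np.sum(a * np.abs(x - x_p)) / d
                twin.positions[idx] = np.clip(new, cfg.lower_bounds, cfg.upper_bounds)
            assert_array_equal(pop.positions, twin.positions)


class TestScoutUpdate:
    def test_equal_fitness_guard_keeps_steps_finite(self, rng):
        cfg = make_cfg(pop_size=10, scout_fraction=0.2)
        pop = make_population(cfg, rng)
        pop.fitness[:] = 3.0  # f_i == f_g == f_w everywhere
        update_scouts(pop, cfg, rng)
        assert np.all(np.isfinite(pop.positions))
        assert np.all(pop.positions >= cfg.lower_bounds)
        assert np.all(pop.positions <= cfg.upper_bounds)

    def test_matches_scalar_oracle(self):
        cfg = make_cfg()
        for seed in range(6):
            pop = make_population(cfg, np.random.default_rng(seed))
            twin = Population(pop.positions.copy(), pop.fitness.copy())
            update_scouts(pop, cfg, rng=np.random.default_rng(300 + seed))

            r2 = np.random.default_rng(300 + seed)
            m = cfg.n_scouts
            chosen = r2.choice(cfg.pop_size, size=m, replace=False)
            b = int(np.argmin(twin.fitness))
            w = int(np.argmax(twin.fitness))
            x_b = twin.positions[b].copy()
            x_l = twin.positions[w].copy()
            f_g, f_w = twin.fitness[b], twin.fitness[w]
            for idx in chosen:
                x = twin.positions[idx].copy()
                f_i = twin.fitness[idx]
                if f_i > f_g:
                    beta = r2.standard_normal()
                    new = x_b + beta * np.abs(x - x_b)
                else:
                    kk = r2.uniform(-1.0, 1.0)
                    new = x + kk * (np.abs(x - x_l) / ((f_i - f_w) + cfg.denom_guard))
                twin.positions[idx] = np.clip(new, cfg.lower_bounds, cfg.upper_bounds)
            assert_array_equal(pop.positions, twin.positions)


class TestOptimize:
    def test_constant_objective(self):
        cfg = make_cfg(max_iters=5)
        res = optimize(lambda x: 2.5, cfg)
        assert res.best_fitness == 2.5
        assert np.all(res.history == 2.5)
        assert len(res.history) == cfg.max_iters

    def test_elitist_history_and_bounds_on_sphere(self):
        cfg = SsaConfig(dims=10, lower_bounds=-100, upper_bounds=100,
                        pop_size=30, max_iters=20, init_mode="logistic", seed=5)
        res = optimize(BENCHMARKS["F1"], cfg)
        assert np.all(np.diff(res.history) <= 0)
        assert res.best_fitness < 100.0
        assert np.all(np.abs(res.best_position) <= 100.0)
        assert res.evaluations == 30 * 21

    def test_deterministic_given_seed(self):
        cfg = make_cfg(seed=11)
        a = optimize(BENCHMARKS["F1"], cfg)
        b = optimize(BENCHMARKS["F1"], cfg)
        assert_array_equal(a.history, b.history)
        assert_array_equal(a.best_position, b.best_position)

    def test_degenerate_random_walk_trace_nonincreasing(self):
        """No scouts, everyone a finder: still an elitist archive."""
        cfg = make_cfg(scout_fraction=0.0, finder_fraction=1.0, safety_value=0.5, max_iters=30)
        res = optimize(BENCHMARKS["F1"], cfg)
        assert np.all(np.diff(res.history) <= 0)

    def test_nonfinite_objective_treated_as_inf(self):
        cfg = make_cfg(max_iters=3)

        def objective(x):
            return np.nan if x[0] > 0 else float(np.sum(x**2))

        with pytest.warns(UserWarning, match="non-finite"):
            res = optimize(objective, cfg)
        assert np.isfinite(res.best_fitness)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="pop_size"):
            make_cfg(pop_size=3)
        with pytest.raises(ValueError, match="safety_value"):
            make_cfg(safety_value=0.4)
        with pytest.raises(ValueError, match="scout_fraction"):
            make_cfg(scout_fraction=0.3)
        with pytest.raises(ValueError, match="lower_bounds"):
            make_cfg(lower_bounds=1.0, upper_bounds=-1.0)
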