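"""Unit and property tests for the falcon finch optimizer."""

import numpy as np
import pytest

from falconfinch import ffo
from falconfinch.ffo import (
    BesiegeParams,
    FFOConfig,
    FinchSwarm,
    StageDraws,
    besiege_update,
    evaluate_fitness,
    hard_besiege_move,
    initialize_swarm,
    optimize,
    perching_update,
    pinv_sign_row,
    producer_update,
    scrounger_update,
    soft_dive_move,
    step,
)
from falconfinch.objectives import rastrigin, sphere


def _draws(s=1, **kw):
    base = dict(
        T=0.3, z=0.7, p=0.7, beta=0.5, n_rand=0.5,
        n1=0.1, n2=0.2, n3=0.3, n4=0.4, e0=0.5, v=1.0, q=0.0,
        b=np.ones(s),
    )
    base.update(kw)
    return StageDraws(**base)


def _swarm_from(positions, fitnesses, config):
    positions = np.asarray(positions, dtype=float)
    fits = np.asarray(fitnesses, dtype=float)
    order = np.argsort(fits, kind="stable")
    positions, fits = positions[order], fits[order]
    best, worst = int(np.argmin(fits)), int(np.argmax(fits))
    return FinchSwarm(
        positions=positions,
        fitnesses=fits,
        best_position=positions[best].copy(),
        best_fitness=float(fits[best]),
        worst_position=positions[worst].copy(),
        worst_fitness=float(fits[worst]),
    )


class TestInitialization:
    def test_bounds_containment(self):
        cfg = FFOConfig(l=4, s=2, lower=0.0, upper=1.0, seed=5)
        swarm = initialize_swarm(cfg, np.random.default_rng(5))
        assert swarm.positions.shape == (4, 2)
        assert np.all((swarm.positions >= 0) & (swarm.positions <= 1))

    def test_degenerate_box(self):
        cfg = FFOConfig(l=3, s=2, lower=0.7, upper=0.7)
        swarm = initialize_swarm(cfg, np.random.default_rng(0))
        assert np.allclose(swarm.positions, 0.7)

    def test_determinism_under_seed(self):
        cfg = FFOConfig(l=30, s=5, lower=-2, upper=2, seed=7)
        a = initialize_swarm(cfg, np.random.default_rng(7)).positions
        b = initialize_swarm(cfg, np.random.default_rng(7)).positions
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("bad", [
        dict(lower=1.0, upper=0.0),
        dict(lower=np.nan),
        dict(producer_fraction=0.0),
        dict(p_alarm=1.5),
        dict(l=0),
    ])
    def test_invalid_config_rejected(self, bad):
        cfg = FFOConfig(**{**dict(l=4, s=2), **bad})
        with pytest.raises(ValueError):
            cfg.validate()


class TestEvaluateFitness:
    def test_known_minimum_becomes_best(self):
        cfg = FFOConfig(l=3, s=2, lower=-1, upper=1)
        swarm = initialize_swarm(cfg, np.random.default_rng(0))
        swarm.positions[1] = 0.0
        evaluate_fitness(swarm, sphere)
        assert swarm.best_fitness == 0.0
        np.testing.assert_array_equal(swarm.best_position, [0.0, 0.0])
        np.testing.assert_array_equal(swarm.positions[0], [0.0, 0.0])

    def test_matches_bruteforce_loop(self, rng):
        cfg = FFOConfig(l=12, s=4, lower=-3, upper=3)
        swarm = initialize_swarm(cfg, rng)
        expected = np.sort([sphere(row) for row in swarm.positions])
        evaluate_fitness(swarm, sphere)
        np.testing.assert_allclose(swarm.fitnesses, expected)

    def test_tie_break_stable_by_original_index(self):
        cfg = FFOConfig(l=3, s=1, lower=-2, upper=2)
        swarm = initialize_swarm(cfg, np.random.default_rng(0))
        swarm.positions = np.array([[1.0], [-1.0], [0.5]])
        evaluate_fitness(swarm, sphere)  # |1| == |-1| tie
        np.testing.assert_array_equal(swarm.positions.ravel(), [0.5, 1.0, -1.0])

    def test_nonfinite_objective_becomes_inf(self):
        cfg = FFOConfig(l=2, s=1, lower=-1, upper=1)
        swarm = initialize_swarm(cfg, np.random.default_rng(0))
        evaluate_fitness(swarm, lambda x: np.nan)
        assert np.all(np.isinf(swarm.fitnesses))


class TestProducerUpdate:
    def test_safe_branch_direct_value(self):
        # Y=2, s=1, beta=0.5, iter_max=10, T below alarm: 2*exp(-1/5)
        cfg = FFOConfig(l=2, s=1, iter_max=10, lower=0, upper=10)
        new = producer_update(np.array([2.0]), _draws(T=0.3, beta=0.5), cfg)
        np.testing.assert_allclose(new, [2.0 * np.exp(-0.2)], rtol=1e-12)
        assert round(float(new[0]), 5) == 1.63746

    def test_zero_normal_draw_annihilates(self):
        cfg = FFOConfig(l=2, s=3, iter_max=10, lower=-1, upper=1)
        new = producer_update(np.array([0.5, -0.5, 0.9]), _draws(s=3, T=0.7, n_rand=0.0), cfg)
        np.testing.assert_array_equal(new, np.zeros(3))

    def test_large_budget_limit_is_identity(self):
        cfg = FFOConfig(l=2, s=2, iter_max=10**9, lower=-5, upper=5)
        pos = np.array([1.5, -2.5])
        new = producer_update(pos, _draws(s=2, T=0.1, beta=0.9), cfg)
        np.testing.assert_allclose(new, pos, rtol=1e-6)

    def test_ssa_compat_additive_form(self):
        cfg = FFOConfig(l=2, s=2, iter_max=10, lower=-5, upper=5, ssa_compat=True)
        pos = np.array([1.0, 2.0])
        new = producer_update(pos, _draws(s=2, T=0.9, n_rand=0.25), cfg)
        np.testing.assert_allclose(new, pos + 0.25)


class TestScroungerUpdate:
    def test_nonstarving_at_optimum_returns_optimum(self):
        cfg = FFOConfig(l=6, s=2, lower=-5, upper=5)
        swarm = _swarm_from(np.tile([[1.0, 2.0]], (6, 1)), np.zeros(6), cfg)
        new = scrounger_update(swarm, rank=2, draws=_draws(s=2), config=cfg)
        np.testing.assert_array_equal(new, swarm.best_position)

    def test_starving_zero_normal_gives_zero(self):
        cfg = FFOConfig(l=4, s=2, lower=-5, upper=5)
        swarm = _swarm_from(np.arange(8.0).reshape(4, 2), [0, 1, 2, 3], cfg)
        new = scrounger_update(swarm, rank=4, draws=_draws(s=2, n_rand=0.0), config=cfg)
        np.testing.assert_array_equal(new, np.zeros(2))

    def test_starving_direct_value(self):
        # Y_worst=5, Y_fin=3, rank=2, N_rand=1: exp(2/4)
        cfg = FFOConfig(l=3, s=1, lower=-10, upper=10)
        swarm = _swarm_from([[0.0], [3.0], [5.0]], [0.0, 3.0, 5.0], cfg)
        new = scrounger_update(swarm, rank=2, draws=_draws(n_rand=1.0), config=cfg)
        np.testing.assert_allclose(new, [np.exp(0.5)], rtol=1e-12)
        assert round(float(new[0]), 5) == 1.64872

    def test_rank_zero_rejected(self):
        cfg = FFOConfig(l=3, s=1, lower=-1, upper=1)
        swarm = _swarm_from([[0.0], [0.1], [0.2]], [0, 1, 2], cfg)
        with pytest.raises(IndexError):
            scrounger_update(swarm, rank=0, draws=_draws(), config=cfg)


class TestBesiegeUpdate:
    def test_soft_mixture_collapse_to_scrounger_kernel(self):
        cfg = FFOConfig(l=4, s=2, lower=-10, upper=10, x1=1.0, x2=0.0, x3=0.0)
        swarm = _swarm_from(np.arange(8.0).reshape(4, 2), [0, 1, 2, 3], cfg)
        d = _draws(s=2, z=0.9, n_rand=0.7)
        got = besiege_update(swarm, rank=4, draws=d, config=cfg)
        expect = 0.7 * np.exp((swarm.worst_position - swarm.positions[3]) / 16.0)
        np.testing.assert_allclose(got, np.clip(expect, -10, 10))

    def test_hard_midpoint_limit(self):
        # E=0 (e0=0), Q=0: ½(Y_scr + Y_fin)
        cfg = FFOConfig(l=4, s=2, lower=-10, upper=10, iter_max=10)
        swarm = _swarm_from(np.arange(8.0).reshape(4, 2), [0, 1, 2, 3], cfg)
        d = _draws(s=2, z=0.1, e0=0.0, q=0.0)
        got = besiege_update(swarm, rank=4, draws=d, config=cfg)
        y_scr = swarm.positions[cfg.n_producers]
        np.testing.assert_allclose(got, 0.5 * (y_scr + swarm.positions[3]))

    def test_soft_dive_oracle_over_random_draws(self, rng):
        # all reference points coincident at c: M = ½[c + T·c·|V−1| + c + 0]
        cfg = FFOConfig(l=4, s=3, lower=-100, upper=100, lam=0.5)
        c = 2.0
        swarm = _swarm_from(np.full((4, 3), c), np.zeros(4), cfg)
        for _ in range(20):
            d = _draws(s=3, T=rng.random(), v=rng.uniform(0, 2))
            got = soft_dive_move(swarm, 4, d, cfg)
            oracle = 0.5 * (c + d.T * abs(d.v * c - c) + c)
            np.testing.assert_allclose(got, np.full(3, oracle), rtol=1e-12)

    def test_hard_denominator_floored_when_degenerate(self):
        cfg = FFOConfig(l=4, s=1, lower=-1e6, upper=1e6, iter_max=10)
        swarm = _swarm_from([[1.0], [2.0], [3.0], [4.0]], np.zeros(4), cfg)
        d = _draws(z=0.1, q=1.0, e0=0.3)
        got = hard_besiege_move(swarm, 4, d, cfg)
        assert np.all(np.isfinite(got))

    def test_dive_taken_only_when_it_improves(self):
        cfg = FFOConfig(l=4, s=2, lower=-10, upper=10, iter_max=10)
        swarm = _swarm_from(np.arange(8.0).reshape(4, 2), [0, 1, 2, 3], cfg)
        d = _draws(s=2, z=0.9)
        base = besiege_update(swarm, 4, d, cfg, objective=None)
        chosen = besiege_update(swarm, 4, d, cfg, objective=sphere)
        dive = np.clip(soft_dive_move(swarm, 4, d, cfg), -10, 10)
        if sphere(dive) < sphere(base):
            np.testing.assert_array_equal(chosen, dive)
        else:
            np.testing.assert_array_equal(chosen, base)


class TestPerchingUpdate:
    def test_attack_term_vanishes(self):
        cfg = FFOConfig(l=3, s=2, iter_max=50, lower=-10, upper=10)
        swarm = _swarm_from([[1.0, 2.0], [3.0, 1.0], [2.0, 2.0]], [0, 1, 2], cfg)
        d = _draws(s=2, T=0.2, p=0.8, n1=0.0)
        got = perching_update(swarm, 1, d, cfg)
        i = np.arange(1, 3)
        expect = 0.5 * swarm.positions[0] * np.exp(-i / 50) + 0.5 * swarm.best_position
        np.testing.assert_allclose(got, expect)

    def test_bound_repulsion_vanishes(self):
        cfg = FFOConfig(l=3, s=2, iter_max=50, lower=-10, upper=10)
        swarm = _swarm_from([[1.0, 2.0], [3.0, 1.0], [2.0, 2.0]], [0, 1, 2], cfg)
        d = _draws(s=2, T=0.2, p=0.1, n3=0.0, n_rand=0.0)
        got = perching_update(swarm, 2, d, cfg)
        expect = 0.5 * swarm.positions[1] + 0.5 * (swarm.best_position - swarm.mean_position)
        np.testing.assert_allclose(got, expect)

    def test_hand_evaluated_full_form(self):
        # s=1: Y_fin=1, Y_prey=0.2, Y_avg=0.5, bounds [0,1], n3=.5, n4=.4 -> 0.25
        cfg = FFOConfig(l=3, s=1, iter_max=50, lower=0.0, upper=1.0)
        swarm = _swarm_from([[0.2], [1.0], [0.3]], [0.0, 2.0, 1.0], cfg)
        assert swarm.mean_position[0] == pytest.approx(0.5)
        d = _draws(T=0.2, p=0.1, n3=0.5, n4=0.4, n_rand=0.0)
        got = perching_update(swarm, 3, d, cfg)  # row 3 holds Y_fin = 1.0
        np.testing.assert_allclose(got, [0.25])


class TestStepAndOptimize:
    def test_elitist_and_bounded_step(self):
        cfg = FFOConfig(l=10, s=3, iter_max=20, lower=-4, upper=4, seed=2)
        rng = np.random.default_rng(2)
        swarm = initialize_swarm(cfg, rng)
        evaluate_fitness(swarm, rastrigin)
        before = swarm.best_fitness
        step(swarm, rastrigin, cfg, rng)
        assert swarm.best_fitness <= before
        assert np.all((swarm.positions >= -4) & (swarm.positions <= 4))

    def test_sphere_convergence(self):
        cfg = FFOConfig(l=30, s=2, iter_max=200, lower=-5, upper=5, seed=11)
        res = optimize(sphere, cfg)
        assert res.best_fitness < 1e-3

    def test_history_non_increasing_and_reproducible(self):
        cfg = FFOConfig(l=15, s=3, iter_max=50, lower=-5, upper=5, seed=9)
        r1 = optimize(rastrigin, cfg)
        r2 = optimize(rastrigin, cfg)
        assert np.all(np.diff(r1.convergence_history) <= 0)
        np.testing.assert_array_equal(r1.convergence_history, r2.convergence_history)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)

    def test_zero_iterations_returns_initial_best(self):
        cfg = FFOConfig(l=10, s=2, iter_max=0, lower=-5, upper=5, seed=4)
        res = optimize(sphere, cfg)
        swarm = initialize_swarm(cfg, np.random.default_rng(4))
        expect = min(sphere(row) for row in swarm.positions)
        assert res.best_fitness == pytest.approx(expect)
        assert len(res.convergence_history) == 0

    def test_initial_guess_never_worsened(self):
        guess = np.array([0.01, -0.01])
        cfg = FFOConfig(l=8, s=2, iter_max=5, lower=-5, upper=5, seed=3)
        res = optimize(sphere, cfg, initial_guess=guess)
        assert res.best_fitness <= sphere(guess)

    def test_rastrigin_beats_random_search(self):
        budget_wins = 0
        for seed in range(10):
            cfg = FFOConfig(l=20, s=2, iter_max=40, lower=-5.12, upper=5.12, seed=seed)
            res = optimize(rastrigin, cfg)
            rng = np.random.default_rng(seed + 500)
            xs = rng.uniform(-5.12, 5.12, (res.evaluations, 2))
            rand_best = min(rastrigin(x) for x in xs)
            budget_wins += res.best_fitness < rand_best
        assert budget_wins >= 8


class TestInvariants:
    def test_pinv_sign_row_closed_form(self, rng):
        for s in (1, 3, 8, 50):
            b = np.where(rng.random(s) < 0.5, -1.0, 1.0)
            explicit = b[:, None] @ np.linalg.inv(b[None, :] @ b[:, None])
            np.testing.assert_allclose(pinv_sign_row(b), explicit.ravel(), rtol=1e-12)

    def test_escape_energy_zero_at_final_iteration(self):
        d = _draws(e0=0.9)
        assert ffo._escape_energy(d, iteration=50, iter_max=50) == 0.0

    def test_mean_position_matches_bruteforce(self, rng):
        cfg = FFOConfig(l=7, s=4, lower=-2, upper=2)
        swarm = initialize_swarm(cfg, rng)
        brute = np.array([swarm.positions[:, j].sum() / 7 for j in range(4)])
        np.testing.assert_allclose(swarm.mean_position, brute, rtol=1e-12)

    def test_random_configs_bounds_elitism_determinism(self):
        # 100 randomized cases: feasibility, elitism, seed determinism
        meta = np.random.default_rng(2024)
        for case in range(100):
            l = int(meta.integers(4, 12))
            s = int(meta.integers(1, 5))
            lo = meta.uniform(-5, 0, s)
            hi = lo + meta.uniform(0.5, 5, s)
            seed = int(meta.integers(0, 2**31))
            cfg = FFOConfig(l=l, s=s, iter_max=3, lower=lo, upper=hi, seed=seed)
            r1 = optimize(sphere, cfg)
            assert np.all(np.diff(r1.convergence_history) <= 0)
            assert np.all((r1.best_position >= lo) & (r1.best_position <= hi))
            if case % 10 == 0:
                r2 = optimize(sphere, cfg)
                np.testing.assert_array_equal(
                    r1.convergence_history, r2.convergence_history
                )


def _ssa_oracle(objective, config):
    """Standalone sparrow-search loop, written independently of `step`.

    Shares only the StageDraws sampling protocol (the declared RNG
    contract) with the implementation under test.
    """
    rng = np.random.default_rng(config.seed)
    lb, ub = config.lb, config.ub
    pos = lb + (ub - lb) * rng.random((config.l, config.s))
    fit = np.array([objective(p) for p in pos])
    order = np.argsort(fit, kind="stable")
    pos, fit = pos[order], fit[order]
    best_x, best_f = pos[0].copy(), float(fit[0])
    worst_x = pos[-1].copy()
    history = []
    n_prod = config.n_producers
    for _ in range(config.iter_max):
        for r in range(config.l):
            d = StageDraws.sample(rng, config.s)
            y = pos[r]
            if r < n_prod:
                if d.T < config.p_alarm:
                    i = np.arange(1, config.s + 1)
                    cand = y * np.exp(-i / (d.beta * config.iter_max))
                else:
                    cand = y * d.n_rand
            else:
                rank = r + 1
                if rank > config.l / 2:
                    cand = d.n_rand * np.exp((worst_x - y) / rank**2)
                else:
                    cand = best_x + float(np.abs(y - best_x) @ (d.b / config.s))
            cand = np.clip(cand, lb, ub)
            f_new = objective(cand)
            if f_new < fit[r]:
                pos[r], fit[r] = cand, f_new
            if r == n_prod - 1:  # producers done: refresh the optimum
                rb = int(np.argmin(fit))
                if fit[rb] <= best_f:
                    best_f, best_x = float(fit[rb]), pos[rb].copy()
        rb = int(np.argmin(fit))
        if fit[rb] <= best_f:
            best_f, best_x = float(fit[rb]), pos[rb].copy()
        order = np.argsort(fit, kind="stable")
        pos, fit = pos[order], fit[order]
        worst_x = pos[-1].copy()
        history.append(best_f)
    return np.array(history)


class TestReducedModeEquivalence:
    def test_matches_standalone_sparrow_search_oracle(self):
        for seed in range(10):
            cfg = FFOConfig(
                l=10, s=3, iter_max=15, lower=-5, upper=5, seed=seed,
                enable_besiege=False, enable_perching=False,
            )
            res = optimize(sphere, cfg)
            oracle = _ssa_oracle(sphere, cfg)
            np.testing.assert_array_equal(res.convergence_history, oracle)

    def test_pure_producer_mode_matches_oracle(self):
        # producer_fraction=1: every individual follows the foraging rule
        for seed in range(3):
            cfg = FFOConfig(
                l=6, s=2, iter_max=10, lower=-3, upper=3, seed=seed,
                producer_fraction=1.0, enable_besiege=False, enable_perching=False,
            )
            res = optimize(sphere, cfg)
            oracle = _ssa_oracle(sphere, cfg)
            np.testing.assert_array_equal(res.convergence_history, oracle)


class TestConfigRoundTrip:
    def test_yaml_round_trip(self, tmp_path):
        cfg = FFOConfig(l=9, s=3, iter_max=7, lower=[-1, -2, -3], upper=[1, 2, 3],
                        seed=42, lam=0.7, besiege=BesiegeParams(v_max=1.5))
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = FFOConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back.l == 9 and back.s == 3 and back.lam == 0.7
        assert back.besiege.v_max == 1.5
        np.testing.assert_array_equal(back.lb, [-1, -2, -3])

    def test_result_serialization(self, tmp_path):
        cfg = FFOConfig(l=6, s=2, iter_max=4, lower=-1, upper=1, seed=0)
        res = optimize(sphere, cfg)
        res.to_json(tmp_path / "res.json")
        res.history_to_csv(tmp_path / "hist.csv")
        import json

        payload = json.loads((tmp_path / "res.json").read_text())
        assert payload["best_fitness"] == res.best_fitness
        assert len(payload["convergence_history"]) == 4
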