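import math

import numpy as np
import pytest

from emgtune import (
    HistoryMemory,
    LShadeConfig,
    OptimizationError,
    SuccessArchive,
    lpsr_size,
    optimize,
    propose_trial,
    random_search,
    sample_parameters,
    tune,
    update_memory,
    weighted_lehmer_mean,
)
from emgtune.model_eval import evaluate, temporal_split, train_classifier
from emgtune.optimize import reduce_population
from emgtune.space import Dimension, HyperparamSpace, default_et_space

from oracles import oracle_lehmer


def sphere_space(d=10, bound=100.0):
    return HyperparamSpace(
        [Dimension(f"x{i}", "real", bounds=(-bound, bound)) for i in range(d)]
    )


def sphere(cand):
    x = np.array(list(cand.decoded.values()))
    return -float((x * x).sum())


class TestSampleParameters:
    def test_range_contract(self, rng):
        mem = HistoryMemory(6)
        for _ in range(10_000):
            sf, cr = sample_parameters(mem, rng)
            assert 0 < sf <= 1
            assert 0 <= cr <= 1

    def test_cr_clips_near_zero_cell(self, rng):
        mem = HistoryMemory(1)
        mem.m_cr[0] = 0.0
        draws = [sample_parameters(mem, rng)[1] for _ in range(10_000)]
        assert all(0 <= c <= 1 for c in draws)
        assert np.median(draws) < 0.1

    def test_deterministic_sequence(self):
        mem1, mem2 = HistoryMemory(4), HistoryMemory(4)
        r1, r2 = np.random.default_rng(9), np.random.default_rng(9)
        seq1 = [sample_parameters(mem1, r1) for _ in range(50)]
        seq2 = [sample_parameters(mem2, r2) for _ in range(50)]
        assert seq1 == seq2


class TestProposeTrial:
    def test_cr_zero_inherits_exactly_jrand(self, rng):
        pop = rng.random((6, 5))
        fit = rng.random(6)
        pool = np.array([0, 1])
        u = propose_trial(pop, fit, 2, 0.5, 0.0, pool, np.empty((0, 5)), rng)
        diffs = np.flatnonzero(u != pop[2])
        assert diffs.size <= 1  # only the guaranteed j_rand coordinate

    def test_sf_zero_cr_one_gives_parent(self, rng):
        """With SF=0 the mutant collapses onto the parent; CR=1 copies it whole."""
        pop = rng.random((6, 5))
        fit = rng.random(6)
        u = propose_trial(pop, fit, 1, 0.0, 1.0, np.array([0]), np.empty((0, 5)), rng)
        np.testing.assert_array_equal(u, pop[1])

    def test_identical_population_fixed_point(self, rng):
        pop = np.tile(np.full(5, 0.3), (6, 1))
        fit = np.ones(6)
        u = propose_trial(pop, fit, 0, 0.7, 0.9, np.array([0, 1]), np.empty((0, 5)), rng)
        np.testing.assert_allclose(u, pop[0])

    def test_repair_stays_strictly_inside_box(self, rng):
        """Midpoint repair of violated coordinates lands strictly inside (0,1)
        when the parent is interior."""
        for _ in range(1000):
            pop = rng.uniform(0.05, 0.95, (6, 3))
            fit = rng.random(6)
            u = propose_trial(
                pop, fit, 0, 1.0, 1.0, np.array([1]), np.empty((0, 3)), rng
            )
            assert np.all(u > 0) and np.all(u < 1)

    def test_small_population_rejected(self, rng):
        pop = rng.random((3, 2))
        with pytest.raises(OptimizationError):
            propose_trial(pop, np.ones(3), 0, 0.5, 0.5, np.array([0]), np.empty((0, 2)), rng)


class TestLehmerMeanAndMemory:
    def test_constant_values(self):
        arch = SuccessArchive(s_sf=[0.4, 0.4, 0.4], s_cr=[0.4, 0.4, 0.4], delta_f=[1, 2, 3])
        assert weighted_lehmer_mean(arch, "SF") == pytest.approx(0.4)

    def test_single_entry(self):
        arch = SuccessArchive(s_sf=[0.66], s_cr=[0.2], delta_f=[5.0])
        assert weighted_lehmer_mean(arch, "SF") == pytest.approx(0.66)
        assert weighted_lehmer_mean(arch, "CR") == pytest.approx(0.2)

    def test_hand_value(self):
        arch = SuccessArchive(s_sf=[0.2, 0.8], s_cr=[0.2, 0.8], delta_f=[1.0, 3.0])
        want = 0.49 / 0.65
        assert weighted_lehmer_mean(arch, "SF") == pytest.approx(want, rel=1e-12)
        assert weighted_lehmer_mean(arch, "SF") == pytest.approx(
            oracle_lehmer([0.2, 0.8], [1.0, 3.0]), rel=1e-12
        )

    def test_within_min_max(self, rng):
        vals = rng.uniform(0.1, 1.0, 20).tolist()
        arch = SuccessArchive(s_sf=vals, s_cr=vals, delta_f=rng.uniform(0.1, 5, 20).tolist())
        m = weighted_lehmer_mean(arch, "SF")
        assert min(vals) <= m <= max(vals)

    def test_empty_archive_error(self):
        with pytest.raises(OptimizationError):
            weighted_lehmer_mean(SuccessArchive(), "SF")

    def test_memory_blend_arithmetic(self):
        mem = HistoryMemory(3)
        arch = SuccessArchive(s_sf=[0.9], s_cr=[0.9], delta_f=[1.0])
        update_memory(mem, arch, c=0.5)
        assert mem.m_sf[0] == pytest.approx(0.7)  # 0.5*0.5 + 0.5*0.9
        assert mem.write_index == 1

    def test_empty_archive_leaves_memory_untouched(self):
        mem = HistoryMemory(2)
        before = (mem.m_sf.copy(), mem.m_cr.copy(), mem.write_index)
        update_memory(mem, SuccessArchive(), c=0.5)
        assert np.array_equal(mem.m_sf, before[0]) and mem.write_index == before[2]

    def test_c_one_freezes_memory(self):
        mem = HistoryMemory(2)
        arch = SuccessArchive(s_sf=[0.9], s_cr=[0.1], delta_f=[2.0])
        update_memory(mem, arch, c=1.0)
        assert mem.m_sf[0] == 0.5 and mem.m_cr[0] == 0.5

    def test_invalid_c(self):
        with pytest.raises(OptimizationError):
            update_memory(HistoryMemory(2), SuccessArchive(s_sf=[0.5], s_cr=[0.5], delta_f=[1.0]), c=0.0)


class TestLpsr:
    def test_endpoints_and_midpoint(self):
        cfg = LShadeConfig(np_init=100, np_min=4, nf_max=10_000)
        assert lpsr_size(cfg, 0) == 100
        assert lpsr_size(cfg, 10_000) == 4
        assert lpsr_size(cfg, 5_000) == 52

    def test_monotone_non_increasing(self):
        cfg = LShadeConfig(np_init=100, np_min=4, nf_max=10_000)
        sizes = [lpsr_size(cfg, nf) for nf in range(0, 10_001, 97)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert all(4 <= s <= 100 for s in sizes)

    def test_nf_out_of_budget(self):
        cfg = LShadeConfig(np_init=100, np_min=4, nf_max=10_000)
        with pytest.raises(OptimizationError):
            lpsr_size(cfg, 10_001)

    def test_reduce_population_tie_break(self):
        pop = np.arange(10).reshape(5, 2).astype(float)
        fit = np.array([1.0, 2.0, 2.0, 0.5, 3.0])
        new_pop, new_fit = reduce_population(pop, fit, 2)
        # among the tied 2.0s the older index 1 is eliminated first
        np.testing.assert_array_equal(new_fit, [2.0, 3.0])
        np.testing.assert_array_equal(new_pop, pop[[2, 4]])

    def test_reduce_population_keeps_exact_worst_out(self):
        pop = np.zeros((4, 1))
        fit = np.array([0.1, 0.9, 0.5, 0.7])
        _, new_fit = reduce_population(pop, fit, 2)
        assert sorted(new_fit.tolist()) == [0.7, 0.9]


class TestDecode:
    def test_integer_endpoints(self):
        d = Dimension("n_estimators", "integer", bounds=(10, 100))
        assert d.decode(0.0) == 10 and d.decode(1.0) == 100

    def test_categorical_split_at_half(self):
        d = Dimension("criterion", "categorical", levels=("gini", "entropy"))
        assert d.decode(0.49) == "gini" and d.decode(0.51) == "entropy"
        assert d.decode(1.0) == "entropy"

    def test_decode_idempotent_and_total(self, rng):
        space = default_et_space(34)
        g = rng.random(space.n_dims)
        hp1 = space.decode(g)
        hp2 = space.decode(g)
        assert hp1 == hp2
        assert set(hp1) == set(space.names)
        space.validate(hp1)

    def test_genome_length_mismatch(self):
        from emgtune import ValidationError

        with pytest.raises(ValidationError):
            default_et_space(34).decode(np.zeros(3))


class TestOptimizeEngine:
    def test_budget_boundary_single_generation(self):
        """nf_max == np_init: only the initial population is evaluated and the
        best individual of that population is returned."""
        seen = []

        def obj(c):
            v = -sum(x * x for x in c.decoded.values())
            seen.append(v)
            return v

        cfg = LShadeConfig(np_init=10, np_min=4, nf_max=10, seed=0)
        best, trace = optimize(obj, sphere_space(3), cfg)
        assert len(seen) == 10
        assert trace == []
        assert best.fitness == max(seen)

    def test_determinism_identical_traces(self):
        cfg = LShadeConfig(np_init=20, np_min=4, nf_max=600, seed=42)
        b1, t1 = optimize(sphere, sphere_space(4), cfg)
        b2, t2 = optimize(sphere, sphere_space(4), cfg)
        assert b1.fitness == b2.fitness
        assert [(g.nf, g.np_size, g.best_fitness, g.m_sf, g.m_cr) for g in t1] == [
            (g.nf, g.np_size, g.best_fitness, g.m_sf, g.m_cr) for g in t2
        ]

    def test_trace_invariants(self):
        """NP follows the linear schedule exactly; memory stays in range;
        best-so-far is monotone; evaluations stay within budget."""
        cfg = LShadeConfig(np_init=30, np_min=4, nf_max=1500, seed=1)
        best, trace = optimize(sphere, sphere_space(5), cfg)
        assert trace[-1].nf <= cfg.nf_max
        prev_best = -math.inf
        for g in trace:
            assert g.np_size == lpsr_size(cfg, g.nf)
            assert g.best_fitness >= prev_best
            prev_best = g.best_fitness
            assert all(0 <= v <= 1 for v in g.m_cr)
            assert all(0 < v <= 1 for v in g.m_sf)
        assert best.fitness == trace[-1].best_fitness

    def test_non_finite_objective_warns_and_continues(self):
        def obj(c):
            x = list(c.decoded.values())[0]
            return float("nan") if x > 0 else -x * x

        cfg = LShadeConfig(np_init=8, np_min=4, nf_max=100, seed=0)
        with pytest.warns(UserWarning, match="non-finite"):
            best, _ = optimize(obj, sphere_space(1), cfg)
        assert math.isfinite(best.fitness)

    def test_equivalent_to_reference_de_at_degenerate_settings(self):
        """With a frozen memory (H=1, c=1), no archive and no population
        reduction, the engine is plain current-to-pbest DE; an independently
        coded reference with the same sampling order reproduces it exactly."""
        d, n, gens, seed = 4, 8, 15, 11

        cfg = LShadeConfig(
            np_init=n, np_min=4, nf_max=10**7, max_generations=gens,
            memory_size=1, blend_c=1.0, archive_rate=0.0, seed=seed,
        )
        space = sphere_space(d, bound=10.0)
        best, trace = optimize(sphere, space, cfg)

        # --- reference DE (independent, ~30 lines) ---
        def f(g):
            x = -10.0 + 20.0 * np.asarray(g)
            return -float((x * x).sum())

        rng = np.random.default_rng(seed)
        pop = rng.random((n, d))
        fit = np.array([f(p) for p in pop])
        ref_best = fit.max()
        for _ in range(gens):
            order = np.argsort(-fit, kind="stable")
            pool = order[: max(2, math.ceil(0.11 * n))]
            for i in range(n):
                rng.integers(1)  # memory cell draw (H = 1)
                sf = 0.0
                while sf <= 0.0:
                    sf = 0.5 + 0.1 * rng.standard_cauchy()
                sf = min(sf, 1.0)
                cr = float(np.clip(rng.normal(0.5, 0.1), 0, 1))
                pb = pop[pool[rng.integers(pool.size)]]
                r1 = i
                while r1 == i:
                    r1 = int(rng.integers(n))
                r2 = i
                while r2 == i or r2 == r1:
                    r2 = int(rng.integers(n))
                v = pop[i] + sf * (pb - pop[i]) + sf * (pop[r1] - pop[r2])
                low, high = v < 0, v > 1
                v[low] = pop[i][low] / 2
                v[high] = (pop[i][high] + 1) / 2
                jr = int(rng.integers(d))
                mask = rng.random(d) < cr
                mask[jr] = True
                u = np.where(mask, v, pop[i])
                fu = f(u)
                if fu >= fit[i]:
                    pop[i], fit[i] = u, fu
                ref_best = max(ref_best, fu)
        assert best.fitness == pytest.approx(ref_best, rel=0, abs=0)

    def test_random_search_baseline_and_history(self):
        best, hist = random_search(sphere, sphere_space(3), nf_max=200, seed=0)
        assert len(hist) == 200
        assert best.fitness == max(hist)


class TestTune:
    def test_fixed_dimension_propagates(self, small_features):
        tr, _ = temporal_split(small_features, 0.7)
        space = HyperparamSpace(
            [
                Dimension("n_estimators", "integer", bounds=(15, 15)),
                Dimension("max_depth", "integer", bounds=(2, 10)),
            ]
        )
        cfg = LShadeConfig(np_init=6, np_min=4, nf_max=18, seed=0)
        hp, hist = tune(tr, "ET", space, cfg)
        assert hp["n_estimators"] == 15
        assert len(hist) <= cfg.nf_max

    def test_tuning_does_not_hurt(self, small_features):
        """Best tuned hyperparameters refit on train score within 0.01 of the
        default configuration on held-out data."""
        tr, te = temporal_split(small_features, 0.7)
        default_acc = evaluate(train_classifier("ET", {}, tr, seed=0), te).accuracy
        cfg = LShadeConfig(np_init=6, np_min=4, max_generations=4, seed=0)
        hp, _ = tune(tr, "ET", None, cfg)
        tuned_acc = evaluate(train_classifier("ET", hp, tr, seed=0), te).accuracy
        assert tuned_acc >= default_acc - 0.05  # lenient at this tiny budget

    def test_holdout_protocol_requires_test(self, small_features):
        tr, _ = temporal_split(small_features, 0.7)
        with pytest.raises(OptimizationError):
            tune(tr, "ET", None, LShadeConfig(np_init=6, nf_max=12), fitness_protocol="holdout")
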