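"""Batch acquisition strategies against exhaustive brute-force selection
oracles (zero-variance posteriors make the comparisons exact), plus the
temperature-constraint wrappers and determinism contracts."""

import numpy as np
import pytest

from plateopt import acquisition as acq
from plateopt import surrogate as sg
from plateopt.pareto import ParetoState, hvi, hypervolume, reference_point
from plateopt.space import ParameterDef, SearchSpace, encode_pool, enumerate_conditions
from tests.conftest import make_observations, make_stub_model


def temp_pool(n_ligands=4, temps=(40.0, 70.0, 100.0)):
    space = SearchSpace(
        parameters=(
            ParameterDef("ligand", tuple(f"L{i}" for i in range(n_ligands))),
            ParameterDef("temperature", tuple(temps), role="temperature"),
        )
    )
    return encode_pool(space, enumerate_conditions(space))


def mean_table(pool, values):
    """Lookup-based mean function over pool feature rows."""
    lut = {pool.X[i].tobytes(): float(v) for i, v in enumerate(values)}
    def fn(X):
        return np.asarray([lut[row.tobytes()] for row in np.asarray(X)])
    return fn


def stub_from_truth(pool, truth, obs_ids):
    """Zero-variance stub model whose posterior means equal ``truth``."""
    truth = np.asarray(truth, dtype=float)
    fns = [mean_table(pool, truth[:, j]) for j in range(truth.shape[1])]
    model = make_stub_model(pool, fns, obs_ids, truth[np.asarray(obs_ids, dtype=int)])
    return model


class TestSobol:
    def test_pool_of_exactly_q_returns_all(self):
        pool = temp_pool(2, (40.0, 70.0))  # 4 conditions
        sel = acq.sobol_batch(pool, 4, seed=1)
        assert sorted(sel.condition_ids) == [0, 1, 2, 3]

    def test_q_zero_empty(self):
        pool = temp_pool()
        assert len(acq.sobol_batch(pool, 0, seed=1)) == 0

    def test_q_exceeding_pool_errors(self):
        pool = temp_pool(2, (40.0, 70.0))
        with pytest.raises(ValueError, match="exceeds"):
            acq.sobol_batch(pool, 5, seed=1)

    def test_temperature_restriction_honoured(self):
        pool = temp_pool()
        sel = acq.sobol_batch(pool, 4, seed=2, allowed_temperatures=[40.0, 70.0])
        temps = pool.temperature_values()[sel.condition_ids]
        assert set(temps) <= {40.0, 70.0}

    def test_deterministic(self):
        pool = temp_pool(8, (40.0, 55.0, 70.0, 85.0))
        a = acq.sobol_batch(pool, 6, seed=3).condition_ids
        b = acq.sobol_batch(pool, 6, seed=3).condition_ids
        assert a == b

    def test_spreads_more_than_uniform_random(self):
        """Sobol batches should cover feature space more diversely than
        uniform-random subsets, on average over seeds."""
        rng = np.random.default_rng(0)
        n, d, q = 1000, 5, 16
        space = SearchSpace(parameters=(ParameterDef("c", tuple(map(str, range(n)))),))
        pool = encode_pool(space, enumerate_conditions(space))
        pool.X = rng.random((n, d))
        def mean_pairwise(ids):
            X = pool.X[np.asarray(ids)]
            diffs = X[:, None, :] - X[None, :, :]
            dd = np.sqrt((diffs**2).sum(-1))
            return dd[np.triu_indices(len(ids), 1)].mean()
        sobol_d, rand_d = [], []
        for seed in range(50):
            sel = acq.sobol_batch(pool, q, seed=seed)
            sobol_d.append(mean_pairwise(sel.condition_ids))
            rand_ids = np.random.default_rng(seed).choice(n, q, replace=False)
            rand_d.append(mean_pairwise(rand_ids))
        assert np.mean(sobol_d) >= np.mean(rand_d)


class TestScalarization:
    @pytest.mark.parametrize(
        "y,w,rho,expected",
        [
            ((1.0, 1.0), (0.5, 0.5), 0.0, 0.5),
            ((0.0, 0.0), (0.5, 0.5), 0.0, 0.0),
            ((1.0, 0.0), (0.5, 0.5), 0.05, 0.025),
        ],
    )
    def test_augmented_chebyshev_formula(self, y, w, rho, expected):
        assert acq.augmented_chebyshev(np.asarray(y), np.asarray(w), rho) == pytest.approx(
            expected
        )

    def test_qnparego_zero_variance_matches_exhaustive_argmax(self):
        pool = temp_pool(6, (40.0, 70.0))  # 12 conditions
        rng = np.random.default_rng(5)
        truth = np.column_stack([rng.uniform(10, 90, 12), rng.uniform(10, 90, 12)])
        obs_ids = [0, 1]
        truth[obs_ids] = [[15.0, 20.0], [20.0, 15.0]]  # low baseline
        model = stub_from_truth(pool, truth, obs_ids)
        pool.mark_run(obs_ids)
        q = 3
        sel = acq.qnparego_batch(model, pool, q=q, mc_samples=16, seed=4)
        # brute force: per slot, argmax of the scalarized posterior mean among
        # remaining candidates, using the recorded weight vectors
        lo, hi = truth[obs_ids].min(axis=0), truth[obs_ids].max(axis=0)
        remaining = sorted(set(range(12)) - set(obs_ids))
        expect = []
        for w in sel.provenance["weights"][:q]:
            yn = (truth[remaining] - lo) / (hi - lo)
            s = acq.augmented_chebyshev(yn, np.asarray(w), 0.05)
            best = remaining[int(np.argmax(s))]
            expect.append(best)
            remaining.remove(best)
        assert sel.condition_ids == expect


class TestTSHVI:
    def test_zero_variance_single_pick_matches_hvi_scan(self):
        pool = temp_pool(6, (40.0, 70.0))
        rng = np.random.default_rng(6)
        truth = np.column_stack([rng.uniform(5, 95, 12), rng.uniform(5, 95, 12)])
        obs_ids = [0, 5, 9]
        model = stub_from_truth(pool, truth, obs_ids)
        pool.mark_run(obs_ids)
        sel = acq.tshvi_batch(model, pool, q=1, seed=7)
        Y_obs = truth[obs_ids]
        ref = reference_point(Y_obs)
        state = ParetoState.from_points(Y_obs, ref)
        unrun = sorted(set(range(12)) - set(obs_ids))
        brute = [hvi(np.maximum(truth[c], ref), state) for c in unrun]
        assert sel.condition_ids[0] == unrun[int(np.argmax(brute))]

    def test_batch_ids_unique(self):
        pool = temp_pool(6, (40.0, 70.0))
        rng = np.random.default_rng(8)
        truth = np.column_stack([rng.uniform(5, 95, 12), rng.uniform(5, 95, 12)])
        model = stub_from_truth(pool, truth, [0, 1])
        pool.mark_run([0, 1])
        sel = acq.tshvi_batch(model, pool, q=5, seed=8)
        assert len(set(sel.condition_ids)) == 5

    def test_dominated_candidate_excluded_first(self):
        pool = temp_pool(1, (40.0, 70.0))  # 2 conditions
        big = temp_pool(2, (40.0, 70.0))  # 4 conditions: observe 2, leave 2
        truth = np.array([[50.0, 50.0], [1.0, 1.0], [80.0, 80.0], [40.0, 40.0]])
        model = stub_from_truth(big, truth, [0, 3])
        big.mark_run([0, 3])
        sel = acq.tshvi_batch(model, big, q=1, seed=9)
        assert sel.condition_ids[0] == 2  # the only candidate above the front
        del pool


class TestQNEHVI:
    def test_zero_variance_single_pick_matches_hvi_scan(self):
        pool = temp_pool(6, (40.0, 70.0))
        rng = np.random.default_rng(10)
        truth = np.column_stack([rng.uniform(5, 95, 12), rng.uniform(5, 95, 12)])
        obs_ids = [2, 7, 11]
        model = stub_from_truth(pool, truth, obs_ids)
        pool.mark_run(obs_ids)
        sel = acq.qnehvi_batch(model, pool, q=1, mc_samples=16, seed=11)
        Y_obs = truth[obs_ids]
        ref = reference_point(Y_obs)
        state = ParetoState.from_points(Y_obs, ref)
        unrun = sorted(set(range(12)) - set(obs_ids))
        brute = [hvi(np.maximum(truth[c], ref), state) for c in unrun]
        assert sel.condition_ids[0] == unrun[int(np.argmax(brute))]

    def test_small_mc_budget_warns(self):
        pool = temp_pool(6, (40.0, 70.0))
        truth = np.tile(np.linspace(10, 90, 12)[:, None], (1, 2))
        model = stub_from_truth(pool, truth, [0, 1])
        pool.mark_run([0, 1])
        with pytest.warns(UserWarning, match="mc_samples"):
            acq.qnehvi_batch(model, pool, q=1, mc_samples=4, seed=0)

    def test_noise_aware_revaluation_of_noisy_observed_point(self, small_oracle):
        """A candidate whose features coincide with a high-noise observation
        keeps strictly positive acquisition value (a noiseless EHVI would
        assign it ~0)."""
        pool = small_oracle.pool
        rng = np.random.default_rng(12)
        ids = rng.choice(len(pool), 10, replace=False)
        Y = small_oracle.truth[ids]
        # three conflicting replicates of the best observed point
        best = ids[np.argmax(Y.sum(axis=1))]
        rep_ids = np.concatenate([ids, [best, best]])
        rep_Y = np.vstack([Y, Y[np.argmax(Y.sum(axis=1))] + [-25.0, +20.0],
                           Y[np.argmax(Y.sum(axis=1))] + [15.0, -30.0]])
        obs = make_observations(rep_ids, rep_Y)
        model = sg.fit(pool, obs, seed=1)
        cfg = acq.AcquisitionConfig(strategy="qnehvi", q=1, mc_samples=128, seed=3)
        score = acq.score_candidates("qnehvi", model, pool, [int(best)], cfg)
        assert score[0] > 1e-6

    def test_greedy_batch_near_exhaustive_pair_optimum(self, small_oracle):
        """Greedy two-slot construction reaches (within Monte-Carlo noise)
        the best joint expected hypervolume improvement over all candidate
        pairs, where the exhaustive oracle evaluates every pair by direct
        hypervolume differences over shared posterior samples."""
        pool = small_oracle.pool
        rng = np.random.default_rng(13)
        obs_ids = rng.choice(len(pool), 8, replace=False)
        obs = make_observations(obs_ids, small_oracle.truth[obs_ids])
        model = sg.fit(pool, obs, seed=2)
        cand = sorted(int(c) for c in rng.choice(
            np.setdiff1d(np.arange(len(pool)), obs_ids), 5, replace=False))
        pool2 = small_oracle.pool
        mask = np.ones(len(pool2), dtype=bool)
        mask[cand] = False
        pool2 = type(pool2)(**{**pool2.__dict__, "run_mask": mask,
                               "_id_lookup": None})
        sel = acq.qnehvi_batch(model, pool2, q=2, mc_samples=256, seed=5)
        ref = reference_point(model.Y_train)
        # exhaustive oracle over shared samples
        S = 1500
        all_ids = np.concatenate([np.unique(obs_ids), cand])
        samples = sg.sample_posterior(model, pool2, all_ids, S, seed=99)
        n_obs = len(np.unique(obs_ids))
        front_s = samples[:, :n_obs, :]
        cand_pos = {c: n_obs + i for i, c in enumerate(cand)}
        import itertools
        pair_stats = {}
        for a, b in itertools.combinations(cand, 2):
            imps = np.empty(S)
            for s in range(S):
                base = np.maximum(front_s[s], ref)
                hv0 = hypervolume(base, ref)
                pts = np.vstack([base,
                                 np.maximum(samples[s, cand_pos[a]], ref),
                                 np.maximum(samples[s, cand_pos[b]], ref)])
                imps[s] = hypervolume(pts, ref) - hv0
            pair_stats[(a, b)] = (imps.mean(), imps.std(ddof=1) / np.sqrt(S))
        best_pair = max(pair_stats, key=lambda k: pair_stats[k][0])
        greedy_pair = tuple(sorted(sel.condition_ids))
        best_val, best_sem = pair_stats[best_pair]
        greedy_val, greedy_sem = pair_stats[tuple(sorted(greedy_pair))]
        assert greedy_val >= best_val - 3 * (best_sem + greedy_sem)


class TestUtopia:
    def test_distance_ranking_examples(self):
        pool = temp_pool(1, (40.0, 70.0))  # 2 conditions
        truth = np.array([[100.0, 100.0], [105.0, 95.0]])
        model = stub_from_truth(pool, truth, [0])
        # distances to (110,110): sqrt(200) ~ 14.142 vs sqrt(250) ~ 15.811
        sel = acq.utopia_exploit_batch(model, pool, q=2)
        assert sel.condition_ids == [0, 1]
        assert -sel.values[0] == pytest.approx(np.sqrt(200.0))
        assert -sel.values[1] == pytest.approx(np.sqrt(250.0))

    def test_exact_utopia_point_ranked_first(self):
        pool = temp_pool(2, (40.0, 70.0))
        truth = np.array([[50.0, 50.0], [110.0, 110.0], [80.0, 90.0], [20.0, 10.0]])
        model = stub_from_truth(pool, truth, [0])
        sel = acq.utopia_exploit_batch(model, pool, q=1)
        assert sel.condition_ids == [1]

    def test_matches_full_sort_oracle(self):
        pool = temp_pool(8, (40.0, 55.0, 70.0))  # 24 conditions
        rng = np.random.default_rng(14)
        truth = np.column_stack([rng.uniform(0, 100, 24), rng.uniform(0, 100, 24)])
        model = stub_from_truth(pool, truth, [0])
        pool.mark_run([0])
        q = 6
        sel = acq.utopia_exploit_batch(model, pool, q=q)
        u = np.array([110.0, 110.0])
        unrun = np.arange(1, 24)
        d = np.linalg.norm(truth[unrun] - u, axis=1)
        oracle = unrun[np.argsort(d, kind="stable")][:q].tolist()
        assert sel.condition_ids == oracle


class TestConstraints:
    def _setup(self, seed=15):
        # 5 ligands x 3 temperatures; observing ligand 0 at all three
        # temperatures leaves 4 un-run candidates per temperature level
        pool = temp_pool(5, (40.0, 70.0, 100.0))
        rng = np.random.default_rng(seed)
        truth = np.column_stack([rng.uniform(5, 95, 15), rng.uniform(5, 95, 15)])
        obs_ids = [0, 1, 2]
        model = stub_from_truth(pool, truth, obs_ids)
        pool.mark_run(obs_ids)
        return pool, model, truth, obs_ids

    def test_vacuous_constraint_equals_unconstrained(self):
        pool, model, _, _ = self._setup()
        cfg = acq.AcquisitionConfig(strategy="qnehvi", q=4, mc_samples=16, seed=20)
        unconstrained = acq.select_batch("qnehvi", model, pool, cfg)
        for mode in ("naive", "nested"):
            con = acq.BatchConstraint("temperature", max_unique=3, mode=mode)
            sel = acq.select_batch("qnehvi", model, pool, cfg, constraint=con)
            assert sel.condition_ids == unconstrained.condition_ids

    @pytest.mark.parametrize("mode", ["naive", "nested"])
    @pytest.mark.parametrize("k", [1, 2])
    def test_unique_temperature_invariant(self, mode, k):
        pool, model, _, _ = self._setup(seed=21)
        cfg = acq.AcquisitionConfig(strategy="qnehvi", q=4, mc_samples=16, seed=22)
        con = acq.BatchConstraint("temperature", max_unique=k, mode=mode)
        sel = acq.select_batch("qnehvi", model, pool, cfg, constraint=con)
        temps = pool.temperature_values()[sel.condition_ids]
        assert len(np.unique(temps)) <= k
        assert len(set(sel.condition_ids)) == 4

    def test_nested_temperature_choice_matches_exhaustive_oracle(self):
        """Nested mode must pick the temperature whose un-run candidates have
        the highest mean single-point acquisition value (zero-variance, so
        the oracle enumerates HVI of every candidate's posterior mean)."""
        pool, model, truth, obs_ids = self._setup(seed=23)
        cfg = acq.AcquisitionConfig(strategy="qnehvi", q=4, mc_samples=16, seed=24)
        con = acq.BatchConstraint("temperature", max_unique=1, mode="nested")
        sel = acq.select_batch("qnehvi", model, pool, cfg, constraint=con)
        Y_obs = truth[obs_ids]
        ref = reference_point(Y_obs)
        state = ParetoState.from_points(Y_obs, ref)
        temps = pool.temperature_values()
        unrun = sorted(set(range(len(pool))) - set(obs_ids))
        per_level = {}
        for t in np.unique(temps):
            cands = [c for c in unrun if temps[c] == t]
            per_level[t] = np.mean(
                [hvi(np.maximum(truth[c], ref), state) for c in cands]
            )
        best_level = max(sorted(per_level), key=lambda t: per_level[t])
        chosen = np.unique(temps[sel.condition_ids])
        assert chosen.tolist() == [best_level]

    def test_infeasible_fill_errors(self):
        pool, model, _, _ = self._setup(seed=25)
        cfg = acq.AcquisitionConfig(strategy="qnehvi", q=5, mc_samples=16, seed=26)
        con = acq.BatchConstraint("temperature", max_unique=1, mode="nested")
        with pytest.raises(ValueError, match="infeasible fill|shortfall"):
            acq.select_batch("qnehvi", model, pool, cfg, constraint=con)


class TestDeterminism:
    @pytest.mark.parametrize("strategy", ["sobol", "qnehvi", "qnparego", "tshvi",
                                          "utopia_exploit"])
    def test_identical_seed_identical_batch(self, strategy, small_oracle):
        from dataclasses import replace
        pool = replace(small_oracle.pool,
                       run_mask=np.zeros(len(small_oracle.pool), dtype=bool),
                       _id_lookup=None)
        rng = np.random.default_rng(30)
        ids = rng.choice(len(pool), 12, replace=False)
        obs = make_observations(ids, small_oracle.truth[ids])
        pool.mark_run(ids)
        model = sg.fit(pool, obs, seed=1)
        cfg = acq.AcquisitionConfig(strategy=strategy, q=5, mc_samples=16, seed=77)
        a = acq.select_batch(strategy, model if strategy != "sobol" else None, pool, cfg)
        b = acq.select_batch(strategy, model if strategy != "sobol" else None, pool, cfg)
        assert a.condition_ids == b.condition_ids
        assert np.array_equal(a.values, b.values)

    def test_batches_never_contain_run_or_duplicate_ids(self, small_oracle):
        from dataclasses import replace
        pool = replace(small_oracle.pool,
                       run_mask=np.zeros(len(small_oracle.pool), dtype=bool),
                       _id_lookup=None)
        rng = np.random.default_rng(31)
        ids = rng.choice(len(pool), 15, replace=False)
        obs = make_observations(ids, small_oracle.truth[ids])
        pool.mark_run(ids)
        model = sg.fit(pool, obs, seed=2)
        for strategy in ("qnehvi", "qnparego", "tshvi", "utopia_exploit"):
            cfg = acq.AcquisitionConfig(strategy=strategy, q=6, mc_samples=16, seed=8)
            sel = acq.select_batch(strategy, model, pool, cfg)
            assert len(set(sel.condition_ids)) == 6
            assert not any(pool.run_mask[c] for c in sel.condition_ids)
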