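import itertools

import numpy as np
import pytest

from wsbbo.moqa import (
    AutoencoderConfig,
    FactorizationMachine,
    QUBO,
    RunState,
    acquisition,
    anneal_sample,
    fit_fm,
    fm_to_qubo,
    merge_runs,
    moqa_run,
    random_generate,
    train_autoencoder,
)
from wsbbo.objectives import ObjectiveVector, TOY_SCORER
from wsbbo.pareto import ParetoArchive


def all_binary(d):
    return np.array(list(itertools.product([0, 1], repeat=d)), dtype=float)


def two_cluster_sequences(n=200, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        base = list("AACCAA" if i % 2 else "CCAACC")
        for j in range(6):
            if rng.random() < 0.1:
                base[j] = "AC"[rng.integers(2)]
        out.append("".join(base))
    return out


class TestAutoencoder:
    def test_round_trip_identity_on_clustered_toy(self):
        seqs = two_cluster_sequences()
        ae = train_autoencoder(seqs, d=8, config=AutoencoderConfig(seed=1),
                               alphabet="AC")
        assert ae.train_identity_rate >= 0.8

    def test_decode_is_deterministic(self):
        ae = train_autoencoder(two_cluster_sequences(), d=8,
                               config=AutoencoderConfig(seed=1), alphabet="AC")
        z = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        assert ae.decode(z) == ae.decode(z)

    def test_encode_decode_closure(self, rng):
        ae = train_autoencoder(two_cluster_sequences(), d=8,
                               config=AutoencoderConfig(seed=1), alphabet="AC")
        for _ in range(20):
            z = rng.integers(0, 2, 8)
            back = ae.encode(ae.decode(z))
            assert back.shape == (8,) and set(np.unique(back)) <= {0, 1}

    def test_mixed_lengths_rejected(self):
        seqs = ["AC"] * 30 + ["ACA"] * 30
        with pytest.raises(ValueError, match="mixed"):
            train_autoencoder(seqs, d=4, alphabet="AC")

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError, match="50"):
            train_autoencoder(["ACAC"] * 10, d=4, alphabet="AC")


class TestFactorizationMachine:
    def test_planted_fm_recovered_exactly(self, rng):
        d, r = 8, 2
        true = FactorizationMachine(w0=0.3, w=rng.normal(0, 1, d),
                                    V=rng.normal(0, 0.5, (d, r)))
        X = rng.integers(0, 2, (300, d)).astype(float)
        fit = fit_fm(X, true.predict(X), rank=r, lam=1e-6, seed=0,
                     epochs=6000, lr=0.01)
        grid = all_binary(d)
        rmse = np.sqrt(np.mean((fit.predict(grid) - true.predict(grid)) ** 2))
        assert rmse < 1e-3

    def test_constant_target_collapses_to_bias(self, rng):
        X = rng.integers(0, 2, (100, 6)).astype(float)
        fm = fit_fm(X, np.full(100, 1.7), rank=3, lam=1e-2, seed=1,
                    epochs=2000, lr=0.02)
        assert fm.w0 == pytest.approx(1.7, abs=0.05)
        assert np.abs(fm.w).max() < 0.05
        gram = fm.V @ fm.V.T
        assert np.abs(gram[np.triu_indices(6, 1)]).max() < 0.05

    def test_regularization_shrinks_interactions_on_linear_target(self, rng):
        d = 6
        X = rng.integers(0, 2, (200, d)).astype(float)
        beta = rng.normal(0, 1, d)
        y = X @ beta
        mags = {}
        for lam in (1e-3, 10.0):
            fm = fit_fm(X, y, rank=3, lam=lam, seed=2, epochs=1500, lr=0.02)
            gram = fm.V @ fm.V.T
            mags[lam] = np.abs(gram[np.triu_indices(d, 1)]).mean()
        assert mags[10.0] < 1e-2 * mags[1e-3]
        assert mags[10.0] < 1e-6

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            fit_fm(np.zeros((0, 4)), np.zeros(0))


class TestQuboCompilation:
    def test_hand_evaluated_example(self):
        fm = FactorizationMachine(w0=0.5, w=np.array([1.0, -1.0]),
                                  V=np.array([[1.0, 0.0], [1.0, 0.0]]))
        qubo = fm_to_qubo(fm)
        x = np.array([1.0, 1.0])
        assert qubo.energy(x) == pytest.approx(-1.5)
        assert qubo.energy(x) == pytest.approx(-fm.predict(x)[0])

    def test_zero_fm_compiles_to_zero_energy(self):
        fm = FactorizationMachine(w0=0.0, w=np.zeros(4), V=np.zeros((4, 2)))
        qubo = fm_to_qubo(fm)
        assert np.all(qubo.energies(all_binary(4)) == 0.0)

    def test_exhaustive_equivalence_d10(self, rng):
        fm = FactorizationMachine(w0=rng.normal(), w=rng.normal(0, 1, 10),
                                  V=rng.normal(0, 1, (10, 4)))
        qubo = fm_to_qubo(fm)
        grid = all_binary(10)
        dev = np.abs(qubo.energies(grid) + fm.predict(grid))
        assert dev.max() < 1e-10


class TestAnnealSample:
    def test_separable_optimum(self):
        qubo = QUBO(Q=np.diag([-1.0, -1.0]))
        best = anneal_sample(qubo, n_samples=5, sweeps=50, seed=0)[0]
        assert best.tolist() == [1, 1]

    def test_sorted_by_ascending_energy(self, rng):
        qubo = QUBO(Q=np.triu(rng.normal(size=(8, 8))))
        samples = anneal_sample(qubo, n_samples=20, sweeps=100, seed=1)
        energies = qubo.energies(samples)
        assert np.all(np.diff(energies) >= -1e-12)

    def test_recovers_exhaustive_optimum(self, rng):
        hits = 0
        grid = all_binary(8)
        for trial in range(20):
            Q = np.triu(np.random.default_rng(trial).normal(size=(8, 8)))
            qubo = QUBO(Q=Q)
            truth = qubo.energies(grid).min()
            best = qubo.energies(anneal_sample(qubo, 20, 500, seed=trial)).min()
            hits += abs(best - truth) < 1e-9
        assert hits >= 19

    def test_degenerate_minima_both_found(self):
        # frustrated 3-spin instance: E = x0*x1 + x1*x2 + x0*x2 - x0 - x1 - x2
        Q = np.array([[-1.0, 1.0, 1.0], [0.0, -1.0, 1.0], [0.0, 0.0, -1.0]])
        qubo = QUBO(Q=Q)
        grid = all_binary(3)
        energies = qubo.energies(grid)
        optima = {tuple(map(int, g)) for g in grid[energies == energies.min()]}
        assert len(optima) >= 2
        found = {tuple(map(int, s))
                 for s in anneal_sample(qubo, n_samples=40, sweeps=200, seed=3)
                 if abs(qubo.energy(s) - energies.min()) < 1e-9}
        assert len(found) >= 2

    def test_deterministic_given_seed(self, rng):
        qubo = QUBO(Q=np.triu(rng.normal(size=(6, 6))))
        a = anneal_sample(qubo, 10, 100, seed=5)
        b = anneal_sample(qubo, 10, 100, seed=5)
        np.testing.assert_array_equal(a, b)


class TestAcquisition:
    def archive(self, points, ref=(0.0, 0.0)):
        arch = ParetoArchive(reference_point=np.array(ref))
        for i, p in enumerate(points):
            arch.update(f"s{i}", np.array(p))
        return arch

    def test_dominated_candidate_scores_zero(self):
        arch = self.archive([(2.0, 2.0)])
        assert acquisition(np.array([1.0, 1.0]), arch) == 0.0

    def test_empty_front_reduces_to_box_volume(self):
        arch = self.archive([])
        assert acquisition(np.array([2.0, 3.0]), arch) == pytest.approx(6.0)

    def test_inclusion_exclusion_example(self):
        arch = self.archive([(2.0, 1.0), (1.0, 2.0)])
        assert acquisition(np.array([2.0, 2.0]), arch) == pytest.approx(1.0)


class TestRandomGenerate:
    def test_shape_and_alphabet(self):
        (seq,) = random_generate(1, 5, "ACDE", seed=0)
        assert len(seq) == 5 and set(seq) <= set("ACDE")

    def test_deterministic(self):
        assert random_generate(20, 8, seed=3) == random_generate(20, 8, seed=3)

    def test_per_position_frequencies_uniform(self):
        seqs = random_generate(10_000, 6, "ACDEFGHIKLMNPQRSTVWY", seed=1)
        n, p = 10_000, 1 / 20
        sigma = np.sqrt(n * p * (1 - p))
        for pos in range(6):
            counts = np.array([sum(s[pos] == aa for s in seqs)
                               for aa in "ACDEFGHIKLMNPQRSTVWY"])
            assert np.all(np.abs(counts - n * p) < 3 * sigma + 1e-9)


class TestMoqaRun:
    def small_run(self, labeled_dataset, toy_ensemble, budget=40, seed=11):
        return moqa_run(
            labeled_dataset, toy_ensemble, TOY_SCORER, budget=budget, seed=seed,
            latent_dim=16, batch_size=20, n_random_init=20,
            ae_config=AutoencoderConfig(epochs=100, seed=seed),
        )

    def test_zero_budget_keeps_only_seed_pool(self, labeled_dataset, toy_ensemble):
        state = self.small_run(labeled_dataset, toy_ensemble, budget=0)
        assert state.generated == []
        assert len(state.evaluated) == state.n_initial

    def test_budget_accounting_and_traces(self, labeled_dataset, toy_ensemble):
        state = self.small_run(labeled_dataset, toy_ensemble)
        assert len(state.generated) == 40
        seqs = [s for s, _ in state.generated]
        assert len(seqs) == len(set(seqs))
        assert not set(seqs) & set(labeled_dataset.positives
                                   + labeled_dataset.negatives)
        hv = [h for _, h in state.archive.hv_history]
        assert all(b >= a - 1e-12 for a, b in zip(hv, hv[1:]))
        best = np.stack(state.archive.best_so_far)
        assert np.all(np.diff(best, axis=0) >= -1e-15)

    def test_same_seed_reproduces_run_exactly(self, labeled_dataset, toy_ensemble):
        a = self.small_run(labeled_dataset, toy_ensemble, seed=13)
        b = self.small_run(labeled_dataset, toy_ensemble, seed=13)
        assert [s for s, _ in a.generated] == [s for s, _ in b.generated]
        np.testing.assert_array_equal(a.archive.front, b.archive.front)

    def test_budget_below_batch_rejected(self, labeled_dataset, toy_ensemble):
        with pytest.raises(ValueError, match="batch"):
            moqa_run(labeled_dataset, toy_ensemble, TOY_SCORER, budget=5,
                     seed=0, batch_size=20)


class TestMergeRuns:
    @staticmethod
    def fake_state(seqs, offset=0.0):
        vecs = [ObjectiveVector(0.5 + offset, -0.1, 1.0) for _ in seqs]
        state = RunState(archive=ParetoArchive(reference_point=np.zeros(3)))
        state.generated = list(zip(seqs, vecs))
        state.evaluated = dict(zip(seqs, vecs))
        return state

    def test_disjoint_union(self):
        merged = merge_runs([self.fake_state(["AAA", "CCC", "DDD"]),
                             self.fake_state(["EEE", "FFF", "GGG", "HHH"])])
        assert len(merged) == 7

    def test_duplicates_counted_once(self):
        merged = merge_runs([self.fake_state(["AAA", "CCC"]),
                             self.fake_state(["CCC", "DDD"])])
        assert len(merged) == 3

    def test_planted_overlap_matches_set_union(self, rng):
        runs = []
        all_seqs = set()
        for i in range(10):
            fresh = ["".join(rng.choice(list("ACDE"), 8)) for _ in range(40)]
            overlap = list(all_seqs)[:10]
            seqs = list(dict.fromkeys(overlap + fresh))[:50]
            all_seqs.update(seqs)
            runs.append(self.fake_state(seqs))
        merged = merge_runs(runs)
        assert len(merged) == len(all_seqs)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_runs([])
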