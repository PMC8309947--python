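import numpy as np
import pytest
from scipy import sparse

import snncluster as sc
from snncluster.clustering import (
    ClusterFrame,
    boundary_report,
    cluster_adjacency,
    read_frame_log,
    write_frame_log,
)


def random_affinity(n: int, seed: int, density: float = 0.3) -> np.ndarray:
    rng = np.random.default_rng(seed)
    A = rng.uniform(0, 10, size=(n, n)) * (rng.uniform(size=(n, n)) < density)
    return sc.symmetrize_affinity(np.triu(A, 1))


class TestSymmetrize:
    def test_sum_of_directed_counts(self):
        A = np.zeros((3, 3))
        A[0, 1], A[1, 0] = 3, 2
        A_prime = sc.symmetrize_affinity(A)
        assert A_prime[0, 1] == A_prime[1, 0] == 5

    def test_zero_diagonal(self):
        A = np.ones((4, 4))
        A_prime = sc.symmetrize_affinity(A)
        assert np.all(np.diag(A_prime) == 0)

    def test_all_zero_log(self):
        assert not sc.symmetrize_affinity(np.zeros((5, 5))).any()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sc.symmetrize_affinity(np.full((2, 2), -1.0))

    def test_sparse_matches_dense(self):
        A = np.random.default_rng(3).integers(0, 5, size=(8, 8)).astype(float)
        np.fill_diagonal(A, 0)
        dense = sc.symmetrize_affinity(A)
        sp = sc.symmetrize_affinity(sparse.csr_matrix(A))
        np.testing.assert_allclose(sp.toarray(), dense)


class TestPropagate:
    @pytest.mark.parametrize("mode", ["closed_form", "iterative"])
    def test_zero_affinity_returns_sources_exactly(self, mode):
        """With no exchanged spikes only the input neurons hold information."""
        Fsrc = np.zeros((6, 2))
        Fsrc[1, 0] = Fsrc[4, 1] = 1.0
        F = sc.propagate(np.zeros((6, 6)), Fsrc, alpha=0.9, mode=mode)
        assert np.array_equal(F, Fsrc)

    def test_two_neuron_chain_hand_solution(self):
        """2 neurons, symmetric affinity c, alpha=0.5: solve (I-aS)F=Fsrc by hand.

        With both T_i = c the normalised S is [[0,1],[1,0]] for either
        normalisation, so F* = (1/(1-a^2)) [[1],[a]]."""
        c = 4.0
        A_prime = np.array([[0.0, c], [c, 0.0]])
        Fsrc = np.array([[1.0], [0.0]])
        alpha = 0.5
        F = sc.propagate(A_prime, Fsrc, alpha=alpha, mode="closed_form")
        expected = np.array([[1.0], [alpha]]) / (1 - alpha**2)
        np.testing.assert_allclose(F, expected, rtol=1e-12)
        assert 0 < F[1, 0] < F[0, 0]

    @pytest.mark.parametrize("n,seed", [(30, 0), (40, 1), (50, 2)])
    def test_iterative_matches_closed_form(self, n, seed):
        A_prime = random_affinity(n, seed)
        Fsrc = np.zeros((n, 4))
        Fsrc[[0, 5, 11, 17], np.arange(4)] = 1.0
        tol = 1e-9
        Fc = sc.propagate(A_prime, Fsrc, alpha=0.9, mode="closed_form")
        Fi = sc.propagate(A_prime, Fsrc, alpha=0.9, mode="iterative", tol=tol)
        assert np.max(np.abs(Fc - Fi)) < 10 * tol

    def test_sparse_closed_form_matches_dense(self):
        A_prime = random_affinity(20, 5)
        Fsrc = np.zeros((20, 2))
        Fsrc[[2, 9], [0, 1]] = 1.0
        Fd = sc.propagate(A_prime, Fsrc)
        Fs = sc.propagate(sparse.csr_matrix(A_prime), Fsrc)
        np.testing.assert_allclose(Fs, Fd, atol=1e-10)

    def test_monotone_information_lower_bound(self):
        """Every F* entry is at least (1-alpha) times the source entry."""
        A_prime = random_affinity(25, 7)
        Fsrc = np.zeros((25, 3))
        Fsrc[[1, 8, 15], np.arange(3)] = 1.0
        alpha = 0.9
        F = sc.propagate(A_prime, Fsrc, alpha=alpha)
        assert np.all(F >= (1 - alpha) * Fsrc - 1e-12)

    def test_inverse_normalization_available(self):
        A_prime = random_affinity(15, 9)
        Fsrc = np.zeros((15, 2))
        Fsrc[[0, 7], [0, 1]] = 1.0
        F = sc.propagate(A_prime, Fsrc, normalization="inverse")
        assert np.all(np.isfinite(F))

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 1.5])
    def test_alpha_domain(self, alpha):
        with pytest.raises(ValueError):
            sc.propagate(np.zeros((3, 3)), np.zeros((3, 1)), alpha=alpha)


class TestAssign:
    def test_source_matrix_assigns_inputs_to_themselves(self):
        Fsrc = np.zeros((5, 2))
        Fsrc[0, 0] = Fsrc[3, 1] = 1.0
        coords = np.arange(15, dtype=float).reshape(5, 3)
        labels, sizes, flagged = sc.assign(Fsrc, coords, np.array([0, 3]))
        assert labels[0] == 0 and labels[3] == 1
        assert flagged[[1, 2, 4]].all() and not flagged[[0, 3]].any()
        assert sizes.sum() == 5

    def test_tie_breaks_to_lowest_column(self):
        F = np.array([[0.2, 0.2, 0.1]])
        labels, _, _ = sc.assign(F)
        assert labels[0] == 0

    def test_zero_row_falls_back_to_nearest_input(self):
        F = np.zeros((3, 2))
        F[0, 0] = F[2, 1] = 1.0
        coords = np.array([[0.0, 0, 0], [0.9, 0, 0], [1.0, 0, 0]])
        labels, _, flagged = sc.assign(F, coords, np.array([0, 2]))
        assert labels[1] == 1  # nearest input is neuron 2 -> cluster 1
        assert flagged[1]

    def test_sizes_sum_to_neuron_count(self, trained):
        _, log, _, _ = trained
        for frame in log.frames:
            assert frame.sizes.sum() == len(frame.labels)


class TestFuzzyBoundaries:
    def _frames(self, histories):
        """Build minimal frames from a (N, n_frames) label history."""
        histories = np.asarray(histories)
        n, nf = histories.shape
        v = int(histories.max()) + 1
        frames = []
        for f in range(nf):
            labels = histories[:, f]
            F = np.zeros((n, v))
            F[np.arange(n), labels] = 1.0
            frames.append(
                ClusterFrame(f, F, labels, np.bincount(labels, minlength=v))
            )
        return frames

    def test_constant_labels_no_boundaries(self):
        frames = self._frames([[0, 0, 0], [1, 1, 1]])
        assert sc.fuzzy_boundaries(frames) == []

    def test_single_exchange_detected(self):
        """Label history [1,1,2,1] puts the neuron in boundary (1,2) only."""
        frames = self._frames([[1, 1, 2, 1], [0, 0, 0, 0]])
        out = sc.fuzzy_boundaries(frames)
        assert len(out) == 1
        assert out[0].pair == (1, 2) and out[0].shared_neurons == {0}

    def test_three_cluster_oscillation_in_all_pairs(self):
        frames = self._frames([[0, 1, 2, 0], [0, 0, 0, 0]])
        pairs = {b.pair for b in sc.fuzzy_boundaries(frames)}
        assert pairs == {(0, 1), (0, 2), (1, 2)}

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(4)
        hist = rng.integers(0, 4, size=(30, 6))
        out = sc.fuzzy_boundaries(self._frames(hist))
        expected = {}
        for i in range(30):
            seen = set(hist[i])
            for a in seen:
                for b in seen:
                    if a < b:
                        expected.setdefault((a, b), set()).add(i)
        assert {b.pair: set(b.shared_neurons) for b in out} == expected
        sizes = [b.size for b in out]
        assert sizes == sorted(sizes, reverse=True)

    def test_single_frame_warns_and_returns_empty(self):
        frames = self._frames([[0], [1]])
        with pytest.warns(UserWarning):
            assert sc.fuzzy_boundaries(frames[:1]) == []

    def test_adjacency_filter(self):
        frames = self._frames([[0, 1], [1, 2], [0, 0]])
        out = sc.fuzzy_boundaries(frames, adjacency=[(0, 1)])
        assert {b.pair for b in out} == {(0, 1)}

    def test_boundary_report_csv(self, tmp_path):
        import pandas as pd

        frames = self._frames([[0, 1], [0, 0]])
        boundary_report(sc.fuzzy_boundaries(frames), tmp_path / "b.csv")
        df = pd.read_csv(tmp_path / "b.csv")
        assert df.loc[0, ["cluster_a", "cluster_b", "size"]].tolist() == [0, 1, 1]


class TestFrameLogIO:
    def test_round_trip(self, tmp_path, trained):
        _, log, _, _ = trained
        write_frame_log(log.frames, tmp_path / "f.h5")
        back = read_frame_log(tmp_path / "f.h5")
        assert len(back) == len(log.frames)
        for a, b in zip(back, log.frames):
            assert a.t == b.t
            np.testing.assert_allclose(a.F_star, b.F_star)
            assert np.array_equal(a.labels, b.labels)


def test_cluster_adjacency_on_unit_line():
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [10.0, 0, 0]])
    pairs = cluster_adjacency(coords, factor=2.0)
    # median nearest-neighbour distance 1 -> cutoff 2; the far point is isolated
    assert (0, 1) in pairs and (1, 2) in pairs and (0, 2) in pairs
    assert not any(3 in p for p in pairs)
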