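import math

import numpy as np
import pandas as pd
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from hdotools.network import (ConnectivityMatrix, _largest_component_edges,
                              average_matrices, correlation_matrix, mdcc,
                              nbs_compare, preprocess_for_network)
from hdotools.synth import connectivity_benchmark
from hdotools.timecourse import TimeCourse


def _mat(r, regions=None, **kw):
    r = np.asarray(r, dtype=float)
    regions = regions or [f"R{i}" for i in range(r.shape[0])]
    return ConnectivityMatrix(regions, r, **kw)


class TestPreprocessForNetwork:
    def _setup(self, seed=0, n_t=200):
        rng = np.random.default_rng(seed)
        vol = rng.normal(100, 1, (6, 6, 1, n_t))
        labels = np.zeros((6, 6, 1), dtype=int)
        labels[:3] = 1
        labels[3:] = 2
        table = pd.DataFrame({"id": [1, 2], "name": ["A", "B"]})
        return vol, labels, table

    def test_lowpass_removes_fast_component(self):
        vol, labels, table = self._setup()
        t = np.arange(200.0)
        vol += 5.0 * np.sin(2 * np.pi * 0.4 * t)
        courses = preprocess_for_network(vol, labels, table, dt=1.0)
        for tc in courses:
            amps = np.abs(np.fft.rfft(tc.values - tc.values.mean()))
            freqs = np.fft.rfftfreq(len(tc), 1.0)
            i = np.argmin(np.abs(freqs - 0.4))
            assert amps[i] < 1e-6 * np.abs(vol).sum()

    def test_global_signal_regression_removes_shared_signal(self):
        t = np.arange(200.0)
        shared = 100 + np.sin(2 * np.pi * 0.05 * t)
        vol = np.tile(shared, (6, 6, 1, 1))
        labels = np.zeros((6, 6, 1), dtype=int)
        labels[:3] = 1
        labels[3:] = 2
        table = pd.DataFrame({"id": [1, 2], "name": ["A", "B"]})
        courses = preprocess_for_network(vol, labels, table, dt=1.0)
        for tc in courses:
            assert np.std(tc.values) < 1e-8 * np.std(shared) * 18

    def test_pipeline_preserves_region_baseline(self):
        """Normalized smoothing kernel + GSR keep each region's mean level."""
        vol, labels, table = self._setup(seed=1)
        courses = preprocess_for_network(vol, labels, table, dt=1.0)
        for tc in courses:
            n_vox = int((labels == (1 if tc.label == "A" else 2)).sum())
            assert abs(tc.values.mean() / (100.0 * n_vox) - 1.0) < 0.01


class TestCorrelationMatrix:
    def test_duplicated_region_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        courses = [TimeCourse(100 + x, dt=1.0, label="a"),
                   TimeCourse(50 + 2 * x, dt=1.0, label="b")]
        m = correlation_matrix(courses)
        assert np.isclose(m.r[0, 1], 1.0)

    def test_independent_noise_low_correlation(self):
        rng = np.random.default_rng(1)
        courses = [TimeCourse(100 + rng.normal(0, 1, 600), dt=1.0,
                              label=f"r{i}") for i in range(10)]
        m = correlation_matrix(courses, negatives_zeroed=False)
        iu = np.triu_indices(10, 1)
        assert np.mean(np.abs(m.r[iu]) < 0.2) >= 0.95

    def test_anticorrelated_pair_clipped(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        courses = [TimeCourse(100 + x, dt=1.0, label="a"),
                   TimeCourse(100 - x, dt=1.0, label="b")]
        m = correlation_matrix(courses, negatives_zeroed=True)
        assert m.r[0, 1] == 0.0

    def test_zero_variance_region_named(self):
        courses = [TimeCourse(np.full(100, 5.0), dt=1.0, label="flatroi"),
                   TimeCourse(np.arange(100.0), dt=1.0, label="b")]
        with pytest.raises(ValueError, match="flatroi"):
            correlation_matrix(courses)


class TestAverageMatrices:
    def test_identical_matrices_fixed_point(self):
        m = _mat([[1.0, 0.3], [0.3, 1.0]])
        out = average_matrices([m, m, m])
        np.testing.assert_allclose(out.r, m.r, atol=1e-12)

    def test_closed_form_two_values(self):
        """Fisher-z mean of r = 0.2 and 0.6 from the logarithm closed form."""
        z = lambda r: 0.5 * math.log((1 + r) / (1 - r))
        zmean = (z(0.2) + z(0.6)) / 2.0
        expected = (math.exp(2 * zmean) - 1) / (math.exp(2 * zmean) + 1)
        m1 = _mat([[1.0, 0.2], [0.2, 1.0]])
        m2 = _mat([[1.0, 0.6], [0.6, 1.0]])
        out = average_matrices([m1, m2])
        assert np.isclose(out.r[0, 1], expected, atol=1e-12)
        assert not np.isclose(out.r[0, 1], 0.4, atol=1e-3)  # not the raw mean

    def test_single_matrix_identity(self):
        m = _mat([[1.0, 0.7], [0.7, 1.0]])
        np.testing.assert_allclose(average_matrices([m]).r, m.r, atol=1e-12)

    def test_unit_entries_survive_clipping(self):
        m = _mat([[1.0, 1.0], [1.0, 1.0]])
        out = average_matrices([m, m])
        assert out.r[0, 1] > 0.999

    def test_mismatched_regions_rejected(self):
        m1 = _mat(np.eye(2), regions=["a", "b"])
        m2 = _mat(np.eye(2), regions=["a", "c"])
        with pytest.raises(ValueError, match="mismatch"):
            average_matrices([m1, m2])


class TestLargestComponent:
    def _oracle(self, edge_nodes, active, n_nodes):
        """Independent route: sparse-graph connected components."""
        idx = np.flatnonzero(active)
        if idx.size == 0:
            return 0
        rows = edge_nodes[idx, 0]
        cols = edge_nodes[idx, 1]
        adj = csr_matrix((np.ones(idx.size), (rows, cols)),
                         shape=(n_nodes, n_nodes))
        n_comp, assign = connected_components(adj, directed=False)
        best = 0
        for c in range(n_comp):
            in_c = np.sum((assign[rows] == c))
            best = max(best, int(in_c))
        return best

    def test_exhaustive_small_graphs(self):
        """All graphs on 4 nodes (64 edge subsets) match the oracle."""
        nodes = 4
        pairs = [(i, j) for i in range(nodes) for j in range(i + 1, nodes)]
        edge_nodes = np.array(pairs)
        for code in range(2 ** len(pairs)):
            active = np.array([(code >> k) & 1 for k in range(len(pairs))],
                              dtype=bool)
            size, members = _largest_component_edges(edge_nodes, active, nodes)
            assert size == self._oracle(edge_nodes, active, nodes)
            assert len(members) == size

    def test_random_eight_node_graphs(self):
        nodes = 8
        pairs = np.array([(i, j) for i in range(nodes)
                          for j in range(i + 1, nodes)])
        rng = np.random.default_rng(4)
        for _ in range(300):
            active = rng.uniform(size=len(pairs)) < rng.uniform(0.05, 0.5)
            size, _ = _largest_component_edges(pairs, active, nodes)
            assert size == self._oracle(pairs, active, nodes)


class TestNBS:
    def test_no_difference_empty_component(self):
        u, s, _ = connectivity_benchmark(seed=5, planted=False)
        res = nbs_compare(u, u, n_perm=50, seed=0)
        assert res.component_size == 0
        assert res.corrected_p == 1.0

    def test_planted_component_recovered(self):
        u, s, clique = connectivity_benchmark(seed=0)
        res = nbs_compare(u, s, n_perm=200, seed=0)
        rec = sum(1 for e in map(tuple, res.component_edges)
                  if e in set(clique))
        assert rec >= 5

    def test_corrected_p_floor(self):
        u, s, _ = connectivity_benchmark(seed=0)
        res = nbs_compare(u, s, n_perm=200, seed=0)
        assert res.corrected_p >= 1.0 / 201.0

    def test_region_relabeling_invariance(self):
        u, s, _ = connectivity_benchmark(seed=3)
        perm = np.random.default_rng(0).permutation(28)
        names = u[0].regions

        def relabel(m):
            return ConnectivityMatrix([names[i] for i in perm],
                                      m.r[np.ix_(perm, perm)])

        r1 = nbs_compare(u, s, n_perm=300, seed=0)
        r2 = nbs_compare([relabel(m) for m in u], [relabel(m) for m in s],
                         n_perm=300, seed=0)
        assert r1.component_size == r2.component_size
        assert np.isclose(r1.corrected_p, r2.corrected_p)

    def test_unpaired_lengths_rejected(self):
        u, s, _ = connectivity_benchmark(seed=1)
        with pytest.raises(ValueError, match="equal length"):
            nbs_compare(u[:-1], s)


class TestMDCC:
    def test_constant_differences(self):
        base = np.eye(3)
        u = [_mat(base, regions=["a", "b", "c"], negatives_zeroed=True)]
        r2 = base.copy()
        r2[0, 1] = r2[1, 0] = 0.05
        r2[0, 2] = r2[2, 0] = 0.05
        np.fill_diagonal(r2, 1.0)
        s = [_mat(r2, regions=["a", "b", "c"])]
        out = mdcc(np.array([[0, 1], [0, 2]]), u, s)
        assert np.isclose(out["mdcc"], 0.05)
        assert np.isclose(out["mdcc_abs"], 0.05)

    def test_cancellation(self):
        base = np.eye(3)
        base[0, 1] = base[1, 0] = 0.5
        base[0, 2] = base[2, 0] = 0.5
        np.fill_diagonal(base, 1.0)
        u = [_mat(base, regions=["a", "b", "c"])]
        r2 = base.copy()
        r2[0, 1] = r2[1, 0] = 0.55
        r2[0, 2] = r2[2, 0] = 0.45
        s = [_mat(r2, regions=["a", "b", "c"])]
        out = mdcc(np.array([[0, 1], [0, 2]]), u, s)
        assert abs(out["mdcc"]) < 1e-12

    def test_empty_edges_rejected(self):
        u, s, _ = connectivity_benchmark(seed=2)
        with pytest.raises(ValueError, match="at least one"):
            mdcc(np.empty((0, 2)), u, s)
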