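import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aperturekit import (
    DissimilarityMatrix,
    OntogenyProfileMatrix,
    pdc_matrix,
    permutation_distribution,
    single_linkage,
    symmetric_alpha_divergence,
)
from aperturekit.pdc import ordinal_pattern


def dist_from(freqs, m=5, t=1):
    from aperturekit import PermutationDistribution

    f = np.zeros(math.factorial(m))
    f[: len(freqs)] = freqs
    return PermutationDistribution(m=m, t=t, frequencies=f, n_windows=46)


def matrix_of(series_by_shell, variables=("curvature",)):
    mats = []
    for sid, series in series_by_shell.items():
        data = {"fraction": np.arange(1, len(series) + 1) / len(series)}
        for v in variables:
            data[v] = series
        mats.append(OntogenyProfileMatrix(sid, pd.DataFrame(data), k=len(series)))
    return mats


class TestPermutationDistribution:
    def test_increasing_series_concentrates_on_identity(self):
        d = permutation_distribution(np.arange(50.0), m=5)
        assert d.n_windows == 46
        assert len(d.frequencies) == 120
        identity = list(itertools.permutations(range(5))).index((0, 1, 2, 3, 4))
        assert d.frequencies[identity] == 1.0

    def test_decreasing_series_concentrates_on_reversal(self):
        d = permutation_distribution(-np.arange(50.0), m=5)
        reversal = list(itertools.permutations(range(5))).index((4, 3, 2, 1, 0))
        assert d.frequencies[reversal] == 1.0

    def test_brute_force_enumeration_m3(self):
        series = np.array([1, 3, 2, 4, 3, 5], float)
        d = permutation_distribution(series, m=3, t=1)
        # independent enumeration of the 4 windows
        patterns = list(itertools.permutations(range(3)))
        counts = np.zeros(6)
        for i in range(4):
            w = series[i : i + 3]
            order = sorted(range(3), key=lambda j: (w[j], j))
            ranks = [0] * 3
            for r, j in enumerate(order):
                ranks[j] = r
            counts[patterns.index(tuple(ranks))] += 1
        np.testing.assert_allclose(d.frequencies, counts / 4)

    def test_tie_break_earlier_index_lower(self):
        assert ordinal_pattern(np.array([2.0, 2.0, 1.0])) == (1, 2, 0)

    def test_series_too_short(self):
        with pytest.raises(ValueError, match="at least 5"):
            permutation_distribution(np.arange(4.0), m=5, t=1)

    def test_delay_embedding(self):
        d = permutation_distribution(np.arange(10.0), m=3, t=2)
        assert d.n_windows == 10 - 2 * 2

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.integers(-1000, 1000), min_size=10, max_size=40, unique=True),
        st.sampled_from([np.exp, np.arctan, lambda x: x**3 + 5 * x]),
    )
    def test_monotone_transform_invariance(self, values, f):
        x = np.asarray(values, dtype=float) / 100.0
        a = permutation_distribution(x, m=3)
        b = permutation_distribution(np.asarray(f(x)), m=3)
        np.testing.assert_array_equal(a.frequencies, b.frequencies)


class TestDivergence:
    def test_identity_of_indiscernibles(self):
        p = dist_from([0.3, 0.3, 0.4])
        assert symmetric_alpha_divergence(p, p) == 0.0

    def test_disjoint_supports_maximal(self):
        p = dist_from([1.0])
        q = dist_from([0.0, 1.0])
        assert symmetric_alpha_divergence(p, q) == pytest.approx(4.0, abs=1e-12)

    def test_hand_evaluated_example(self):
        p = dist_from([0.5, 0.5])
        q = dist_from([0.25, 0.75])
        expected = 2 * (
            (np.sqrt(0.5) - np.sqrt(0.25)) ** 2 + (np.sqrt(0.5) - np.sqrt(0.75)) ** 2
        )
        assert symmetric_alpha_divergence(p, q) == pytest.approx(expected, abs=1e-15)

    def test_mismatched_embedding_rejected(self):
        p = dist_from([1.0], m=5)
        q = dist_from([1.0], m=4)
        with pytest.raises(ValueError, match="mismatch"):
            symmetric_alpha_divergence(p, q)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_divergence_axioms_random_distributions(self, seed):
        rng = np.random.default_rng(seed)
        p = dist_from(rng.dirichlet(np.ones(120)))
        q = dist_from(rng.dirichlet(np.ones(120)))
        d_pq = symmetric_alpha_divergence(p, q)
        d_qp = symmetric_alpha_divergence(q, p)
        assert d_pq == d_qp
        assert 0.0 <= d_pq <= 4.0 + 1e-12
        assert symmetric_alpha_divergence(p, p) == 0.0

    def test_general_alpha_agrees_at_half(self):
        rng = np.random.default_rng(8)
        p = dist_from(rng.dirichlet(np.ones(120)))
        q = dist_from(rng.dirichlet(np.ones(120)))
        closed = symmetric_alpha_divergence(p, q, alpha=0.5)
        general = symmetric_alpha_divergence(p, q, alpha=0.5 + 1e-12)
        assert general == pytest.approx(closed, rel=1e-5)


class TestPdcMatrix:
    def test_zero_diagonal_and_symmetry(self):
        rng = np.random.default_rng(4)
        mats = matrix_of({f"s{i}": rng.normal(size=50) for i in range(4)})
        dm = pdc_matrix(mats, variables=("curvature",))
        np.testing.assert_array_equal(np.diag(dm.D), 0.0)
        np.testing.assert_array_equal(dm.D, dm.D.T)

    def test_scaled_copy_distance_zero(self):
        rng = np.random.default_rng(5)
        x = np.cumsum(rng.normal(size=50))
        mats = matrix_of({"orig": x, "scaled": 7.3 * x})
        dm = pdc_matrix(mats, variables=("curvature",))
        assert dm.D[0, 1] == 0.0

    def test_trend_sharing_pair_joins_first(self):
        t = np.linspace(0, 4 * np.pi, 50)
        mats = matrix_of(
            {
                "up_a": np.sin(t) + 0.5 * t,
                "up_b": 2 * np.sin(t) + t,
                "down": -np.sin(t) - 0.5 * t,
            }
        )
        dm = pdc_matrix(mats, variables=("curvature",))
        tree = single_linkage(dm)
        first = set(tree.merges[0, :2].astype(int))
        assert first == {0, 1}

    def test_inconsistent_lengths_rejected(self):
        rng = np.random.default_rng(6)
        mats = matrix_of({"a": rng.normal(size=50)}) + matrix_of(
            {"b": rng.normal(size=40)}
        )
        with pytest.raises(ValueError, match="length"):
            pdc_matrix(mats, variables=("curvature",))

    def test_sum_vs_mean_combination(self):
        rng = np.random.default_rng(7)
        mats = matrix_of(
            {"a": rng.normal(size=50), "b": rng.normal(size=50)},
            variables=("curvature", "torsion"),
        )
        ds = pdc_matrix(mats, variables=("curvature", "torsion"), combine="sum")
        dmn = pdc_matrix(mats, variables=("curvature", "torsion"), combine="mean")
        assert ds.D[0, 1] == pytest.approx(2 * dmn.D[0, 1], rel=1e-12)


def brute_force_single_linkage_heights(D):
    """Naive agglomeration: repeatedly merge the closest cluster pair."""
    clusters = [{i} for i in range(len(D))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(D[i][j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] |= clusters[b]
        del clusters[b]
    return np.array(heights)


class TestSingleLinkage:
    def test_two_shells_single_merge(self):
        dm = DissimilarityMatrix(["a", "b"], np.array([[0.0, 1.7], [1.7, 0.0]]))
        tree = single_linkage(dm)
        assert tree.merges.shape[0] == 1
        assert tree.heights[0] == pytest.approx(1.7)

    def test_unique_closest_pair_merges_first(self):
        D = np.array(
            [[0, 0.1, 5, 6], [0.1, 0, 4, 7], [5, 4, 0, 2], [6, 7, 2, 0]], float
        )
        tree = single_linkage(DissimilarityMatrix(list("abcd"), D))
        assert set(tree.merges[0, :2].astype(int)) == {0, 1}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_heights_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(0.1, 10, size=(6, 6))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0.0)
        tree = single_linkage(DissimilarityMatrix([f"s{i}" for i in range(6)], D))
        np.testing.assert_array_equal(
            np.sort(tree.heights), np.sort(brute_force_single_linkage_heights(D))
        )

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(9)
        A = rng.uniform(0.1, 10, size=(8, 8))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0.0)
        tree = single_linkage(DissimilarityMatrix([f"s{i}" for i in range(8)], D))
        assert np.all(np.diff(tree.heights) >= 0)

    def test_newick_parses_with_all_leaves(self):
        import io

        import dendropy

        rng = np.random.default_rng(10)
        A = rng.uniform(0.1, 10, size=(5, 5))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0.0)
        ids = [f"shell{i}" for i in range(5)]
        tree = single_linkage(DissimilarityMatrix(ids, D))
        t = dendropy.Tree.get(file=io.StringIO(tree.to_newick()), schema="newick")
        assert sorted(l.taxon.label for l in t.leaf_node_iter()) == sorted(ids)

    def test_single_shell_rejected(self):
        with pytest.raises(ValueError):
            single_linkage(DissimilarityMatrix(["a"], np.zeros((1, 1))))
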