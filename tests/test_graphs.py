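"""Graph construction: brute-force oracles and structural invariants."""

import numpy as np
import pytest

import eegcorr as ec
from eegcorr.graphs import graph_from_json, graph_to_json
from eegcorr.layout import STANDARD_1020_CHANNELS


from oracle_utils import (
    oracle_corr,
    oracle_dist,
    oracle_dtf,
    oracle_normalize,
    oracle_pair_corr,
    oracle_topk,
)


# ---------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------

class TestLayout:
    def test_nineteen_standard_channels(self):
        lay = ec.standard_1020_layout()
        assert lay.coords.shape == (19, 3)
        assert np.allclose(np.linalg.norm(lay.coords, axis=1), 1.0, atol=0.01)

    def test_single_vertex_lookup(self):
        lay = ec.standard_1020_layout(["Cz"])
        assert np.allclose(lay.coords, [[0.0, 0.0, 1.0]])

    def test_unknown_electrode_is_named_in_error(self):
        with pytest.raises(KeyError, match="Qz"):
            ec.standard_1020_layout(["Qz"])

    def test_order_follows_labels(self):
        lay = ec.standard_1020_layout(["O2", "Fp1"])
        full = ec.standard_1020_layout()
        assert np.allclose(lay.coords[0], full.coords[full.labels.index("O2")])


# ---------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------

class TestExtractFeatures:
    def test_constant_channel_raw_mode_is_zero_row(self):
        sig = np.vstack([np.ones(100), np.sin(np.arange(100))])
        clip = ec.EEGClip(sig, fs=100.0)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            fm = ec.extract_features(clip, "raw", D=20)
        assert np.allclose(fm.X[0], 0.0)

    def test_sinusoid_peaks_at_its_bin(self):
        n, f = 256, 17
        t = np.arange(n)
        sig = np.vstack([np.sin(2 * np.pi * f * t / n), np.sin(2 * np.pi * 5 * t / n)])
        fm = ec.extract_features(ec.EEGClip(sig, fs=256.0), "spectral", D=64)
        assert int(np.argmax(fm.X[0])) == f
        assert int(np.argmax(fm.X[1])) == 5

    @pytest.mark.parametrize("mode", ["spectral", "raw"])
    def test_row_count_equals_channel_count(self, rng, mode):
        clip = ec.EEGClip(rng.standard_normal((7, 200)), fs=100.0)
        assert ec.extract_features(clip, mode, D=32).X.shape == (7, 32)

    def test_spectral_dimension_bound(self, rng):
        clip = ec.EEGClip(rng.standard_normal((3, 40)), fs=40.0)
        with pytest.raises(ValueError):
            ec.extract_features(clip, "spectral", D=30)


# ---------------------------------------------------------------------
# builders vs oracles
# ---------------------------------------------------------------------

def random_layout(rng, n):
    coords = rng.standard_normal((n, 3))
    return ec.ElectrodeLayout(coords, tuple(f"E{i}" for i in range(n)))


class TestBuilders:
    def test_coincident_electrodes_weight_one(self):
        lay = ec.ElectrodeLayout(np.array([[0, 0, 1.0], [0, 0, 1.0]]), ("a", "b"))
        A = ec.build_dist_graph(lay, tau=0.7)
        assert A.A[0, 1] == pytest.approx(1.0)

    def test_distant_pair_zeroed(self):
        # antipodal unit vectors: distance 2 > k = 0.9
        lay = ec.ElectrodeLayout(np.array([[1, 0, 0.0], [-1, 0, 0.0]]), ("a", "b"))
        A = ec.build_dist_graph(lay)
        assert A.A[0, 1] == 0.0 and A.A[0, 0] == 1.0

    def test_dist_requires_positive_tau(self):
        with pytest.raises(ValueError):
            ec.build_dist_graph(ec.standard_1020_layout(), tau=0.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_dist_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lay = random_layout(rng, 19)
        got = ec.build_dist_graph(lay, tau=1.0, k=0.9).A
        assert np.allclose(got, oracle_dist(lay.coords, 1.0, 0.9), atol=1e-10)

    def test_perfectly_correlated_row_retained(self, rng):
        X = rng.standard_normal((6, 20))
        X[1] = 2.0 * X[0]
        A = ec.build_corr_graph(ec.FeatureMatrix(X)).A
        assert A[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_corr_row_support_at_most_three(self, rng):
        X = rng.standard_normal((19, 64))
        A = ec.build_corr_graph(ec.FeatureMatrix(X)).A
        assert ((A != 0).sum(axis=1) <= 3).all()

    @pytest.mark.parametrize("seed", range(6))
    def test_corr_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((8, 16))
        got = ec.build_corr_graph(ec.FeatureMatrix(X)).A
        assert np.allclose(got, oracle_corr(X), atol=1e-10)

    def test_corr_small_graph_keeps_everything(self, rng):
        X = rng.standard_normal((3, 10))
        A = ec.build_corr_graph(ec.FeatureMatrix(X)).A
        assert ((A != 0).sum(axis=1) == 2).all()

    def test_rand_graph_closed_form(self):
        A = ec.build_rand_graph(3).A
        assert np.array_equal(A, [[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1]])
        assert np.allclose(ec.build_rand_graph(7).A.sum(axis=1), 1 + 0.5 * 6)
        assert np.array_equal(ec.build_rand_graph(1).A, [[1.0]])

    def test_full_graph(self):
        assert np.array_equal(ec.build_full_graph(2).A, np.ones((2, 2)))
        A = ec.build_full_graph(5).A
        assert np.array_equal(A, A.T)

    def test_dtf_orthogonal_row_is_zero(self):
        # row 0 exactly orthogonal (after centering) to every other row
        X = np.array(
            [
                [1.0, -1.0, 1.0, -1.0],
                [1.0, 1.0, -1.0, -1.0],
                [2.0, 2.0, -2.0, -2.0],
                [-1.0, -1.0, 1.0, 1.0],
            ]
        )
        A = ec.build_dtf_graph(ec.FeatureMatrix(X)).A
        assert np.array_equal(A[0], np.zeros(4))

    def test_dtf_row_support_at_most_three(self, rng):
        X = rng.standard_normal((19, 64))
        A = ec.build_dtf_graph(ec.FeatureMatrix(X)).A
        assert ((A != 0).sum(axis=1) <= 3).all()

    @pytest.mark.parametrize("seed", range(6))
    def test_dtf_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((6, 16))
        got = ec.build_dtf_graph(ec.FeatureMatrix(X)).A
        assert np.allclose(got, oracle_dtf(X), atol=1e-10)

    def test_dtf_needs_three_channels(self, rng):
        with pytest.raises(ValueError, match="3 channels"):
            ec.build_dtf_graph(ec.FeatureMatrix(rng.standard_normal((2, 8))))

    def test_identity_graph(self):
        A = ec.build_identity_graph(3)
        assert np.array_equal(A.A, np.eye(3))
        assert A.kind == "identity"


class TestNormalizeAdjacency:
    def test_full_graph_entries_one_over_n(self):
        out = ec.normalize_adjacency(ec.build_full_graph(5), add_self_loops=False)
        assert np.allclose(out.A, 1 / 5)

    def test_identity_untouched(self):
        A = ec.build_identity_graph(4)
        assert np.array_equal(ec.normalize_adjacency(A).A, np.eye(4))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        M = np.abs(rng.standard_normal((7, 7)))
        M = (M + M.T) / 2
        A = ec.AdjacencyMatrix(M, "full", {})
        got = ec.normalize_adjacency(A, add_self_loops=True).A
        assert np.allclose(got, oracle_normalize(M, True), atol=1e-12)
        assert np.allclose(got, got.T)

    def test_zero_degree_without_self_loops_raises(self):
        A = ec.AdjacencyMatrix(np.zeros((3, 3)), "corr", {})
        with pytest.raises(ValueError, match="degree"):
            ec.normalize_adjacency(A, add_self_loops=False)


class TestProperties:
    @pytest.mark.parametrize("builder", ["dist", "rand", "full", "identity"])
    def test_symmetry(self, rng, builder):
        if builder == "dist":
            A = ec.build_dist_graph(random_layout(rng, 12)).A
        elif builder == "rand":
            A = ec.build_rand_graph(12).A
        elif builder == "full":
            A = ec.build_full_graph(12).A
        else:
            A = ec.build_identity_graph(12).A
        assert np.array_equal(A, A.T)

    def test_dist_weights_non_increasing_in_distance(self, rng):
        lay = random_layout(rng, 19)
        A = ec.build_dist_graph(lay, tau=1.0, k=2.5).A  # radius covers everything
        d = lay.pairwise_distances()
        iu = np.triu_indices(19, 1)
        order = np.argsort(d[iu])
        w = A[iu][order]
        assert (np.diff(w) <= 1e-12).all()

    def test_construction_deterministic(self, rng):
        X = ec.FeatureMatrix(rng.standard_normal((10, 32)))
        a = ec.build_corr_graph(X).A
        b = ec.build_corr_graph(X).A
        assert np.array_equal(a, b)

    def test_json_roundtrip(self, small_graph):
        back = graph_from_json(graph_to_json(small_graph, STANDARD_1020_CHANNELS[:8]))
        assert np.array_equal(back.A.A, small_graph.A.A)
        assert np.array_equal(back.X.X, small_graph.X.X)
        assert back.A.kind == "corr"


# ---------------------------------------------------------------------
# randomized invariants (hypothesis)
# ---------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@given(n=st.integers(2, 19), seed=st.integers(0, 2**20))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_dist_graph_symmetric_bounded(n, seed):
    rng = np.random.default_rng(seed)
    A = ec.build_dist_graph(random_layout(rng, n)).A
    assert np.array_equal(A, A.T)
    assert np.all((A >= 0) & (A <= 1))
    assert np.allclose(np.diag(A), 1.0)


@given(n=st.integers(4, 19), d=st.integers(4, 32), seed=st.integers(0, 2**20))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_corr_graph_sparsity_and_weight_range(n, d, seed):
    rng = np.random.default_rng(seed)
    A = ec.build_corr_graph(ec.FeatureMatrix(rng.standard_normal((n, d)))).A
    assert ((A != 0).sum(axis=1) <= 3).all()
    assert np.all(np.abs(A) <= 1 + 1e-12)
    assert np.all(np.diag(A) == 0)


@given(n=st.integers(2, 12), seed=st.integers(0, 2**20))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_normalized_adjacency_spectrum_bounded_by_one(n, seed):
    # for symmetric nonnegative M = A + I, eigenvalues of D^{-1/2} M D^{-1/2}
    # lie in [-1, 1] with the top eigenvalue exactly 1
    rng = np.random.default_rng(seed)
    M = np.abs(rng.standard_normal((n, n)))
    M = (M + M.T) / 2
    out = ec.normalize_adjacency(ec.AdjacencyMatrix(M, "full", {})).A
    eig = np.linalg.eigvalsh(out)
    assert np.all(np.abs(eig) <= 1 + 1e-9)
    assert eig.max() == pytest.approx(1.0)
    assert np.allclose(out, out.T)


def test_matrix_to_csv_header_is_channel_labels(tmp_path, rng, small_graph):
    import pandas as pd

    labels = [f"E{i}" for i in range(8)]
    path = tmp_path / "A.csv"
    ec.graphs.matrix_to_csv(small_graph.A.A, labels, path)
    back = pd.read_csv(path, index_col="channel")
    assert list(back.columns) == labels
    assert np.allclose(back.to_numpy(), small_graph.A.A, atol=1e-10)
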