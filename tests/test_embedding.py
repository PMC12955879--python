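"""Joint matrix assembly, similarity transform, spectral embedding, distances."""

import numpy as np
import pandas as pd
import pytest

import afblueprint as af
from afblueprint.divergence import DivergenceMatrix


def dm(values, level="region"):
    values = np.asarray(values, float)
    return DivergenceMatrix(values, level,
                            tuple(f"r{i}" for i in range(values.shape[0])),
                            tuple(f"c{j}" for j in range(values.shape[1])))


def sym(rng, n):
    m = rng.random((n, n))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return m


class TestAssembleJoint:
    def test_identical_blocks(self, rng):
        w = dm(sym(rng, 3))
        joint = af.assemble_joint(w, w, w)
        assert joint.values.shape == (6, 6)
        for bi in (slice(0, 3), slice(3, 6)):
            for bj in (slice(0, 3), slice(3, 6)):
                assert np.allclose(joint.values[bi, bj], w.values)

    def test_hand_assembled_five_by_five(self, rng):
        wa, wb = sym(rng, 3), sym(rng, 2)
        wab = rng.random((3, 2))
        joint = af.assemble_joint(dm(wa), dm(wb), dm(wab))
        expect = np.block([[wa, wab], [wab.T, wb]])
        assert np.allclose(joint.values, expect)
        assert np.allclose(joint.values, joint.values.T)

    def test_zero_diagonal(self, rng):
        joint = af.assemble_joint(dm(sym(rng, 4)), dm(sym(rng, 3)),
                                  dm(rng.random((4, 3))))
        assert np.allclose(np.diag(joint.values), 0.0)

    def test_asymmetric_within_block_rejected(self, rng):
        bad = rng.random((3, 3))
        with pytest.raises(ValueError, match="asymmetric"):
            af.assemble_joint(dm(bad), dm(sym(rng, 3)), dm(rng.random((3, 3))))

    def test_wrong_cross_shape_rejected(self, rng):
        with pytest.raises(ValueError, match="cross block"):
            af.assemble_joint(dm(sym(rng, 3)), dm(sym(rng, 2)),
                              dm(rng.random((2, 3))))


class TestToSimilarity:
    def test_closed_forms(self, rng):
        w = sym(rng, 3)
        w[0, 1] = w[1, 0] = np.log(2)
        sm = af.to_similarity(af.assemble_joint(dm(w), dm(sym(rng, 2)),
                                                dm(rng.random((3, 2)))))
        assert sm.values[0, 1] == pytest.approx(0.5)
        assert np.allclose(np.diag(sm.values), 1.0)
        assert np.all((sm.values > 0) & (sm.values <= 1))

    def test_monotone_decreasing(self):
        assert np.exp(-0.2) > np.exp(-1.5)  # d1 < d2 -> s1 > s2
        w1 = dm([[0.0, 0.2], [0.2, 0.0]])
        w2 = dm([[0.0, 1.5], [1.5, 0.0]])
        s1 = af.to_similarity(af.assemble_joint(w1, w1, w1))
        s2 = af.to_similarity(af.assemble_joint(w2, w2, w2))
        assert s1.values[0, 1] > s2.values[0, 1]


class TestSpectralEmbed:
    def _embed(self, values, **kw):
        n = values.shape[0]
        sm = af.SimilarityMatrix(values, tuple(f"u{i}" for i in range(n)),
                                 ("A",) * n)
        return af.spectral_embed(sm, **kw)

    def test_two_blocks_separate(self):
        eps = 1e-6
        n = 4
        w = np.full((2 * n, 2 * n), eps)
        w[:n, :n] = 1.0
        w[n:, n:] = 1.0
        emb = self._embed(w)
        within = np.linalg.norm(emb.coords[0] - emb.coords[1])
        cent_a = emb.coords[:n].mean(axis=0)
        cent_b = emb.coords[n:].mean(axis=0)
        across = np.linalg.norm(cent_a - cent_b)
        assert within < 1e-6
        assert across > 10 * max(within, 1e-12)

    def test_permutation_equivariance(self, rng):
        w = np.exp(-sym(rng, 6))
        emb = self._embed(w)
        perm = rng.permutation(6)
        emb_p = self._embed(w[np.ix_(perm, perm)])
        assert np.allclose(emb_p.coords, emb.coords[perm], atol=1e-8)

    def test_duplicated_unit_coincides(self, rng):
        w = np.exp(-sym(rng, 5))
        w[1] = w[0]
        w[:, 1] = w[:, 0]
        w[1, 1] = w[0, 0]
        emb = self._embed(0.5 * (w + w.T))
        assert np.linalg.norm(emb.coords[0] - emb.coords[1]) < 1e-9

    def test_deterministic(self, rng):
        w = np.exp(-sym(rng, 8))
        a = self._embed(w).coords
        b = self._embed(w.copy()).coords
        assert np.array_equal(a, b)

    def test_sign_convention(self, rng):
        coords = self._embed(np.exp(-sym(rng, 7))).coords
        for c in range(2):
            v = coords[:, c]
            assert v[np.argmax(np.abs(v))] > 0

    def test_disconnected_graph_rejected(self):
        w = np.eye(4)
        with pytest.raises(ValueError, match="disconnected"):
            self._embed(w)

    def test_components_match_sklearn_up_to_sign(self, rng):
        pytest.importorskip("sklearn")
        from sklearn.manifold import spectral_embedding
        # shared convention for the cross-check: no self-loops in the graph
        w = np.exp(-sym(rng, 10))
        np.fill_diagonal(w, 0.0)
        ours = self._embed(w).coords
        ref = spectral_embedding(w, n_components=2, drop_first=True,
                                 random_state=0)
        for c in range(2):
            r = np.corrcoef(ours[:, c], ref[:, c])[0, 1]
            assert abs(r) > 0.999


class TestDistances:
    def _emb(self, coords, ids=None, species=None):
        coords = np.asarray(coords, float)
        n = coords.shape[0]
        ids = ids or tuple(f"u{i}" for i in range(n))
        return af.Embedding(coords, np.array([0.1, 0.2]), tuple(ids),
                            tuple(species or ["A"] * n))

    def test_three_four_five(self):
        emb = self._emb([[0, 0], [3, 4]])
        d = af.pair_distances(emb, pd.DataFrame(
            [{"unit_a": "u0", "unit_b": "u1"}]))
        assert d["distance"][0] == pytest.approx(5.0)

    def test_identical_coords_zero(self):
        emb = self._emb([[1, 2], [1, 2]])
        d = af.pair_distances(emb, pd.DataFrame(
            [{"unit_a": "u0", "unit_b": "u1"}]))
        assert d["distance"][0] == 0.0

    def test_matches_hand_formula(self, rng):
        coords = rng.random((6, 2))
        emb = self._emb(coords)
        pairs = pd.DataFrame([{"unit_a": "u0", "unit_b": f"u{j}"}
                              for j in range(1, 6)])
        d = af.pair_distances(emb, pairs)["distance"].to_numpy()
        expect = np.sqrt(((coords[1:] - coords[0]) ** 2).sum(axis=1))
        assert np.allclose(d, expect)

    def test_missing_unit_recorded_not_raised(self):
        emb = self._emb([[0, 0]])
        d = af.pair_distances(emb, pd.DataFrame(
            [{"unit_a": "u0", "unit_b": "nope"}]))
        assert not d["found"][0] and np.isnan(d["distance"][0])

    def test_intra_cluster_collinear_points(self):
        emb = self._emb([[0, 0], [1, 0], [2, 0]])
        dists = af.intra_cluster_distances(emb, {"u0": "c", "u1": "c", "u2": "c"})
        assert sorted(dists["c"].tolist()) == [1.0, 1.0, 2.0]

    def test_singleton_cluster_flagged(self):
        emb = self._emb([[0, 0], [1, 1]])
        dists = af.intra_cluster_distances(emb, {"u0": "a", "u1": "b"})
        assert dists["a"].size == 0
        with pytest.raises(ValueError, match="singleton|sizes"):
            af.compare_clusters(dists, "a", "b")

    def test_cluster_comparison_matches_stats_module(self, rng):
        emb = self._emb(np.vstack([rng.random((5, 2)),
                                   rng.random((5, 2)) + 3.0]))
        labels = {f"u{i}": ("a" if i < 5 else "b") for i in range(10)}
        dists = af.intra_cluster_distances(emb, labels)
        res = af.compare_clusters(dists, "a", "b")
        ref = af.mann_whitney_u(dists["a"], dists["b"])
        assert res.p_value == ref.p_value
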