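"""Symmetric KL divergence: closed forms, oracles, masking, selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import afblueprint as af
from afblueprint.blueprint import Blueprint
from afblueprint.divergence import DivergenceMatrix

from conftest import make_species_pair, normalized_blueprints, random_simplex


def skl_oracle(p, q):
    """Direct base-2 evaluation on strictly positive profiles."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    return float(np.sum(p * np.log2(p / q)) + np.sum(q * np.log2(q / p)))


class TestSymmetricKL:
    def test_identical_profiles_zero(self):
        assert af.symmetric_kl([0.5, 0.5], [0.5, 0.5]) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_value(self):
        # 0.5*log2(2) + 0.5*log2(2/3) + 0.25*log2(0.5) + 0.75*log2(1.5)
        assert af.symmetric_kl([0.5, 0.5], [0.25, 0.75]) == pytest.approx(
            0.39624, abs=1e-4)

    def test_symmetry_on_random_pairs(self, rng):
        for _ in range(100):
            p, q = random_simplex(rng, 6), random_simplex(rng, 6)
            assert af.symmetric_kl(p, q) == pytest.approx(
                af.symmetric_kl(q, p), abs=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8),
           st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    def test_nonnegative_and_matches_oracle(self, pw, qw):
        k = min(len(pw), len(qw))
        p = np.asarray(pw[:k]) / np.sum(pw[:k])
        q = np.asarray(qw[:k]) / np.sum(qw[:k])
        d = af.symmetric_kl(p, q)
        assert d >= 0
        assert d == pytest.approx(skl_oracle(p, q), abs=1e-5)

    def test_epsilon_stability_on_positive_profiles(self, rng):
        p, q = random_simplex(rng, 8), random_simplex(rng, 8)
        d1 = af.symmetric_kl(p, q, eps=1e-8)
        d2 = af.symmetric_kl(p, q, eps=5e-9)
        assert abs(d1 - d2) < 1e-6

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError, match="not a valid"):
            af.symmetric_kl([0.0, 0.0], [0.5, 0.5])
        with pytest.raises(ValueError, match="lengths"):
            af.symmetric_kl([0.5, 0.5], [0.2, 0.3, 0.5])


class TestVertexwiseDivergence:
    def _bp(self, rng, n, k=6):
        return af.normalize_rows(Blueprint(rng.random((n, k)), tuple("abcdef")[:k]))

    def test_identical_blueprints_zero_for_same_vertex(self, rng):
        bp = self._bp(rng, 10)
        vd = af.vertexwise_divergence(bp, bp)
        assert np.allclose(np.diag(vd.values), 0.0, atol=1e-10)

    def test_matches_per_pair_loop_oracle(self, rng):
        bpa, bpb = self._bp(rng, 50), self._bp(rng, 40)
        vd = af.vertexwise_divergence(bpa, bpb)
        for i in range(0, 50, 7):
            for j in range(0, 40, 5):
                assert vd.values[i, j] == pytest.approx(
                    af.symmetric_kl(bpa.values[i], bpb.values[j]), abs=1e-10)

    def test_invalid_row_fully_masked(self, rng):
        vals = rng.random((5, 4))
        vals[2] = 0.0
        bpa = af.normalize_rows(Blueprint(vals, tuple("abcd")))
        bpb = af.normalize_rows(Blueprint(rng.random((6, 4)), tuple("abcd")))
        vd = af.vertexwise_divergence(bpa, bpb)
        assert np.all(np.isnan(vd.values[2]))
        assert not np.any(np.isnan(np.delete(vd.values, 2, axis=0)))

    def test_tract_mismatch_rejected(self, rng):
        bpa = self._bp(rng, 5)
        bpb = af.normalize_rows(Blueprint(rng.random((5, 6)), tuple("ABCDEF")))
        with pytest.raises(ValueError, match="tract"):
            af.vertexwise_divergence(bpa, bpb)

    def test_nonnegative_and_symmetric_in_arguments(self, rng):
        bpa, bpb = self._bp(rng, 12), self._bp(rng, 9)
        vd = af.vertexwise_divergence(bpa, bpb)
        vd_t = af.vertexwise_divergence(bpb, bpa)
        assert np.nanmin(vd.values) >= 0
        assert np.allclose(vd.values, vd_t.values.T, atol=1e-10)


class TestRegionwiseDivergence:
    def test_median_of_small_block(self):
        values = np.array([[1.0, 2.0, 9.0]])
        vd = DivergenceMatrix(values, "vertex", ("A0",), ("B0", "B1", "B2"))
        parc_a = af.Parcellation(np.array([0]), ("RA",))
        parc_b = af.Parcellation(np.array([0, 0, 0]), ("RB",))
        rd = af.regionwise_divergence(vd, parc_a, parc_b)
        assert rd.values[0, 0] == 2.0

    def test_constant_block(self):
        vd = DivergenceMatrix(np.full((4, 4), 3.3), "vertex",
                              tuple("abcd"), tuple("wxyz"))
        parc = af.Parcellation(np.array([0, 0, 1, 1]), ("R0", "R1"))
        rd = af.regionwise_divergence(vd, parc, parc)
        assert np.allclose(rd.values, 3.3)

    def test_matches_brute_force_block_median(self, rng):
        values = rng.random((20, 20))
        vd = DivergenceMatrix(values, "vertex",
                              tuple(f"a{i}" for i in range(20)),
                              tuple(f"b{i}" for i in range(20)))
        parc_a = af.Parcellation(rng.integers(0, 4, 20), tuple("ABCD"))
        parc_b = af.Parcellation(rng.integers(0, 5, 20), tuple("VWXYZ"))
        rd = af.regionwise_divergence(vd, parc_a, parc_b)
        for ra in range(4):
            for rb in range(5):
                block = [values[i, j]
                         for i in parc_a.vertices_of(ra)
                         for j in parc_b.vertices_of(rb)]
                assert rd.values[ra, rb] == pytest.approx(np.median(block))


class TestMinDivergenceMap:
    def test_row_minimum(self):
        dm = DivergenceMatrix(np.array([[3.0, 1.0, 2.0]]), "region", ("r",), tuple("xyz"))
        assert af.min_divergence_map(dm, "rows")[0] == 1.0

    def test_zero_entry_gives_zero(self, rng):
        values = rng.random((4, 4)) + 0.5
        values[2, 1] = 0.0
        dm = DivergenceMatrix(values, "region", tuple("abcd"), tuple("wxyz"))
        assert af.min_divergence_map(dm, "rows")[2] == 0.0

    def test_matches_row_and_col_min_oracle(self, rng):
        values = rng.random((6, 8))
        dm = DivergenceMatrix(values, "region",
                              tuple(f"a{i}" for i in range(6)),
                              tuple(f"b{i}" for i in range(8)))
        assert np.allclose(af.min_divergence_map(dm, "rows"), values.min(axis=1))
        assert np.allclose(af.min_divergence_map(dm, "cols"), values.min(axis=0))

    def test_fully_masked_row_stays_masked(self):
        values = np.array([[np.nan, np.nan], [1.0, 2.0]])
        dm = DivergenceMatrix(values, "region", ("a", "b"), ("x", "y"))
        out = af.min_divergence_map(dm, "rows")
        assert np.isnan(out[0]) and out[1] == 1.0


class TestSelectAfConnected:
    def _bp_with_af(self, af_probs, n_per_region=4):
        """Blueprint whose regions have the given mean AF probability."""
        rows, regions = [], []
        for r, p in enumerate(af_probs):
            for _ in range(n_per_region):
                rest = (1 - p) / 5
                rows.append([p] + [rest] * 5)
                regions.append(r)
        bp = Blueprint(np.array(rows), af.DEFAULT_TRACTS[:6], normalized=True)
        parc = af.Parcellation(np.array(regions),
                               tuple(f"R{r}" for r in range(len(af_probs))))
        return bp, parc

    def test_strict_threshold_boundary(self):
        bp, parc = self._bp_with_af([0.12, 0.10, 0.02])
        sel = af.select_af_connected(bp, parc)
        assert sel.tolist() == [0]  # 0.10 exactly is excluded

    def test_planted_dominant_regions_recovered(self):
        bp, parc = self._bp_with_af([0.02, 0.4, 0.02, 0.4, 0.4, 0.02])
        assert af.select_af_connected(bp, parc).tolist() == [1, 3, 4]

    def test_unknown_tract_rejected(self):
        bp, parc = self._bp_with_af([0.5])
        with pytest.raises(KeyError, match="available"):
            af.select_af_connected(bp, parc, tract="NOPE")


class TestLobeSummary:
    def _dm(self, values):
        n, m = np.asarray(values).shape
        return DivergenceMatrix(np.asarray(values, float), "region",
                                tuple(f"a{i}" for i in range(n)),
                                tuple(f"b{i}" for i in range(m)))

    def test_single_entry_block(self):
        df = af.lobe_summary(self._dm([[2.5]]), ("frontal",), ("frontal",))
        row = df.iloc[0]
        assert row["mean"] == 2.5 and row["sd"] == 0.0 and row["n"] == 1

    def test_hand_two_block_values(self):
        # frontal block pools {1, 3}; temporal block pools {2, 2, 2, 2}
        dm = self._dm([[1.0, 9.0, 9.0], [3.0, 9.0, 9.0],
                       [9.0, 2.0, 2.0], [9.0, 2.0, 2.0]])
        lobes_a = ("frontal", "frontal", "temporal", "temporal")
        lobes_b = ("frontal", "temporal", "temporal")
        df = af.lobe_summary(dm, lobes_a, lobes_b).set_index("lobe")
        assert df.loc["frontal", "mean"] == 2.0
        assert df.loc["frontal", "sd"] == pytest.approx(np.sqrt(2), abs=1e-3)
        assert df.loc["temporal", "mean"] == 2.0
        assert df.loc["temporal", "sd"] == 0.0

    def test_matches_masked_mean_oracle(self, rng):
        values = rng.random((8, 6))
        dm = self._dm(values)
        lobes_a = tuple(rng.choice(["frontal", "temporal"], 8))
        lobes_b = tuple(rng.choice(["frontal", "temporal"], 6))
        df = af.lobe_summary(dm, lobes_a, lobes_b).set_index("lobe")
        for lobe in ("frontal", "temporal"):
            block = values[np.ix_([l == lobe for l in lobes_a],
                                  [l == lobe for l in lobes_b])].ravel()
            if block.size:
                assert df.loc[lobe, "mean"] == pytest.approx(block.mean())

    def test_empty_block_flagged(self):
        dm = self._dm([[1.0]])
        df = af.lobe_summary(dm, ("frontal",), ("temporal",))
        assert df.empty or (df["n"] == 0).all()


class TestPlantedRecovery:
    def test_zero_delta_divergence_vanishes_at_depth(self):
        pair = make_species_pair([0.0], count_depth=1e5, vertices_per_region=10)
        bpa, bpb = normalized_blueprints(pair)
        vd = af.vertexwise_divergence(bpa, bpb)
        rd = af.regionwise_divergence(vd, pair.a.parcellation, pair.b.parcellation)
        assert rd.values[0, 0] < 0.01

    def test_divergence_monotone_in_delta_on_replicate_means(self):
        deltas = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = np.zeros(5)
        n_rep = 10
        for rep in range(n_rep):
            pair = make_species_pair(deltas, seed=1 + rep)
            bpa, bpb = normalized_blueprints(pair)
            vd = af.vertexwise_divergence(bpa, bpb)
            rd = af.regionwise_divergence(vd, pair.a.parcellation,
                                          pair.b.parcellation)
            means += np.array([rd.values[i, i] for i in range(5)]) / n_rep
        assert np.all(np.diff(means) > 0)
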