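"""Similarity matrices, binarization and "see one, get one" fusion."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings, strategies as st

from pairsage.similarity import (
    AssociationMatrix,
    BinaryNetwork,
    binarize,
    fuse_networks,
    jaccard_similarity,
    smith_waterman_similarity,
    tanimoto_similarity,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_jaccard(a, b):
    """Independent oracle: explicit set intersection/union counting."""
    sa = {i for i, v in enumerate(a) if v}
    sb = {i for i, v in enumerate(b) if v}
    if not sa | sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)


def sw_oracle(a, b, matrix_name="BLOSUM62", gap_open=10.0, gap_extend=0.5):
    """Independent quadratic Gotoh DP for local alignment with affine gaps
    (gap of length L costs gap_open + (L - 1) * gap_extend)."""
    sub = substitution_matrices.load(matrix_name)
    n, m = len(a), len(b)
    neg = -1e30
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)
    F = np.full((n + 1, m + 1), neg)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            diag = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, diag, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def assoc(rows, prefix="e"):
    rows = np.asarray(rows, dtype=np.uint8)
    return AssociationMatrix(
        [f"{prefix}{i}" for i in range(rows.shape[0])],
        [f"a{j}" for j in range(rows.shape[1])],
        rows,
    )


class TestJaccard:
    def test_identical_profiles_score_one(self):
        sim = jaccard_similarity(assoc([[1, 1, 0], [1, 1, 0]]))
        assert sim.values[0, 1] == 1.0

    def test_disjoint_profiles_score_zero(self):
        sim = jaccard_similarity(assoc([[1, 0, 0], [0, 1, 0]]))
        assert sim.values[0, 1] == 0.0

    def test_partial_overlap_matches_set_counting(self):
        sim = jaccard_similarity(assoc([[1, 1, 1, 0], [0, 1, 1, 1]]))
        assert sim.values[0, 1] == pytest.approx(brute_jaccard([1, 1, 1, 0], [0, 1, 1, 1]))

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            rows = (rng.random((10, 8)) < 0.4).astype(np.uint8)
            sim = jaccard_similarity(assoc(rows))
            for i in range(10):
                for j in range(10):
                    assert sim.values[i, j] == pytest.approx(
                        brute_jaccard(rows[i], rows[j]), abs=1e-12
                    )

    def test_all_zero_profile_pair_defined_as_zero(self):
        sim = jaccard_similarity(assoc([[0, 0], [0, 0], [1, 0]]))
        assert sim.values[0, 1] == 0.0
        assert sim.values[0, 0] == 0.0  # degenerate diagonal

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            jaccard_similarity(AssociationMatrix([], ["a0"], np.zeros((0, 1))))

    def test_binary_input_enforced(self):
        with pytest.raises(ValueError):
            assoc([[0, 2], [1, 0]])


class TestTanimoto:
    def test_identity_and_disjoint(self):
        sim = tanimoto_similarity(assoc([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]]))
        assert sim.values[0, 1] == 1.0
        assert sim.values[0, 2] == 0.0

    def test_bit_count_oracle(self):
        # a=2, b=2, c=1 -> 1 / (2 + 2 - 1)
        sim = tanimoto_similarity(assoc([[1, 1, 0, 0], [1, 0, 1, 0]]))
        assert sim.values[0, 1] == pytest.approx(1.0 / 3.0)

    def test_matches_brute_force_on_random_fingerprints(self):
        rng = np.random.default_rng(3)
        bits = (rng.random((10, 16)) < 0.3).astype(np.uint8)
        sim = tanimoto_similarity(assoc(bits))
        for i in range(10):
            for j in range(10):
                a = int(bits[i].sum())
                b = int(bits[j].sum())
                c = int((bits[i] & bits[j]).sum())
                expected = c / (a + b - c) if a + b - c else 0.0
                assert sim.values[i, j] == pytest.approx(expected, abs=1e-12)


class TestSmithWaterman:
    def test_self_alignment_normalizes_to_one(self):
        seqs = [("p1", "MKTAYIAKQR"), ("p2", "GGGGSSGGGG")]
        sim = smith_waterman_similarity(seqs)
        assert np.allclose(np.diag(sim.values), 1.0)

    def test_classic_pair_matches_dp_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        raw = smith_waterman_similarity(
            [("a", a), ("b", b)], matrix="BLOSUM50", gap_open=8, gap_extend=8,
            normalize=False,
        )
        assert raw.values[0, 1] == pytest.approx(
            sw_oracle(a, b, "BLOSUM50", 8, 8)
        )

    def test_random_peptides_match_dp_oracle(self):
        rng = np.random.default_rng(11)
        seqs = [
            (f"p{k}", "".join(rng.choice(list(AA), size=rng.integers(5, 31))))
            for k in range(6)
        ]
        raw = smith_waterman_similarity(seqs, normalize=False)
        for i in range(6):
            for j in range(i, 6):
                assert raw.values[i, j] == pytest.approx(
                    sw_oracle(seqs[i][1], seqs[j][1]), abs=1e-9
                )
                # self-alignment dominates under match-dominant scoring
                assert raw.values[i, j] <= min(raw.values[i, i], raw.values[j, j]) + 1e-9
        assert (raw.values >= 0).all()

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman_similarity([("p", "")])

    def test_unknown_residue_rejected_unless_x(self):
        with pytest.raises(ValueError):
            smith_waterman_similarity([("p", "MKTB")])
        smith_waterman_similarity([("p", "MKTX")])  # X tolerated by default
        with pytest.raises(ValueError):
            smith_waterman_similarity([("p", "MKTX")], x_tolerant=False)


class TestBinarize:
    def test_strict_inequality_at_threshold(self):
        from pairsage.similarity import SimilarityMatrix

        sim = SimilarityMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert binarize(sim, 0.5).values[0, 1] == 0  # S_ij == alpha -> no edge

    def test_alpha_zero_gives_complete_graph(self):
        from pairsage.similarity import SimilarityMatrix

        vals = np.full((4, 4), 0.2)
        np.fill_diagonal(vals, 1.0)
        net = binarize(SimilarityMatrix(list("abcd"), vals), 0.0)
        off = ~np.eye(4, dtype=bool)
        assert net.values[off].all()
        assert np.diag(net.values).sum() == 0  # diagonal forced off

    def test_three_by_three_example(self):
        from pairsage.similarity import SimilarityMatrix

        sim = SimilarityMatrix(
            list("abc"), np.array([[1, 0.6, 0.2], [0.6, 1, 0.4], [0.2, 0.4, 1]])
        )
        net = binarize(sim, 0.5)
        expected = np.zeros((3, 3), dtype=np.uint8)
        expected[0, 1] = expected[1, 0] = 1
        assert (net.values == expected).all()

    @given(st.floats(min_value=0, max_value=0.99), st.floats(min_value=0, max_value=0.99))
    @settings(deadline=None, max_examples=25)
    def test_edge_set_shrinks_with_alpha(self, a1, a2):
        from pairsage.similarity import SimilarityMatrix

        rng = np.random.default_rng(5)
        vals = rng.random((6, 6))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        sim = SimilarityMatrix([f"e{i}" for i in range(6)], vals)
        lo, hi = sorted((a1, a2))
        edges_hi = binarize(sim, hi).values
        edges_lo = binarize(sim, lo).values
        assert (edges_hi <= edges_lo).all()

    def test_alpha_range_validated(self):
        from pairsage.similarity import SimilarityMatrix

        sim = SimilarityMatrix(["a"], np.ones((1, 1)))
        with pytest.raises(ValueError):
            binarize(sim, 1.0)


class TestFusion:
    def _net(self, values, alpha=0.5):
        values = np.asarray(values, dtype=np.uint8)
        ids = [f"e{i}" for i in range(values.shape[0])]
        return BinaryNetwork(ids, values, alpha)

    def test_single_network_identity(self):
        v = np.array([[0, 1], [1, 0]], dtype=np.uint8)
        assert (fuse_networks([self._net(v)]).values == v).all()

    def test_union_of_complementary_edges(self):
        a = self._net([[0, 1, 0], [1, 0, 0], [0, 0, 0]])
        b = self._net([[0, 0, 1], [0, 0, 0], [1, 0, 0]])
        fused = fuse_networks([a, b])
        assert fused.values[0, 1] == 1 and fused.values[0, 2] == 1

    def test_elementwise_or_against_loop_oracle(self):
        rng = np.random.default_rng(9)
        nets = [self._net((rng.random((5, 5)) < 0.3).astype(np.uint8) * 0) for _ in range(4)]
        for net in nets:
            m = (rng.random((5, 5)) < 0.4).astype(np.uint8)
            net.values = (m | m.T).astype(np.uint8)
            np.fill_diagonal(net.values, 0)
        fused = fuse_networks(nets)
        for i in range(5):
            for j in range(5):
                if i == j:
                    assert fused.values[i, j] == 0
                else:
                    assert fused.values[i, j] == int(
                        any(n.values[i, j] for n in nets)
                    )

    def test_idempotent_commutative_monotone(self):
        rng = np.random.default_rng(2)
        m1 = (rng.random((6, 6)) < 0.3).astype(np.uint8)
        m2 = (rng.random((6, 6)) < 0.3).astype(np.uint8)
        a, b = self._net(m1 | m1.T), self._net(m2 | m2.T)
        ab = fuse_networks([a, b]).values
        assert (fuse_networks([a, a]).values == fuse_networks([a]).values).all()
        assert (ab == fuse_networks([b, a]).values).all()
        assert (fuse_networks([a]).values <= ab).all()  # adding never removes

    def test_mismatched_ids_rejected(self):
        a = self._net(np.zeros((2, 2), dtype=np.uint8))
        b = BinaryNetwork(["x0", "x1"], np.zeros((2, 2), dtype=np.uint8), 0.5)
        with pytest.raises(ValueError):
            fuse_networks([a, b])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            fuse_networks([])


def test_similarity_outputs_symmetric_in_unit_interval(tiny_synth):
    for mat in [
        jaccard_similarity(tiny_synth.associations["drug_disease"]),
        tanimoto_similarity(tiny_synth.fingerprints),
        smith_waterman_similarity(tiny_synth.sequences[:8]),
    ]:
        assert np.allclose(mat.values, mat.values.T, atol=1e-12)
        assert mat.values.min() >= 0.0 and mat.values.max() <= 1.0 + 1e-12
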