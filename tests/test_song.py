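"""DTW element comparison, motif combination and tutor ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from finchnet.song import (
    ElementTrace,
    dtw_distance,
    element_dissimilarity_matrix,
    male_dissimilarity,
    motif_dissimilarity,
    motif_dissimilarity_matrix,
    motif_pair_dissimilarity,
    standardize_elements,
    tutor_ranking,
)

from .oracles import brute_force_dtw, brute_force_motif_alignment


def _trace(values, bird="b", motif=0, element=0):
    return ElementTrace(np.asarray(values, dtype=float), bird, motif, element)


class TestDtwDistance:
    def test_identical_traces_have_zero_distance(self, rng):
        v = rng.normal(size=(7, 2))
        assert dtw_distance(_trace(v), _trace(v)) == 0.0

    def test_single_point_traces(self):
        assert dtw_distance(_trace([0.0]), _trace([3.0])) == pytest.approx(3.0)

    def test_known_small_example(self):
        # best alignment of (1,2,3) onto (1,3) accumulates cost 1
        assert dtw_distance(_trace([1, 2, 3]), _trace([1, 3])) == pytest.approx(1.0)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            ElementTrace(np.empty((0, 2)))

    def test_feature_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="feature dimensions"):
            dtw_distance(_trace(rng.normal(size=(4, 2))), _trace(rng.normal(size=(4, 3))))

    def test_matches_bruteforce_enumeration_on_short_traces(self, rng):
        for _ in range(300):
            n, m = rng.integers(1, 6, size=2)
            k = int(rng.integers(1, 3))
            a, b = rng.normal(size=(n, k)), rng.normal(size=(m, k))
            expected, lengths = brute_force_dtw(a, b)
            got = dtw_distance(_trace(a), _trace(b))
            assert got == pytest.approx(expected, abs=1e-10)
            norm = dtw_distance(_trace(a), _trace(b), normalize=True)
            assert any(norm == pytest.approx(expected / L, abs=1e-10) for L in lengths)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_self_identity(self, seed):
        r = np.random.default_rng(seed)
        a = r.normal(size=(int(r.integers(1, 12)), 2))
        b = r.normal(size=(int(r.integers(1, 12)), 2))
        assert dtw_distance(_trace(a), _trace(b)) == pytest.approx(
            dtw_distance(_trace(b), _trace(a))
        )
        assert dtw_distance(_trace(a), _trace(a)) == 0.0


class TestElementMatrix:
    def _elements(self, rng, n=5):
        return [
            _trace(rng.normal(size=(int(rng.integers(2, 8)), 2)), f"b{i}", 0, i)
            for i in range(n)
        ]

    def test_matches_pairwise_loop_oracle(self, rng):
        els = self._elements(rng)
        M = element_dissimilarity_matrix(els, normalize=False)
        for i in range(5):
            for j in range(5):
                expected = dtw_distance(els[i], els[j]) if i != j else 0.0
                assert M.iloc[i, j] == pytest.approx(expected)

    def test_symmetric_zero_diagonal(self, rng):
        M = element_dissimilarity_matrix(self._elements(rng))
        assert np.allclose(M, M.T)
        assert np.all(np.diag(M) == 0)

    def test_duplicate_element_content_gives_zero_entry(self, rng):
        v = rng.normal(size=(6, 2))
        els = [_trace(v, "a", 0, 0), _trace(v.copy(), "b", 0, 0)]
        M = element_dissimilarity_matrix(els)
        assert M.iloc[0, 1] == 0.0

    def test_duplicate_keys_rejected(self, rng):
        v = rng.normal(size=(4, 2))
        with pytest.raises(ValueError, match="duplicate"):
            element_dissimilarity_matrix([_trace(v), _trace(v)])


class TestMotifDissimilarity:
    def _setup(self, rng, n_a=2, n_b=3):
        ma = [_trace(rng.normal(size=(5, 2)), "A", 0, i) for i in range(n_a)]
        mb = [_trace(rng.normal(size=(5, 2)), "B", 0, i) for i in range(n_b)]
        em = element_dissimilarity_matrix(ma + mb)
        return ma, mb, em

    def test_identical_motifs_zero(self, rng):
        ma = [_trace(rng.normal(size=(5, 2)), "A", 0, i) for i in range(3)]
        em = element_dissimilarity_matrix(ma)
        assert motif_dissimilarity(ma, ma, em) == 0.0

    def test_single_element_motifs_reduce_to_element_entry(self, rng):
        ma, mb, em = self._setup(rng, 1, 1)
        assert motif_dissimilarity(ma, mb, em) == pytest.approx(
            float(em.loc[ma[0].key, mb[0].key])
        )

    def test_matches_bruteforce_alignment(self, rng):
        ma, mb, em = self._setup(rng, 2, 3)
        cost = np.array(
            [[float(em.loc[a.key, b.key]) for b in mb] for a in ma]
        )
        best, lengths = brute_force_motif_alignment(cost)
        got = motif_dissimilarity(ma, mb, em)
        assert any(got == pytest.approx(best / L) for L in lengths)
        assert motif_dissimilarity(ma, mb, em, normalize=False) == pytest.approx(best)

    def test_missing_element_raises(self, rng):
        ma, mb, em = self._setup(rng)
        stranger = [_trace(rng.normal(size=(4, 2)), "C", 0, 0)]
        with pytest.raises(KeyError, match="missing"):
            motif_dissimilarity(stranger, mb, em)

    def test_pair_dissimilarity_agrees_with_matrix_route(self, rng):
        a = [[_trace(rng.normal(size=(6, 2)), "A", m, i) for i in range(3)]
             for m in range(2)]
        b = [[_trace(rng.normal(size=(6, 2)), "B", m, i) for i in range(3)]
             for m in range(2)]
        em = element_dissimilarity_matrix(
            [el for mot in a + b for el in mot]
        )
        assert motif_pair_dissimilarity(a, b) == pytest.approx(
            male_dissimilarity(a, b, em)
        )

    def test_noise_monotonically_degrades_similarity(self):
        # copies with increasing noise drift away from the original (median
        # over replicates is non-decreasing)
        r = np.random.default_rng(5)
        original = [[_trace(r.normal(size=(15, 2)), "A", 0, i) for i in range(4)]]
        medians = []
        for sd in (0.0, 0.1, 0.3, 0.6):
            d = [
                motif_pair_dissimilarity(
                    original,
                    [[_trace(el.values + rr.normal(0, sd, el.values.shape), "B", 0,
                             el.element_idx) for el in original[0]]],
                )
                for rr in (np.random.default_rng(100 + t) for t in range(20))
            ]
            medians.append(np.median(d))
        assert all(a <= b + 1e-12 for a, b in zip(medians, medians[1:]))
        assert medians[0] == 0.0


class TestStandardize:
    def test_features_zscored_dataset_wide(self, rng):
        motifs = {
            b: [[_trace(rng.normal(2.0, 3.0, size=(10, 2)), b, 0, i) for i in range(2)]]
            for b in ("a", "b", "c")
        }
        std = standardize_elements(motifs)
        allv = np.concatenate(
            [el.values for r in std.values() for mot in r for el in mot]
        )
        assert np.allclose(allv.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(allv.std(axis=0), 1.0, atol=1e-12)


class TestTutorRanking:
    def _matrix(self):
        males = ["dad", "juv", "m1", "m2"]
        M = pd.DataFrame(0.0, index=males, columns=males)
        M.loc["juv", ["dad", "m1", "m2"]] = [0.1, 0.5, 0.3]
        return M + M.T

    def test_father_with_minimal_score_gets_rank_one(self):
        r = tutor_ranking(self._matrix(), "juv", ["dad", "m1", "m2"], father="dad")
        assert r.father_rank == 1
        assert r.primary_tutor == "dad"

    def test_ranks_span_candidate_count(self):
        r = tutor_ranking(self._matrix(), "juv", ["dad", "m1", "m2"], father="dad")
        assert list(r.table["rank"]) == [1, 2, 3]

    def test_ties_break_by_bird_id(self):
        males = ["juv", "x", "a", "b"]
        M = pd.DataFrame(0.0, index=males, columns=males)
        M.loc["juv", ["x", "a", "b"]] = [0.2, 0.2, 0.2]
        r1 = tutor_ranking(M, "juv", ["x", "a", "b"])
        r2 = tutor_ranking(M, "juv", ["b", "a", "x"])
        assert list(r1.table["candidate"]) == ["a", "b", "x"]
        assert list(r1.table["candidate"]) == list(r2.table["candidate"])

    def test_focal_among_candidates_rejected(self):
        with pytest.raises(ValueError, match="candidates"):
            tutor_ranking(self._matrix(), "juv", ["juv", "dad"])


def test_motif_matrix_is_symmetric_nonnegative(rng):
    motifs = {
        b: [[_trace(rng.normal(size=(8, 2)), b, 0, i) for i in range(3)]]
        for b in ("a", "b", "c", "d")
    }
    D = motif_dissimilarity_matrix(motifs)
    assert np.allclose(D, D.T)
    assert (D.to_numpy() >= 0).all()
    assert np.all(np.diag(D) == 0)
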