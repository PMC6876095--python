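import itertools

import numpy as np
import pytest

from probpfp.guidetree import clustalw_weights, upgma
from probpfp.pairwise import mea_align
from probpfp.progressive import (ConsistencyLibrary, Profile,
                                 alignment_to_profile, consistency_transform,
                                 iterative_refine, profile_align,
                                 profile_column_score, profile_to_alignment,
                                 progressive_align, _score_matrix)
from probpfp.scoring import sop_score
from probpfp.seqio import MultipleAlignment, ProteinSequence


def _pair_library(rng, lengths, scale=0.3):
    post = {}
    for i, j in itertools.combinations(range(len(lengths)), 2):
        post[(i, j)] = rng.random((lengths[i], lengths[j])) * scale
    return post


class TestConsistencyTransform:
    def test_two_sequence_identity(self, rng):
        P = rng.random((4, 5)) * 0.4
        lib = consistency_transform({(0, 1): P}, np.ones(2), cutoff=0.0)
        assert np.allclose(lib.get(0, 1), P)

    def test_permutation_composition(self):
        # P_xz and P_zy both near-permutations: the transform concentrates
        # P'_xy on the composed matching.  Checked against explicit
        # hand-multiplied matrices.
        Pxz = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], float)
        Pzy = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]], float)
        Pxy = np.zeros((3, 3))
        w = np.ones(3)
        lib = consistency_transform(
            {(0, 1): Pxy, (0, 2): Pxz, (1, 2): Pzy.T},
            w, cutoff=0.0)
        expected = (2 * Pxy + Pxz @ Pzy) / 3
        assert np.allclose(lib.get(0, 1), expected)

    def test_entries_stay_in_unit_interval(self, rng):
        lengths = [4, 5, 6, 3]
        post = _pair_library(rng, lengths, scale=1.0)
        # make rows sub-stochastic as true posteriors are
        for k, P in post.items():
            post[k] = P / np.maximum(1.0, P.sum(axis=1, keepdims=True))
        lib = consistency_transform(post, np.ones(4), cutoff=0.0)
        for i, j in lib.pairs():
            M = lib.get(i, j)
            assert M.min() >= 0 and M.max() <= 1

    def test_missing_pair_rejected(self, rng):
        with pytest.raises(ValueError, match="missing"):
            consistency_transform({(0, 1): np.zeros((2, 2))}, np.ones(3))

    def test_cutoff_sparsifies(self, rng):
        P = np.full((3, 3), 0.005)
        lib = consistency_transform({(0, 1): P}, np.ones(2), cutoff=0.01)
        assert np.all(lib.get(0, 1) == 0)


class TestColumnScore:
    def _single(self, idx, length):
        return Profile.from_sequence(idx, length)

    def test_single_sequence_reduction(self, rng):
        P = rng.random((3, 4)) * 0.5
        lib = ConsistencyLibrary({(0, 1): P})
        X, Y = self._single(0, 3), self._single(1, 4)
        w = np.ones(2)
        for i in range(3):
            for j in range(4):
                assert profile_column_score(X, Y, i, j, lib, w) == \
                    pytest.approx(P[i, j])

    def test_hand_value_two_by_one(self):
        # two rows against one, all weights 1, posteriors 0.4 and 0.8
        P02 = np.array([[0.4]])
        P12 = np.array([[0.8]])
        lib = ConsistencyLibrary({(0, 1): np.zeros((1, 1)),
                                  (0, 2): P02, (1, 2): P12})
        X = Profile([0, 1], np.zeros((2, 1), dtype=np.int64))
        Y = self._single(2, 1)
        assert profile_column_score(X, Y, 0, 0, lib, np.ones(3)) == \
            pytest.approx(0.6)

    def test_gapped_rows_contribute_nothing(self):
        # row 0 is gapped at the scored column and row 1 has zero posterior:
        # the numerator vanishes while both weight pairs stay in the
        # denominator
        lib = ConsistencyLibrary({
            (0, 1): np.zeros((1, 2)),
            (0, 2): np.array([[0.9]]),
            (1, 2): np.zeros((2, 1)),
        })
        X = Profile([0, 1], np.array([[0, -1], [0, 1]]))
        Y = self._single(2, 1)
        assert profile_column_score(X, Y, 1, 0, lib, np.ones(3)) == 0.0

    def test_out_of_range_rejected(self):
        lib = ConsistencyLibrary({(0, 1): np.zeros((2, 2))})
        with pytest.raises(IndexError):
            profile_column_score(self._single(0, 2), self._single(1, 2),
                                 5, 0, lib, np.ones(2))

    def test_vectorised_matrix_agrees_with_scalar(self, rng):
        lengths = [5, 4, 6]
        lib = ConsistencyLibrary(_pair_library(rng, lengths))
        w = np.array([0.8, 1.1, 1.1])
        X = Profile([0, 2], np.array([[0, 1, -1, 2, 3, 4],
                                      [0, 1, 2, 3, -1, 5]]))
        Y = Profile([1], np.arange(4)[None, :])
        S = _score_matrix(X, Y, lib, w, gap_renorm=False)
        for i in range(X.ncols):
            for j in range(Y.ncols):
                assert S[i, j] == pytest.approx(
                    profile_column_score(X, Y, i, j, lib, w))


class TestProfileAlign:
    def test_two_singletons_reproduce_pairwise_mea(self, rng):
        P = rng.random((5, 6)) * 0.5
        lib = ConsistencyLibrary({(0, 1): P})
        X = Profile.from_sequence(0, 5)
        Y = Profile.from_sequence(1, 6)
        merged = profile_align(X, Y, lib, np.ones(2))
        mea = mea_align(P)
        matched = [
            (merged.pos[0, c], merged.pos[1, c])
            for c in range(merged.ncols)
            if merged.pos[0, c] >= 0 and merged.pos[1, c] >= 0
        ]
        assert matched == mea.matching

    def test_result_length_bounds(self, rng):
        lengths = [4, 7]
        lib = ConsistencyLibrary(_pair_library(rng, lengths))
        merged = profile_align(Profile.from_sequence(0, 4),
                               Profile.from_sequence(1, 7),
                               lib, np.ones(2))
        assert max(lengths) <= merged.ncols <= sum(lengths)

    def test_near_permutation_library_stacks_diagonally(self):
        n, L = 3, 4
        post = {
            (i, j): np.eye(L) * 0.9
            for i in range(n) for j in range(i + 1, n)
        }
        lib = ConsistencyLibrary(post)
        w = np.ones(n)
        merged = profile_align(
            profile_align(Profile.from_sequence(0, L),
                          Profile.from_sequence(1, L), lib, w),
            Profile.from_sequence(2, L), lib, w)
        assert merged.ncols == L
        assert np.array_equal(merged.pos,
                              np.tile(np.arange(L), (n, 1)))

    def test_overlapping_rows_rejected(self):
        lib = ConsistencyLibrary({(0, 1): np.zeros((2, 2))})
        with pytest.raises(ValueError, match="disjoint"):
            profile_align(Profile.from_sequence(0, 2),
                          Profile.from_sequence(0, 2), lib, np.ones(2))


class TestProgressiveAndRefine:
    def _identity_setup(self, n, residues="ARNDCQ"):
        family = [ProteinSequence(f"s{k + 1}", residues) for k in range(n)]
        L = len(residues)
        post = {(i, j): np.eye(L) * 0.95
                for i in range(n) for j in range(i + 1, n)}
        lib = ConsistencyLibrary(post)
        return family, lib

    def test_two_sequences_equal_pairwise_mea(self, rng):
        family = [ProteinSequence("s1", "ARND"), ProteinSequence("s2", "AND")]
        P = rng.random((4, 3)) * 0.5
        lib = ConsistencyLibrary({(0, 1): P})
        D = np.array([[0, 0.5], [0.5, 0]])
        tree = upgma(D, [s.id for s in family])
        aln = progressive_align(tree, lib, np.ones(2), family)
        from probpfp.pairwise import alignment_from_moves
        expected = alignment_from_moves(family[0], family[1],
                                        mea_align(P).moves)
        assert aln.rows == expected.rows

    def test_rows_ungap_to_inputs(self, rng):
        lengths = [5, 6, 4, 7]
        from conftest import random_protein
        family = [random_protein(rng, L, f"s{k}")
                  for k, L in enumerate(lengths)]
        lib = ConsistencyLibrary(_pair_library(rng, lengths))
        D = np.array([[0, .2, .4, .6], [.2, 0, .5, .7],
                      [.4, .5, 0, .3], [.6, .7, .3, 0]])
        tree = upgma(D, [s.id for s in family])
        aln = progressive_align(tree, lib, np.ones(4), family)
        for k, s in enumerate(family):
            assert aln.ungapped(k) == s.residues

    def test_planted_core_aligned_across_all_rows(self):
        family, lib = self._identity_setup(4)
        D = np.full((4, 4), 0.1)
        np.fill_diagonal(D, 0)
        tree = upgma(D, [s.id for s in family])
        aln = progressive_align(tree, lib, np.ones(4), family)
        assert all(g == "ARNDCQ" for _, g in aln.rows)

    def test_refine_zero_iterations_identity(self):
        family, lib = self._identity_setup(3)
        aln = MultipleAlignment([(s.id, s.residues) for s in family])
        out = iterative_refine(aln, lib, np.ones(3), family, iters=0)
        assert out.rows == aln.rows

    def test_refine_never_decreases_sop(self, rng):
        family, lib = self._identity_setup(3)
        start = MultipleAlignment([
            ("s1", "ARNDCQ-"), ("s2", "ARNDCQ-"), ("s3", "-ARNDCQ"),
        ])
        base = sop_score(start)
        for seed in range(20):
            out = iterative_refine(start, lib, np.ones(3), family, iters=3,
                                   rng=np.random.default_rng(seed))
            assert sop_score(out) >= base

    def test_refine_recovers_shifted_row(self):
        # the progressive stage is simulated as having misplaced s3 by one
        # column; a bipartition that isolates s3 must recover the
        # strictly better diagonal stacking
        family, lib = self._identity_setup(3)
        start = MultipleAlignment([
            ("s1", "ARNDCQ-"), ("s2", "ARNDCQ-"), ("s3", "-ARNDCQ"),
        ])
        out = iterative_refine(start, lib, np.ones(3), family, iters=10,
                               rng=np.random.default_rng(0))
        assert sop_score(out) > sop_score(start)
        assert all(g == "ARNDCQ" for _, g in out.rows)

    def test_refine_output_order_is_input_order(self):
        family, lib = self._identity_setup(3)
        start = MultipleAlignment([
            ("s1", "ARNDCQ-"), ("s2", "-ARNDCQ"), ("s3", "ARNDCQ-"),
        ])
        out = iterative_refine(start, lib, np.ones(3), family, iters=5,
                               rng=np.random.default_rng(1))
        assert out.ids == ["s1", "s2", "s3"]

    def test_profile_alignment_round_trip(self, rng):
        family, lib = self._identity_setup(3)
        aln = MultipleAlignment([
            ("s1", "ARNDCQ-"), ("s2", "ARNDCQ-"), ("s3", "-ARNDCQ"),
        ])
        prof = alignment_to_profile(aln, family)
        assert profile_to_alignment(prof, family).rows == aln.rows
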