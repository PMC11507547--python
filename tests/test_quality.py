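import itertools

import numpy as np
import pytest

from coitad import (
    ContactMatrix,
    Segment,
    inter_score,
    intra_score,
    overall_quality,
    select_best_radius,
    tad_quality,
)
from coitad.domains import DomainCall

from conftest import random_symmetric


def tad(s, e):
    return Segment(s, e, 0, category="tad")


def call_of(tads, resolution_kb=40):
    # quality only reads the tad list; coverage is irrelevant here
    return DomainCall(segments=list(tads), radius=2, resolution_kb=resolution_kb, min_tad_bins=5)


def block_matrix(blocks, values, n, fill=0.0):
    m = np.full((n, n), fill)
    for (s, e), v in zip(blocks, values):
        m[s : e + 1, s : e + 1] = v
    return ContactMatrix(m, resolution_kb=40)


class TestIntraInter:
    def test_constant_block_mean_is_value(self):
        m = block_matrix([(2, 5)], [7.5], 8, fill=1.0)
        assert intra_score(m, tad(2, 5)) == pytest.approx(7.5)

    def test_single_bin_tad_is_diagonal_entry(self, random_matrix):
        m = random_matrix(6)
        assert intra_score(m, tad(3, 3)) == pytest.approx(m.values[3, 3])

    def test_intra_matches_double_loop(self, rng):
        values = random_symmetric(rng, 8)
        m = ContactMatrix(values, resolution_kb=40)
        brute = np.mean([values[i, j] for i in range(2, 6) for j in range(2, 6)])
        assert intra_score(m, tad(2, 5)) == pytest.approx(brute, abs=1e-12)

    def test_inter_zero_rectangle(self):
        m = block_matrix([(0, 2), (3, 6)], [5.0, 9.0], 7)
        assert inter_score(m, tad(0, 2), tad(3, 6)) == 0.0

    def test_inter_constant_rectangle(self):
        m = ContactMatrix(np.full((6, 6), 4.25), resolution_kb=40)
        assert inter_score(m, tad(0, 2), tad(3, 5)) == pytest.approx(4.25)

    def test_inter_matches_double_loop(self, rng):
        values = random_symmetric(rng, 9)
        m = ContactMatrix(values, resolution_kb=40)
        brute = np.mean([values[i, j] for i in range(0, 3) for j in range(3, 7)])
        assert inter_score(m, tad(0, 2), tad(3, 6)) == pytest.approx(brute, abs=1e-12)

    def test_inter_identical_segments_rejected(self, random_matrix):
        m = random_matrix(6)
        with pytest.raises(ValueError):
            inter_score(m, tad(1, 3), tad(1, 3))


class TestTadQuality:
    def test_ideal_block_matrix_interior_quality(self):
        blocks = [(0, 3), (4, 8), (9, 12)]
        m = block_matrix(blocks, [10.0, 10.0, 10.0], 13)
        tads = [tad(*b) for b in blocks]
        assert tad_quality(m, tads, 1) == pytest.approx(10.0)

    def test_uniform_matrix_quality_zero(self):
        m = ContactMatrix(np.full((10, 10), 3.0), resolution_kb=40)
        tads = [tad(0, 4), tad(5, 9)]
        for i in range(2):
            assert tad_quality(m, tads, i) == pytest.approx(0.0)

    def test_lone_tad_quality_is_intra(self, random_matrix):
        m = random_matrix(8)
        tads = [tad(1, 5)]
        assert tad_quality(m, tads, 0) == pytest.approx(intra_score(m, tads[0]))

    def test_matches_composed_oracle(self, rng):
        values = random_symmetric(rng, 14)
        m = ContactMatrix(values, resolution_kb=40)
        tads = [tad(0, 3), tad(4, 9), tad(10, 13)]
        for i in range(3):
            inters = [
                inter_score(m, tads[i], tads[j])
                for j in (i - 1, i + 1)
                if 0 <= j < 3
            ]
            expected = intra_score(m, tads[i]) - np.mean(inters)
            assert tad_quality(m, tads, i) == pytest.approx(expected, abs=1e-9)


class TestOverallQuality:
    def test_single_tad_constant_matrix(self):
        m = ContactMatrix(np.full((6, 6), 10.0), resolution_kb=40)
        assert overall_quality(m, call_of([tad(0, 5)])) == pytest.approx(10.0)

    def test_no_tads_scores_worst(self, random_matrix):
        m = random_matrix(6)
        boundary = Segment(0, 5, 0, category="boundary")
        assert overall_quality(m, call_of([boundary])) == float("-inf")

    def test_mean_of_tad_qualities(self, rng):
        values = random_symmetric(rng, 12)
        m = ContactMatrix(values, resolution_kb=40)
        tads = [tad(0, 3), tad(4, 7), tad(8, 11)]
        expected = np.mean([tad_quality(m, tads, i) for i in range(3)])
        assert overall_quality(m, call_of(tads)) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_global_scaling(self, rng):
        values = random_symmetric(rng, 12)
        tads = [tad(0, 5), tad(6, 11)]
        q1 = overall_quality(ContactMatrix(values, resolution_kb=40), call_of(tads))
        q2 = overall_quality(ContactMatrix(values * 3.0, resolution_kb=40), call_of(tads))
        assert q2 == pytest.approx(3.0 * q1, rel=1e-12)


class TestSelectBestRadius:
    def test_argmax_with_smallest_radius_tiebreak(self):
        assert select_best_radius({2: 5.0, 3: 7.5, 4: 7.5}) == 3

    def test_single_entry(self):
        assert select_best_radius({2: -1.0}) == 2

    def test_matches_linear_scan(self, rng):
        scores = {r: float(rng.normal()) for r in range(2, 21)}
        best = max(sorted(scores), key=lambda r: scores[r])
        assert select_best_radius(scores) == best

    def test_removing_dominated_radius_is_neutral(self, rng):
        scores = {r: float(rng.normal()) for r in range(2, 12)}
        best = select_best_radius(scores)
        dominated = min(scores, key=lambda r: scores[r])
        if dominated != best:
            reduced = {r: s for r, s in scores.items() if r != dominated}
            assert select_best_radius(reduced) == best

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_radius({})


class TestTruePartitionDominance:
    """On a noiseless block matrix the planted partition strictly beats every
    one-bin boundary shift and every merge of two adjacent blocks."""

    def test_exhaustive_small_instance(self):
        blocks = [(0, 7), (8, 18), (19, 29)]
        m = block_matrix(blocks, [10.0, 14.0, 12.0], 30)
        truth = [tad(*b) for b in blocks]
        q_true = overall_quality(m, call_of(truth))

        # every single interior boundary shifted by one bin either way
        for b in range(1, len(blocks)):
            for delta in (-1, 1):
                shifted = [list(x) for x in blocks]
                shifted[b - 1][1] += delta
                shifted[b][0] += delta
                if shifted[b - 1][0] > shifted[b - 1][1] or shifted[b][0] > shifted[b][1]:
                    continue
                alt = call_of([tad(s, e) for s, e in shifted])
                assert overall_quality(m, alt) < q_true

        # every merge of two adjacent blocks
        for b in range(len(blocks) - 1):
            merged = blocks[:b] + [(blocks[b][0], blocks[b + 1][1])] + blocks[b + 2 :]
            alt = call_of([tad(s, e) for s, e in merged])
            assert overall_quality(m, alt) < q_true
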