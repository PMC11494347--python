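"""k-mer decomposition, similarity matrices, SHARK scores and baselines.

Matrix-based scores are checked against nested-loop brute-force
recomputation; count-vector baselines against dense closed forms.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_sequence
from sharkdive.kmer_scores import (SequenceTooShortError,
                                   euclidean_kmer_distance, extract_kmers,
                                   kmer_similarity, kmer_similarity_matrix,
                                   ngd, shark_score_T, shark_score_best,
                                   similarity_ratio)
from sharkdive.physchem import ALPHABET, default_similarity_matrix

MATRIX = default_similarity_matrix()

seq_strategy = st.text(alphabet=ALPHABET, min_size=1, max_size=30)


def brute_force_w(s1, s2, k):
    k1 = extract_kmers(s1, k).kmers
    k2 = extract_kmers(s2, k).kmers
    w = np.zeros((len(k1), len(k2)))
    for i, x in enumerate(k1):
        for j, y in enumerate(k2):
            w[i, j] = np.mean([MATRIX.sim(a, b) for a, b in zip(x, y)])
    return w


def test_extract_kmers_examples():
    kl = extract_kmers("ACDE", 2)
    assert kl.kmers == ("AC", "CD", "DE")
    assert kl.start_positions == (0, 1, 2)
    assert extract_kmers("ACDE", 1).kmers == ("A", "C", "D", "E")
    with pytest.raises(SequenceTooShortError):
        extract_kmers("AC", 3)
    with pytest.raises(ValueError):
        extract_kmers("ACDE", 0)


def test_kmer_counts_and_offsets(rng):
    s = random_sequence(rng, 25)
    for k in (1, 3, 7):
        kl = extract_kmers(s, k)
        assert len(kl.kmers) == len(s) - k + 1
        for mer, pos in zip(kl.kmers, kl.start_positions):
            assert s[pos:pos + k] == mer


def test_kmer_similarity_examples():
    assert kmer_similarity("GGG", "GGG") == 1.0
    assert kmer_similarity("LI", "IL") == pytest.approx(1 - 5 / 215, abs=1e-4)
    assert kmer_similarity("CW", "WC") == pytest.approx(0.0)
    with pytest.raises(ValueError, match="mismatch"):
        kmer_similarity("AA", "AAA")


def test_matrix_examples():
    km = kmer_similarity_matrix("AAA", "AAA", 2)
    assert km.w.shape == (2, 2) and np.allclose(km.w, 1.0)
    km = kmer_similarity_matrix("CC", "WW", 2)
    assert km.w.shape == (1, 1) and km.w[0, 0] == pytest.approx(0.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seq_strategy, seq_strategy, st.integers(1, 5))
def test_matrix_equals_brute_force(s1, s2, k):
    if min(len(s1), len(s2)) < k:
        return
    km = kmer_similarity_matrix(s1, s2, k)
    assert np.allclose(km.w, brute_force_w(s1, s2, k), atol=0, rtol=0)
    # transposing the sequence order transposes w exactly
    assert np.array_equal(kmer_similarity_matrix(s2, s1, k).w, km.w.T)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seq_strategy, seq_strategy, st.integers(1, 5))
def test_shark_best_brute_force_and_symmetry(s1, s2, k):
    if min(len(s1), len(s2)) < k:
        return
    w = brute_force_w(s1, s2, k)
    expected = (w.max(axis=1).mean() + w.max(axis=0).mean()) / 2
    assert shark_score_best(s1, s2, k) == pytest.approx(expected, abs=1e-12)
    assert shark_score_best(s1, s2, k) == \
        pytest.approx(shark_score_best(s2, s1, k), abs=1e-12)


def test_shark_best_identity_and_extreme(rng):
    s = random_sequence(rng, 18)
    for k in (1, 4, 9, len(s)):
        assert shark_score_best(s, s, k) == pytest.approx(1.0, abs=1e-12)
    assert shark_score_best("CC", "WW", 2) == 0.0


def test_shark_best_superstring_directional(rng):
    # every k-mer of s occurs in its superstring: directional best = 1
    s = random_sequence(rng, 12)
    sup = random_sequence(rng, 5) + s + random_sequence(rng, 5)
    k = 4
    w = brute_force_w(s, sup, k)
    assert w.max(axis=1).mean() == pytest.approx(1.0, abs=1e-12)
    assert shark_score_best(s, sup, k) >= w.max(axis=0).mean() - 1e-12


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seq_strategy, seq_strategy, st.integers(1, 4),
       st.floats(0, 1), st.floats(0, 1))
def test_shark_T_brute_force_and_monotonicity(s1, s2, k, t1, t2):
    if min(len(s1), len(s2)) < k:
        return
    w = brute_force_w(s1, s2, k)
    for t in (t1, t2):
        expected = w[w >= t].sum() / w.size
        assert shark_score_T(s1, s2, k, t) == pytest.approx(expected, abs=1e-12)
    lo, hi = min(t1, t2), max(t1, t2)
    assert shark_score_T(s1, s2, k, hi) <= shark_score_T(s1, s2, k, lo) + 1e-12


def test_shark_T_examples():
    assert shark_score_T("AAAA", "AAAA", 2, 0.8) == 1.0
    assert shark_score_T("CC", "WW", 2, 0.5) == 0.0
    with pytest.raises(ValueError):
        shark_score_T("AAAA", "AAAA", 2, 1.5)


def test_ngd_conventions_and_closed_form():
    assert ngd("ACDEF", "ACDEF", 3) == 0.0
    assert ngd("AAAA", "WWWW", 2) == 1.0  # disjoint k-mer sets
    # |X|=3, |Y|=3, |I|=2, k=2: (ln3-ln2)/(ln400-ln3)
    s1, s2 = "ACDE", "CDEF"  # sets {AC,CD,DE} and {CD,DE,EF}
    expected = (math.log(3) - math.log(2)) / (math.log(400) - math.log(3))
    assert ngd(s1, s2, 2) == pytest.approx(expected, abs=1e-6)
    assert expected == pytest.approx(0.0829, abs=5e-4)


def test_euclidean_closed_forms(rng):
    assert euclidean_kmer_distance("ACDE", "ACDE", 2) == 0.0
    assert euclidean_kmer_distance("AA", "CC", 1) == pytest.approx(math.sqrt(8))
    s1, s2 = random_sequence(rng, 20), random_sequence(rng, 15)
    # dense brute force over the full 400-dim 2-mer space
    mers = [a + b for a in ALPHABET for b in ALPHABET]
    v1 = np.array([extract_kmers(s1, 2).kmers.count(m) for m in mers])
    v2 = np.array([extract_kmers(s2, 2).kmers.count(m) for m in mers])
    assert euclidean_kmer_distance(s1, s2, 2) == \
        pytest.approx(np.linalg.norm(v1 - v2), abs=1e-12)
    assert similarity_ratio(s1, s2, 2) == pytest.approx(
        v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), abs=1e-12)


def test_similarity_ratio_examples():
    assert similarity_ratio("ACDE", "ACDE", 2) == pytest.approx(1.0)
    assert similarity_ratio("AAAA", "WWWW", 2) == 0.0
    assert similarity_ratio("AAC", "ACC", 1) == pytest.approx(4 / 5)


def test_count_based_scores_invariant_to_kmer_order():
    # residue shuffles preserving the 1-mer multiset leave the
    # count/set-based baselines unchanged
    s = "ACDEFG"
    p1, p2 = "GFEDCA", "CADEFG"  # two permutations of the same multiset
    for fn in (euclidean_kmer_distance, similarity_ratio, ngd):
        assert fn(s, p1, 1) == pytest.approx(fn(s, p2, 1), abs=1e-12)


def test_scores_symmetric(rng):
    s1, s2 = random_sequence(rng, 22), random_sequence(rng, 17)
    for fn in (lambda a, b: shark_score_best(a, b, 3),
               lambda a, b: shark_score_T(a, b, 3, 0.7),
               lambda a, b: ngd(a, b, 3),
               lambda a, b: euclidean_kmer_distance(a, b, 3),
               lambda a, b: similarity_ratio(a, b, 3)):
        assert fn(s1, s2) == pytest.approx(fn(s2, s1), abs=1e-12)


def test_too_short_raises_everywhere():
    for fn in (lambda: shark_score_best("AC", "ACDE", 3),
               lambda: shark_score_T("AC", "ACDE", 3, 0.5),
               lambda: ngd("AC", "ACDE", 3),
               lambda: euclidean_kmer_distance("AC", "ACDE", 3),
               lambda: similarity_ratio("AC", "ACDE", 3)):
        with pytest.raises(SequenceTooShortError):
            fn()
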