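"""Alignment-free k-mer scores between protein sequences.

Two sequences are decomposed into overlapping k-mers (stride 1).  Each
k-mer pair (x, y) receives a physicochemical similarity

    w(x, y) = (1/k) * sum_i sim(x_i, y_i)

the position-wise mean of Grantham residue similarities (ungapped,
collinear within the k-mer).  The n1 x n2 matrix of w values is then
aggregated into sequence-level scores:

``shark_score_best``
    for every k-mer of one sequence take its best match in the other,
    average, and symmetrise as the mean of the two directions — 1 for
    identical sequences, higher means more similar.
``shark_score_T``
    the sum of all w >= T divided by n1*n2 — counts every sufficiently
    similar k-mer pair, not just the best one.

Three classical alignment-free baselines operate on k-mer count
vectors / sets instead of physicochemical similarity: Euclidean
distance, cosine Similarity Ratio, and the Normalized Google Distance
(NGD) over distinct k-mer sets with corpus size 20**k.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .physchem import ALPHABET, ResidueSimilarityMatrix, default_similarity_matrix


class SequenceTooShortError(ValueError):
    """Sequence shorter than the requested k-mer length."""


@dataclass(frozen=True)
class KmerList:
    parent_id: str
    k: int
    kmers: tuple[str, ...]
    start_positions: tuple[int, ...]


def extract_kmers(sequence: str, k: int, parent_id: str = "") -> KmerList:
    """All overlapping k-mers of ``sequence`` with their 0-based offsets."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    sequence = sequence.upper()
    if len(sequence) < k:
        raise SequenceTooShortError(
            f"sequence of length {len(sequence)} has no {k}-mers")
    n = len(sequence) - k + 1
    return KmerList(parent_id=parent_id, k=k,
                    kmers=tuple(sequence[i:i + k] for i in range(n)),
                    start_positions=tuple(range(n)))


def kmer_similarity(x: str, y: str,
                    matrix: ResidueSimilarityMatrix | None = None) -> float:
    """Position-wise mean residue similarity of two equal-length k-mers."""
    if len(x) != len(y):
        raise ValueError(f"k-mer length mismatch: {len(x)} vs {len(y)}")
    matrix = matrix or default_similarity_matrix()
    ix, iy = matrix.encode(x), matrix.encode(y)
    return float(matrix.matrix[ix, iy].mean())


def residue_level_similarity(s1: str, s2: str,
                             matrix: ResidueSimilarityMatrix) -> np.ndarray:
    """len(s1) x len(s2) matrix of residue similarities (the k=1 grid)."""
    i1, i2 = matrix.encode(s1), matrix.encode(s2)
    return matrix.matrix[np.ix_(i1, i2)]


def _window_mean(S: np.ndarray, k: int) -> np.ndarray:
    """Mean of S over length-k diagonal windows.

    Given the residue-level grid S (L1 x L2), returns W with
    W[i, j] = mean(S[i+t, j+t] for t in 0..k-1), i.e. the k-mer
    similarity matrix, shape (L1-k+1) x (L2-k+1).
    """
    n1, n2 = S.shape[0] - k + 1, S.shape[1] - k + 1
    W = S[:n1, :n2].copy()
    for t in range(1, k):
        W += S[t:t + n1, t:t + n2]
    return W / k


@dataclass(frozen=True)
class KmerSimilarityMatrix:
    k: int
    rows: KmerList
    cols: KmerList
    w: np.ndarray = field(repr=False)


def kmer_similarity_matrix(s1: str, s2: str, k: int,
                           matrix: ResidueSimilarityMatrix | None = None,
                           id1: str = "seq1", id2: str = "seq2",
                           ) -> KmerSimilarityMatrix:
    """All-vs-all k-mer similarity matrix between two sequences."""
    matrix = matrix or default_similarity_matrix()
    rows = extract_kmers(s1, k, id1)
    cols = extract_kmers(s2, k, id2)
    S = residue_level_similarity(s1.upper(), s2.upper(), matrix)
    return KmerSimilarityMatrix(k=k, rows=rows, cols=cols, w=_window_mean(S, k))


def _best_from_w(w: np.ndarray) -> float:
    return float((w.max(axis=1).mean() + w.max(axis=0).mean()) / 2.0)


def _t_from_w(w: np.ndarray, T: float) -> float:
    return float(w[w >= T].sum() / w.size)


def shark_score_best(s1: str, s2: str, k: int,
                     matrix: ResidueSimilarityMatrix | None = None) -> float:
    """Symmetrised best-match k-mer score in [0, 1]; 1 iff s1 == s2."""
    return _best_from_w(kmer_similarity_matrix(s1, s2, k, matrix).w)


def shark_score_T(s1: str, s2: str, k: int, T: float,
                  matrix: ResidueSimilarityMatrix | None = None) -> float:
    """Threshold-sum k-mer score in [0, 1]; non-increasing in T."""
    if not 0.0 <= T <= 1.0:
        raise ValueError(f"T must be in [0, 1], got {T}")
    return _t_from_w(kmer_similarity_matrix(s1, s2, k, matrix).w, T)


def _kmer_set(s: str, k: int) -> set[str]:
    return set(extract_kmers(s, k).kmers)


def _kmer_counts(s: str, k: int) -> Counter:
    return Counter(extract_kmers(s, k).kmers)


def ngd(s1: str, s2: str, k: int) -> float:
    """Normalized Google Distance over distinct k-mer sets.

    Corpus size N = 20**k (the full k-mer space); 0 for identical sets,
    1 for disjoint sets, clamped to [0, 1].
    """
    X, Y = _kmer_set(s1, k), _kmer_set(s2, k)
    if X == Y:
        return 0.0
    I = X & Y
    if not I:
        return 1.0
    log_n = k * math.log(len(ALPHABET))
    lx, ly = math.log(len(X)), math.log(len(Y))
    value = (max(lx, ly) - math.log(len(I))) / (log_n - min(lx, ly))
    return float(min(1.0, max(0.0, value)))


def euclidean_kmer_distance(s1: str, s2: str, k: int) -> float:
    """Euclidean norm between sparse k-mer count vectors."""
    c1, c2 = _kmer_counts(s1, k), _kmer_counts(s2, k)
    return math.sqrt(sum((c1[m] - c2[m]) ** 2 for m in c1.keys() | c2.keys()))


def similarity_ratio(s1: str, s2: str, k: int) -> float:
    """Cosine similarity between k-mer count vectors, in [0, 1]."""
    c1, c2 = _kmer_counts(s1, k), _kmer_counts(s2, k)
    dot = sum(c1[m] * c2[m] for m in c1.keys() & c2.keys())
    n1 = math.sqrt(sum(v * v for v in c1.values()))
    n2 = math.sqrt(sum(v * v for v in c2.values()))
    return dot / (n1 * n2)
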