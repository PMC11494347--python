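"""Homology search and interpretation of pair predictions.

``search`` scores one query against every database record with a
trained ensemble and returns ranked hits.  The interpretability layer
answers *why* a pair scored the way it did:

* ``build_background`` / ``score_context`` place each per-k feature of
  a pair on the empirical distribution of unrelated-pair features, as
  a percentile — a feature at the 99th percentile of unrelated pairs
  is strong evidence of relatedness at that k;
* ``extract_matches`` pulls every k-mer pair at or above a similarity
  threshold out of the k-mer similarity matrix and maps it back onto
  both sequences (defaults k = 8, T = 0.85), so conserved short motifs
  become visible as aligned spans — including one-to-many matches and
  order-swapped motifs that no collinear alignment can show.

Coordinates are 0-based half-open internally; the plain-text report
prints 1-based inclusive positions (stated in its header).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dive import DiveModel
from .features import N_FEATURES
from .kmer_scores import SequenceTooShortError, kmer_similarity_matrix
from .physchem import InvalidResidueError, ResidueSimilarityMatrix, \
    default_similarity_matrix
from .simulate import SequenceRecord

DEFAULT_EXPLAIN_K = 8
DEFAULT_EXPLAIN_T = 0.85


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    target_id: str
    probability: float
    features: tuple[float, ...]
    rank: int
    predicted_homolog: bool


@dataclass(frozen=True)
class MatchSpan:
    k: int
    query_start: int
    target_start: int
    query_kmer: str
    target_kmer: str
    w: float


@dataclass(frozen=True)
class BackgroundDistribution:
    """Per-k empirical feature samples from unrelated pairs."""

    samples: np.ndarray = field(repr=False)  # shape (n_pairs, 10)
    n_pairs: int
    seed: int

    def quantile(self, k: int, q: float) -> float:
        return float(np.quantile(self.samples[:, k - 1], q))


def search(model: DiveModel, query: SequenceRecord,
           database: list[SequenceRecord],
           threshold: float | None = None,
           ) -> tuple[list[SearchHit], list[tuple[str, str]]]:
    """Rank every database record by homology probability to the query.

    Returns (hits, rejects); rejects are (id, reason) for entries that
    could not be scored (e.g. invalid residues).  Hits are sorted by
    probability descending; probability ties resolve by raw feature sum
    descending, then target id; ranks run 1..n.
    """
    if not database:
        raise ValueError("database is empty")
    threshold = model.threshold if threshold is None else threshold
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")

    scored, rejects = [], []
    kept = []
    pairs = []
    for rec in database:
        try:
            model.matrix.encode(rec.sequence)
        except InvalidResidueError as exc:
            warnings.warn(f"skipping database entry {rec.id}: {exc}")
            rejects.append((rec.id, str(exc)))
            continue
        kept.append(rec)
        pairs.append((query.sequence, rec.sequence))
    if kept:
        X = model.featurize(pairs)
        probs = model.classifier.predict_proba(X)[:, 1]
        for rec, feats, prob in zip(kept, X, probs):
            scored.append((rec.id, float(prob), tuple(float(v) for v in feats)))
    # probability desc; probability ties (e.g. tree-leaf saturation on
    # near-identical pairs) resolved by raw feature sum desc, then id
    scored.sort(key=lambda t: (-t[1], -sum(t[2]), t[0]))
    hits = [SearchHit(query_id=query.id, target_id=tid, probability=prob,
                      features=feats, rank=i + 1,
                      predicted_homolog=prob >= threshold)
            for i, (tid, prob, feats) in enumerate(scored)]
    return hits, rejects


def build_background(records: list[SequenceRecord], n_pairs: int = 10_000,
                     seed: int = 0, model: DiveModel | None = None,
                     family_of: dict[str, str] | None = None,
                     ) -> BackgroundDistribution:
    """Empirical per-k feature distribution over unrelated pairs.

    Pairs are sampled without replacement from cross-family pairs when
    a family map is given, otherwise from all distinct record pairs.
    ``n_pairs`` beyond the available pairs is capped with a warning.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records for a background")
    if model is None:
        from .features import KmerFeaturizer
        featurize = KmerFeaturizer().fit().transform
    else:
        featurize = model.featurize

    index_pairs = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            if family_of is not None and \
                    family_of.get(records[i].id) == family_of.get(records[j].id):
                continue
            index_pairs.append((i, j))
    if not index_pairs:
        raise ValueError("no unrelated pairs available")
    if n_pairs > len(index_pairs):
        warnings.warn(f"only {len(index_pairs)} unrelated pairs available "
                      f"(requested {n_pairs}); using all")
        n_pairs = len(index_pairs)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(index_pairs), size=n_pairs, replace=False)
    pairs = [(records[index_pairs[c][0]].sequence,
              records[index_pairs[c][1]].sequence) for c in chosen]
    samples = featurize(pairs)
    return BackgroundDistribution(samples=samples, n_pairs=n_pairs, seed=seed)


def score_context(features, background: BackgroundDistribution) -> np.ndarray:
    """Per-k percentile of each feature within the unrelated background.

    percentile = fraction of background samples <= feature value.
    """
    feats = np.asarray(getattr(features, "features", features), dtype=float)
    if feats.shape != (N_FEATURES,):
        raise ValueError(f"expected {N_FEATURES} features, got {feats.shape}")
    return np.array([
        float(np.mean(background.samples[:, k] <= feats[k]))
        for k in range(N_FEATURES)])


def extract_matches(s1: str, s2: str, k: int = DEFAULT_EXPLAIN_K,
                    T: float = DEFAULT_EXPLAIN_T,
                    matrix: ResidueSimilarityMatrix | None = None,
                    ) -> list[MatchSpan]:
    """Every k-mer pair with similarity >= T, mapped onto both parents.

    Sorted by w descending, then (query_start, target_start).  Supports
    one-to-many matches; a too-short sequence yields an empty list with
    a warning.
    """
    if not 0.0 <= T <= 1.0:
        raise ValueError(f"T must be in [0, 1], got {T}")
    matrix = matrix or default_similarity_matrix()
    try:
        km = kmer_similarity_matrix(s1, s2, k, matrix)
    except SequenceTooShortError as exc:
        warnings.warn(f"extract_matches: {exc}; returning no matches")
        return []
    ii, jj = np.nonzero(km.w >= T)
    spans = [MatchSpan(k=k, query_start=int(i), target_start=int(j),
                       query_kmer=km.rows.kmers[i], target_kmer=km.cols.kmers[j],
                       w=float(km.w[i, j]))
             for i, j in zip(ii, jj)]
    spans.sort(key=lambda m: (-m.w, m.query_start, m.target_start))
    return spans


# ---------------------------------------------------------------------------
# reporting

_TSV_HEADER = "#k\tquery_start\ttarget_start\tquery_kmer\ttarget_kmer\tw"


def _check_span(s1: str, s2: str, span: MatchSpan) -> None:
    s1, s2 = s1.upper(), s2.upper()
    q = s1[span.query_start:span.query_start + span.k]
    t = s2[span.target_start:span.target_start + span.k]
    if q != span.query_kmer or t != span.target_kmer:
        raise ValueError(
            f"span at ({span.query_start}, {span.target_start}) does not "
            f"re-derive from the parent sequences: {q}/{t} vs "
            f"{span.query_kmer}/{span.target_kmer}")


def match_report_tsv(s1: str, s2: str, spans: list[MatchSpan]) -> str:
    """TSV rendering (0-based offsets); round-trips via parse_match_tsv."""
    lines = [_TSV_HEADER]
    for span in spans:
        _check_span(s1, s2, span)
        lines.append(f"{span.k}\t{span.query_start}\t{span.target_start}\t"
                     f"{span.query_kmer}\t{span.target_kmer}\t{span.w:.17g}")
    return "\n".join(lines) + "\n"


def parse_match_tsv(text: str) -> list[MatchSpan]:
    spans = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        k, qs, ts, qk, tk, w = line.split("\t")
        spans.append(MatchSpan(k=int(k), query_start=int(qs),
                               target_start=int(ts), query_kmer=qk,
                               target_kmer=tk, w=float(w)))
    return spans


def match_report_text(s1: str, s2: str, spans: list[MatchSpan],
                      width: int = 60) -> str:
    """Plain-text panel marking matched spans under each sequence.

    Positions in the header are 1-based inclusive; the mark lines use
    '*' under every residue covered by at least one matched k-mer.
    """
    s1, s2 = s1.upper(), s2.upper()
    cov1 = np.zeros(len(s1), dtype=bool)
    cov2 = np.zeros(len(s2), dtype=bool)
    for span in spans:
        _check_span(s1, s2, span)
        cov1[span.query_start:span.query_start + span.k] = True
        cov2[span.target_start:span.target_start + span.k] = True

    out = [f"# {len(spans)} matched k-mer pair(s); positions are 1-based "
           "inclusive"]
    for span in spans:
        out.append(f"#   w={span.w:.4f}  query {span.query_start + 1}-"
                   f"{span.query_start + span.k} {span.query_kmer}  ~  "
                   f"target {span.target_start + 1}-"
                   f"{span.target_start + span.k} {span.target_kmer}")
    for name, seq, cov in (("query", s1, cov1), ("target", s2, cov2)):
        out.append(f"> {name}")
        for off in range(0, len(seq), width):
            chunk = seq[off:off + width]
            marks = "".join("*" if c else " " for c in cov[off:off + width])
            out.append(f"{off + 1:>6d} {chunk}")
            out.append("       " + marks.rstrip())
    return "\n".join(out) + "\n"
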