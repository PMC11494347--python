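"""Evaluation harness: PR curves, auPRC, F1, PID-binned sensitivity,
and a Smith-Waterman local-alignment baseline.

All metrics treat a method as a scorer of sequence pairs; ground truth
is family membership.  Conventions are fixed and documented rather
than configurable surprises:

* the PR curve is evaluated at every distinct score (ties grouped);
* auPRC is the step-wise integral (average-precision style, no
  interpolation);
* F1 threshold ties resolve to the lower threshold;
* PID bins are half-open [lo, hi), last bin closed, defaulting to
  10-point bins over [0, 0.5] plus a >= 0.5 bin — the identity regime
  of a 50%-capped dataset;
* the local alignment baseline uses affine gaps where a gap of length
  L costs open + (L-1)*extend.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from sklearn.metrics import average_precision_score, precision_recall_curve

from .simulate import SequenceFamily, pairwise_identity

DEFAULT_PID_BINS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0)


@dataclass(frozen=True)
class PRCurve:
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    prevalence: float


@dataclass(frozen=True)
class AlignmentParams:
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    matrix_path: str | None = None

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")

    def load_matrix(self):
        if self.matrix_path is not None:
            return substitution_matrices.read(self.matrix_path)
        return substitution_matrices.load(self.matrix_name)


@dataclass
class BenchmarkResult:
    method: str
    auprc: float
    f1: float
    f1_threshold: float
    best_f1: float
    best_f1_threshold: float
    sensitivity_by_bin: dict[str, float | None]
    pairs_by_bin: dict[str, int]
    n_pairs: int
    n_positives: int
    failures: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# metric primitives

def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    return scores, labels


def pr_curve(scores, labels) -> PRCurve:
    """Precision-recall curve at every distinct score threshold."""
    scores, labels = _check_scores_labels(scores, labels)
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    # drop the synthetic (precision=1, recall=0) endpoint sklearn appends
    return PRCurve(thresholds=thresholds, precision=precision[:-1],
                   recall=recall[:-1], prevalence=float(labels.mean()))


def auprc(scores, labels=None) -> float:
    """Step-wise area under the PR curve (average precision).

    Accepts either (scores, labels) or a PRCurve built from them; the
    PRCurve form re-integrates the stored points.
    """
    if isinstance(scores, PRCurve):
        curve = scores
        if curve.recall.size == 0:
            raise ValueError("empty PR curve")
        rec = curve.recall[::-1]
        prec = curve.precision[::-1]
        return float(np.sum(np.diff(np.concatenate([[0.0], rec])) * prec))
    scores, labels = _check_scores_labels(scores, labels)
    return float(average_precision_score(labels, scores))


def f1_at_threshold(scores, labels, threshold: float) -> float:
    """F1 of the detector score >= threshold."""
    scores, labels = _check_scores_labels(scores, labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def best_f1_threshold(scores, labels) -> tuple[float, float]:
    """(threshold, F1) maximising F1 over all distinct scores.

    Ties on F1 resolve to the lower threshold.
    """
    scores, labels = _check_scores_labels(scores, labels)
    best_t, best_f1 = None, -1.0
    for t in sorted(np.unique(scores)):
        f1 = f1_at_threshold(scores, labels, t)
        if f1 > best_f1:
            best_t, best_f1 = float(t), f1
    return best_t, best_f1


def sensitivity_by_pid_bin(pids, labels, predictions,
                           bin_edges=DEFAULT_PID_BINS,
                           ) -> tuple[dict[str, float | None], dict[str, int]]:
    """Recall among positive pairs, stratified by pairwise identity.

    Bins are half-open [lo, hi), last bin closed.  Empty bins report
    None (undefined), never 0.  Returns (sensitivity, positive pair
    count) per bin label "lo-hi".
    """
    pids = np.asarray(pids, dtype=float)
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if np.any((pids < 0) | (pids > 1)):
        raise ValueError("PID values must be in [0, 1]")
    sens: dict[str, float | None] = {}
    counts: dict[str, int] = {}
    for lo, hi in itertools.pairwise(bin_edges):
        last = hi == bin_edges[-1]
        in_bin = (pids >= lo) & ((pids <= hi) if last else (pids < hi))
        pos = in_bin & (labels == 1)
        label = f"{lo:g}-{hi:g}"
        counts[label] = int(pos.sum())
        sens[label] = None if counts[label] == 0 else \
            float(predictions[pos].mean())
    return sens, counts


# ---------------------------------------------------------------------------
# Smith-Waterman baseline

def smith_waterman(s1: str, s2: str,
                   params: AlignmentParams = AlignmentParams()) -> float:
    """Affine-gap local alignment score (>= 0; 0 for an empty sequence)."""
    s1, s2 = s1.upper(), s2.upper()
    if not s1 or not s2:
        return 0.0
    matrix = params.load_matrix()
    for r in set(s1) | set(s2):
        if r not in matrix.alphabet:
            raise ValueError(f"residue {r!r} absent from matrix "
                             f"{params.matrix_name}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return float(aligner.score(s1, s2))


def sw_scorer(params: AlignmentParams = AlignmentParams()):
    """A (s1, s2) -> score callable for run_benchmark."""
    return lambda s1, s2: smith_waterman(s1, s2, params)


# ---------------------------------------------------------------------------
# harness

def run_benchmark(methods: dict, families: list[SequenceFamily],
                  test_family_ids=None, threshold_by_method=None,
                  bin_edges=DEFAULT_PID_BINS,
                  ) -> list[BenchmarkResult]:
    """All-vs-all evaluation of pair scorers on test families.

    ``methods`` maps a name to a callable (s1, s2) -> score (higher =
    more similar).  Labels come from family membership; PID from global
    alignment.  A method's threshold for F1/sensitivity defaults to its
    best-F1 threshold unless given in ``threshold_by_method`` (e.g. 0.5
    for the ensemble classifier).  Scorer failures on a pair exclude
    the pair from that method with a warning.
    """
    if test_family_ids is not None:
        fam_by_id = {f.family_id: f for f in families}
        families = [fam_by_id[i] for i in test_family_ids]
    records = [(rec, fam.family_id) for fam in families for rec in fam.members]
    if not records:
        raise ValueError("no test sequences")

    pairs = list(itertools.combinations(range(len(records)), 2))
    labels = np.array([int(records[i][1] == records[j][1]) for i, j in pairs])
    pids = np.array([pairwise_identity(records[i][0].sequence,
                                       records[j][0].sequence)
                     for i, j in pairs])

    results = []
    for name, scorer in methods.items():
        scores = np.full(len(pairs), np.nan)
        failures = []
        for idx, (i, j) in enumerate(pairs):
            try:
                scores[idx] = scorer(records[i][0].sequence,
                                     records[j][0].sequence)
            except Exception as exc:
                failures.append(f"{records[i][0].id}/{records[j][0].id}: {exc}")
        if failures:
            warnings.warn(f"{name}: {len(failures)} pair(s) failed and were "
                          "excluded")
        ok = ~np.isnan(scores)
        sc, lb, pid = scores[ok], labels[ok], pids[ok]
        best_t, best = best_f1_threshold(sc, lb)
        thr = (threshold_by_method or {}).get(name, best_t)
        preds = (sc >= thr).astype(int)
        sens, counts = sensitivity_by_pid_bin(pid, lb, preds, bin_edges)
        results.append(BenchmarkResult(
            method=name, auprc=auprc(sc, lb),
            f1=f1_at_threshold(sc, lb, thr), f1_threshold=float(thr),
            best_f1=best, best_f1_threshold=best_t,
            sensitivity_by_bin=sens, pairs_by_bin=counts,
            n_pairs=int(ok.sum()), n_positives=int(lb.sum()),
            failures=failures))
    return results


def write_benchmark(results: list[BenchmarkResult], out_dir) -> None:
    """Emit metrics as TSV (one row per method) and JSON (full detail)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["#method\tauprc\tf1\tf1_threshold\tbest_f1\tbest_f1_threshold"
             "\tn_pairs\tn_positives"]
    for r in results:
        lines.append(f"{r.method}\t{r.auprc:.6f}\t{r.f1:.6f}\t"
                     f"{r.f1_threshold:.6f}\t{r.best_f1:.6f}\t"
                     f"{r.best_f1_threshold:.6f}\t{r.n_pairs}\t{r.n_positives}")
    (out_dir / "metrics.tsv").write_text("\n".join(lines) + "\n")
    payload = [{**r.__dict__} for r in results]
    (out_dir / "metrics.json").write_text(json.dumps(payload, indent=2,
                                                     default=str) + "\n")


# ---------------------------------------------------------------------------
# external search-tool output parsing (never executes the tools)

@dataclass(frozen=True)
class ExternalHit:
    query: str
    target: str
    e_value: float


def parse_external_hits(path, dialect: str,
                        ) -> tuple[list[ExternalHit], list[str]]:
    """Parse BLAST outfmt-6 or HMMER tblout tabular output.

    Returns (records, rejects); malformed lines land in rejects and
    parsing continues.  A detection predicate ``e_value <= cutoff``
    turns records into binary predictions for the metric suite.
    """
    if dialect not in ("blast_tab", "hmmer_tab"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records, rejects = [], []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t") if dialect == "blast_tab" else line.split()
        try:
            if dialect == "blast_tab":
                if len(fields) < 12:
                    raise ValueError("fewer than 12 columns")
                query, target, e_value = fields[0], fields[1], float(fields[10])
            else:  # hmmer tblout: target, t-acc, query, q-acc, full-seq E
                if len(fields) < 5:
                    raise ValueError("fewer than 5 columns")
                query, target, e_value = fields[2], fields[0], float(fields[4])
            records.append(ExternalHit(query=query, target=target,
                                       e_value=e_value))
        except ValueError as exc:
            rejects.append(f"line {line_no}: {exc}")
    return records, rejects
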