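"""Evaluation metrics against hand-enumerated oracles, the local
alignment baseline against an independent DP, external-format parsing."""

import numpy as np
import pytest

from conftest import random_sequence
from sharkdive import (AlignmentParams, auprc, best_f1_threshold,
                       f1_at_threshold, parse_external_hits, pr_curve,
                       run_benchmark, sensitivity_by_pid_bin, smith_waterman,
                       sw_scorer)
from sharkdive.benchmark import write_benchmark
from Bio.Align import substitution_matrices


# ---------------------------------------------------------------------------
# independent affine-gap local alignment oracle (Gotoh recursion)

def gotoh_local(s1, s2, matrix, gap_open, gap_extend):
    """Quadratic DP; gap of length L costs open + (L-1)*extend."""
    n, m = len(s1), len(s2)
    if n == 0 or m == 0:
        return 0.0
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, :] = M[:, 0] = 0.0
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = matrix[s1[i - 1], s2[j - 1]]
            M[i, j] = sub + max(0.0, M[i - 1, j - 1], Ix[i - 1, j - 1],
                                Iy[i - 1, j - 1])
            Ix[i, j] = max(M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend)
            best = max(best, M[i, j])
    return best


class TestPRCurve:
    def test_perfect_separation(self):
        curve = pr_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert curve.prevalence == 0.5
        # some threshold attains precision 1 at recall 1
        assert any(p == 1.0 and r == 1.0
                   for p, r in zip(curve.precision, curve.recall))
        assert auprc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_score_gives_prevalence(self):
        scores = [0.5] * 8
        labels = [1, 0, 0, 1, 0, 0, 0, 0]
        curve = pr_curve(scores, labels)
        assert len(curve.thresholds) == 1
        assert curve.precision[0] == pytest.approx(0.25)
        assert auprc(scores, labels) == pytest.approx(0.25)

    def test_hand_enumerated_four_pairs(self):
        # scores descending: 0.9(+), 0.7(-), 0.6(+), 0.2(-)
        # ranks:  P=1/1,R=1/2 ; P=1/2,R=1/2 ; P=2/3,R=1 ; P=2/4,R=1
        # AP = 0.5*1 + 0.5*(2/3) = 5/6
        scores = [0.9, 0.7, 0.6, 0.2]
        labels = [1, 0, 1, 0]
        assert auprc(scores, labels) == pytest.approx(5 / 6)
        curve = pr_curve(scores, labels)
        assert auprc(curve) == pytest.approx(5 / 6)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.random(200)
        labels = (rng.random(200) < 0.4).astype(int)
        assert auprc(scores, labels) == \
            pytest.approx(auprc(np.exp(3 * scores) - 1, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            pr_curve([0.1, 0.9], [1, 1])

    def test_random_scorer_near_prevalence(self):
        rng = np.random.default_rng(424)
        n = 2000
        labels = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        scores = rng.random(n)
        assert auprc(scores, labels) == pytest.approx(0.5, abs=0.05)


class TestF1:
    def test_perfect_classifier(self):
        assert f1_at_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 0.5) == 1.0

    def test_all_positive_closed_form(self):
        labels = [1, 0, 0, 0, 1, 0, 0, 0]  # prevalence 0.25
        prev = 0.25
        assert f1_at_threshold([1.0] * 8, labels, 0.5) == \
            pytest.approx(2 * prev / (1 + prev))

    def test_best_threshold_enumeration(self):
        scores = [0.9, 0.7, 0.6, 0.2]
        labels = [1, 0, 1, 0]
        # exhaustive: t=0.2 F1=2/3; t=0.6 F1=0.8; t=0.7 F1=0.4; t=0.9 F1=2/3
        t, f1 = best_f1_threshold(scores, labels)
        assert (t, f1) == (pytest.approx(0.6), pytest.approx(0.8))

    def test_tie_resolves_to_lower_threshold(self):
        scores = [0.2, 0.8]
        labels = [0, 1]
        t, f1 = best_f1_threshold(scores, labels)  # both attain F1=1? no:
        # t=0.2 predicts both positive (F1=2/3); t=0.8 predicts one (F1=1)
        assert f1 == 1.0 and t == pytest.approx(0.8)
        # genuine tie: duplicate scores
        t2, _ = best_f1_threshold([0.5, 0.5, 0.9], [0, 1, 1])
        assert t2 == pytest.approx(0.5)


class TestSensitivityByPID:
    def test_all_detected(self):
        pids = [0.05, 0.15, 0.45, 0.7]
        labels = [1, 1, 1, 1]
        # pr_curve-free path needs a negative? sensitivity only uses positives
        sens, counts = sensitivity_by_pid_bin(pids, labels, [1, 1, 1, 1])
        for label, value in sens.items():
            if counts[label] > 0:
                assert value == 1.0

    def test_threshold_detector_and_empty_bins(self):
        pids = [0.05, 0.15, 0.55]
        labels = [1, 1, 1]
        preds = [0, 0, 1]  # fires only at PID >= 0.5
        sens, counts = sensitivity_by_pid_bin(pids, labels, preds)
        assert sens["0-0.1"] == 0.0 and sens["0.1-0.2"] == 0.0
        assert sens["0.5-1"] == 1.0
        assert sens["0.2-0.3"] is None and counts["0.2-0.3"] == 0
        assert sum(counts.values()) == 3

    def test_pid_domain_checked(self):
        with pytest.raises(ValueError):
            sensitivity_by_pid_bin([1.2], [1], [1])


class TestSmithWaterman:
    def test_identity_triplet(self):
        # 3 x BLOSUM62 A/A diagonal entries
        blosum = substitution_matrices.load("BLOSUM62")
        assert smith_waterman("AAA", "AAA") == 3 * blosum["A", "A"]

    def test_empty_sequence_zero(self):
        assert smith_waterman("A", "") == 0.0
        assert smith_waterman("", "") == 0.0

    def test_residue_absent_from_matrix(self):
        with pytest.raises(ValueError, match="absent"):
            smith_waterman("AJA", "AAA")

    @pytest.mark.parametrize("gap", [(11.0, 1.0), (5.0, 2.0)])
    def test_matches_independent_dp(self, rng, gap):
        blosum = substitution_matrices.load("BLOSUM62")
        params = AlignmentParams(gap_open=gap[0], gap_extend=gap[1])
        for _ in range(40):
            s1 = random_sequence(rng, int(rng.integers(1, 21)))
            s2 = random_sequence(rng, int(rng.integers(1, 21)))
            expected = gotoh_local(s1, s2, blosum, *gap)
            assert smith_waterman(s1, s2, params) == pytest.approx(expected)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            AlignmentParams(gap_open=1.0, gap_extend=2.0)
        with pytest.raises(ValueError):
            AlignmentParams(gap_open=-1.0)


class TestRunBenchmark:
    def test_rows_and_invariants(self, small_dataset, small_split, tmp_path):
        from sharkdive import shark_score_best
        methods = {
            "shark_best_k5": lambda a, b: shark_score_best(a, b, 5),
            "sw": sw_scorer(),
        }
        results = run_benchmark(methods, small_dataset,
                                test_family_ids=small_split.test)
        assert len(results) == 2
        n_seqs = sum(len(f.members) for f in small_dataset
                     if f.family_id in small_split.test)
        for r in results:
            assert r.n_pairs == n_seqs * (n_seqs - 1) // 2
            assert 0.0 <= r.auprc <= 1.0 and 0.0 <= r.f1 <= 1.0
            assert sum(r.pairs_by_bin.values()) == r.n_positives
        write_benchmark(results, tmp_path)
        assert (tmp_path / "metrics.tsv").exists()
        assert (tmp_path / "metrics.json").exists()

    def test_identical_method_identical_metrics(self, small_dataset,
                                                small_split):
        from sharkdive import shark_score_best
        scorer = lambda a, b: shark_score_best(a, b, 5)
        results = run_benchmark({"m1": scorer, "m2": scorer}, small_dataset,
                                test_family_ids=small_split.test)
        assert results[0].auprc == results[1].auprc
        assert results[0].f1 == results[1].f1

    def test_scorer_failures_excluded_with_warning(self, small_dataset,
                                                   small_split):
        calls = {"n": 0}

        def flaky(a, b):
            calls["n"] += 1
            if calls["n"] == 1:
                raise RuntimeError("boom")
            return len(a)

        with pytest.warns(UserWarning, match="excluded"):
            results = run_benchmark({"flaky": flaky}, small_dataset,
                                    test_family_ids=small_split.test)
        assert len(results[0].failures) == 1


class TestExternalParsing:
    def test_blast_tab(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\tt1\t90.0\t100\t5\t1\t1\t100\t1\t100\t1e-30\t200\n"
            "q1\tt2\t80.0\t100\t5\t1\t1\t100\t1\t100\tnot_a_number\t150\n"
            "short\tline\n")
        records, rejects = parse_external_hits(path, "blast_tab")
        assert len(records) == 1
        assert records[0].query == "q1" and records[0].e_value == 1e-30
        assert len(rejects) == 2

    def test_hmmer_tab(self, tmp_path):
        path = tmp_path / "hits.tbl"
        path.write_text(
            "#                                  --- full sequence ----\n"
            "t1  -  q1  -  1.3e-20  100.0  0.1  ...\n")
        records, rejects = parse_external_hits(path, "hmmer_tab")
        assert len(records) == 1
        assert records[0].query == "q1" and records[0].target == "t1"
        assert records[0].e_value == pytest.approx(1.3e-20)
        assert not rejects

    def test_empty_file_and_unknown_dialect(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        records, rejects = parse_external_hits(path, "blast_tab")
        assert records == [] and rejects == []
        with pytest.raises(ValueError, match="dialect"):
            parse_external_hits(path, "csv")
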