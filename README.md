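# sharkdive

Alignment-free homology detection for unalignable protein sequences —
intrinsically disordered regions (IDRs), low-complexity segments and
other rapidly evolving regions where alignment breaks down.

Classical homology search (Smith–Waterman, BLAST, HMMER) assumes a
collinear correspondence between residues. IDRs evolve too fast for
that: only short motifs, repeats and overall amino-acid composition
tend to be conserved. This package compares sequences through their
k-mers in physicochemical space instead, and aggregates the per-k
evidence with a small ensemble classifier.

## The scores

Each sequence is decomposed into overlapping k-mers. A k-mer pair
(x, y) gets the similarity

```
w(x, y) = (1/k) Σᵢ sim(xᵢ, yᵢ),     sim(a, b) = 1 − D(a, b)/215
```

where D is the Grantham distance — the classical amino-acid
dissimilarity built from side-chain composition, polarity and
molecular volume (maximum 215, Cys/Trp). Two aggregations of the
n₁ × n₂ matrix of w values give the sequence-level scores:

* **best** — average of each k-mer's best match in the other sequence,
  symmetrised over the two directions; 1 for identical sequences;
* **T** — the sum of all w ≥ T, divided by n₁·n₂, which rewards
  *every* sufficiently similar k-mer pair, not just the best one.

Classical alignment-free baselines over k-mer count vectors/sets are
included: Euclidean distance, cosine Similarity Ratio, and the
Normalized Google Distance (NGD, reported to users as the similarity
1 − NGD).

## The classifier

`DiveClassifier` is a scikit-learn-style estimator: a 10-fold ensemble
of gradient-boosted decision trees over a 10-vector of per-k scores
(k = 1…10; by default the T-variant at k = 1, 1 − NGD at k = 2…4, best
at k = 5…10). Sequence *families* — not pairs — are partitioned into
folds, so no family leaks across any submodel's train/held-out
boundary. The ensemble probability is the mean over submodels;
probability ≥ 0.5 predicts homology.

Because no public corpus of unalignable homolog families can ship with
the package, `sharkdive.simulate` generates ground-truth families with
the same statistical structure: disordered-like composition bias,
implanted short motifs, heavy substitution/InDel divergence, and a 50%
cap on pairwise identity enforced by global alignment.

## Worked example

```
$ shark --seed 1 simulate --n-families 12 --members 4 --out data
wrote 48 sequences in 12 families to data
$ shark --seed 1 dive-train --families data/families.fasta \
        --family-map data/family_map.tsv --out model.shark
model written to model.shark
$ shark search --model model.shark --query query.fasta --db data/families.fasta
#rank  query_id  target_id  probability  predicted_homolog
1      F000|m00  F000|m00   0.987538     1
2      F000|m00  F000|m01   0.987538     1
3      F000|m00  F000|m02   0.987538     1
4      F000|m00  F000|m03   0.987538     1
5      F000|m00  F006|m03   0.016756     0
```

The query is the first member of family `F000`; its three true family
members saturate the ensemble probability (0.988) and are flagged as
homologs, while the best cross-family sequence scores 0.017 — the
classifier separates the two groups by nearly the full probability
range. The `explain` command then shows *why* a pair was called
homologous, by mapping similar k-mers back onto both sequences
(defaults k = 8, T = 0.85):

```
129 spans at k=8, T=0.85; top:
  w=0.9593 query 246-253 QHFLTYES ~ target 237-244 QRFLTYNS
  w=0.9529 query  30-37  YHYHVKMR ~ target  31-38  YHYEVRLR
```

These are diverged copies of the implanted motifs: not identical, but
physicochemically near-equivalent (H→R, E→N substitutions), and found
at shifted positions that a collinear alignment would penalise.
`explain` also reports each per-k feature as a percentile of its
distribution over unrelated pairs.

The same pipeline is available as a library; see `docs/methods.md` for
the model details and `tests/` for executable examples.

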