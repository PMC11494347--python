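# Methods

## Residue physicochemistry

All scores reduce to a 20×20 residue similarity matrix derived from
the Grantham distance

D(a, b) = ρ·[α(c_a−c_b)² + β(p_a−p_b)² + γ(v_a−v_b)²]^½

with α = 1.833, β = 0.1018, γ = 0.000399 over side-chain atomic
composition (c), polarity (p) and molecular volume (v). The scale
factor ρ is not hardcoded: it is recomputed at import from the
defining constraint that the mean of the 190 pairwise distances is
100 (giving ρ ≈ 50.79). Distances are rounded to integers — the
convention of the published table, which the formula then reproduces
at its anchor values (Leu/Ile = 5, Cys/Trp = 215 = maximum).

Distance becomes similarity by the linear transform
sim(a, b) = 1 − D/D_max with D_max = 215. The transform is bounded in
[0, 1], order-preserving and strictly decreasing in distance; D_max is
a configuration point (a larger constant compresses the similarity
range upward, e.g. 430 puts the floor at 0.5). The property table
ships as a TSV and can be replaced wholesale to use an alternative
property scheme; ρ is then recalibrated from the same mean-100 rule.

Non-canonical residues (X, B, Z, U, O, `*`) are rejected by default;
an explicit sanitize policy drops them. Silent coercion to a "neutral"
residue is deliberately not offered — it would corrupt the composition
features that carry most of the k = 1 signal.

## k-mer scores

The k-mer similarity w(x, y) is the arithmetic mean of the per-position
residue similarities — ungapped and collinear *within* the k-mer.
The mean (rather than a product) keeps w on [0, 1] for every k and
avoids the collapse toward 0 that multiplicative aggregation suffers
at k = 10. The n₁×n₂ matrix of w values is computed from a single
residue-level similarity grid by diagonal window sums, so all ten
per-k features of a pair cost one O(L₁·L₂) grid plus 54 slice
additions.

* **best**: mean over the k-mers of sequence 1 of their row maxima,
  averaged with the transposed direction. The directional score is 1
  whenever every k-mer of one sequence occurs in the other; the
  symmetrised mean keeps the score symmetric, as homology is.
* **T**: Σ{w ≥ T} w / (n₁·n₂). Dividing by n₁·n₂ removes the length
  dependence and bounds the score in [0, 1]; it also means the score
  of a self pair is the sequence's mean self-similarity, not 1 — the
  score rewards *density* of similar k-mer pairs, not identity. The
  normalisation is isolated in one helper so an alternative
  convention is a one-line change.
* **NGD** is computed over *distinct* k-mer sets with corpus size
  N = 20^k: the full k-mer space is the only deterministic,
  database-independent choice for the corpus-size constant of the
  original web-scale formulation. Identical sets give 0, disjoint sets
  are defined as 1, and the value is clamped to [0, 1]. Euclidean
  distance and the cosine Similarity Ratio use k-mer count vectors
  (sparse; the 20^k space is never materialised).

Sequences shorter than k raise in standalone calls; inside a feature
vector the per-k entry is 0.0 with a warning, so database-scale
scoring never aborts on a short entry. Inputs are upper-cased before
validation.

## Feature map and classifier

The per-pair feature vector holds one score per k = 1…10 — the range
of typical short-motif lengths in disordered regions. The default
assignment is the T-variant at T = 0 for k = 1 (pure composition
aggregation), 1 − NGD for k = 2…4, and best for k = 5…10; every entry
is configurable and the map is stored inside the model archive, so a
trained model is self-describing. NGD features are always stored as
1 − NGD so that, like every other feature, higher means more similar.

`DiveClassifier` follows the scikit-learn estimator contract
(`fit(X, y, groups)`, `predict_proba`, `get_params`/`set_params`,
fitted attributes with trailing underscores) and so composes with
sklearn pipelines and model selection. Families are shuffled with the
seed and round-robin partitioned into 10 folds; submodel i trains on
the pairs whose *both* families lie outside fold i. This is the
grouped analogue of bagging: it guarantees that no family contributes
pairs to both the training side and the held-out fold of any submodel,
which the tests assert on the stored fold assignment. The ensemble
probability is the mean of the submodel probabilities (probability
averaging rather than voting — a documented choice); a pair is called
homologous at probability ≥ threshold (default 0.5; the tie counts as
positive).

Submodels are XGBoost gradient-boosted trees with 200 estimators,
depth 3, learning rate 0.1, single-threaded histogram construction and
a seed derived from the global one — a modest model matched to the
10-dimensional feature space, fully exposed in the configuration.
Feature importances are per-submodel gain values normalised to sum to
1, summarised as mean ± SD per k. Training pairs are all within-family
pairs plus cross-family pairs sampled without replacement at a 1:1
ratio by default; precision–recall evaluation handles the true
all-vs-all prevalence, so training balance is a variance choice, not a
calibration claim.

Model archives are joblib payloads carrying a format version, the
feature map, threshold, similarity matrix and training metadata;
loading a truncated or versionless file raises a dedicated error, and
a round-trip preserves predictions bit-exactly.

## Synthetic families

The generator emulates the structure of curated unalignable-ortholog
benchmarks rather than reproducing any particular corpus:

* a disordered-like base composition (enriched S, G, P, Q, E, K;
  depleted W, C, F); each family's profile is a Dirichlet perturbation
  with concentration 50/spread (spread 1 by default; 0 disables
  compositional separation, with a warning);
* a private motif set per family (3 motifs of 6–10 residues drawn from
  the family profile), implanted at non-overlapping random positions
  in an ancestor sampled from the profile;
* members are independently mutated copies: substitutions at rate 0.40
  per residue, Grantham-biased (replacement probability ∝ sim^8, so
  physicochemistry is conserved while identity decays); insertions and
  deletions at 0.03 per residue with geometric lengths (mean 2.5,
  truncated at 10), kept outside motif spans so every member retains
  each motif as a contiguous, mutated block;
* the 0.5 pairwise-identity cap is enforced by rejection: a member
  violating the cap against any accepted member is re-mutated (up to
  100 retries), mirroring an identity-filtering step without a
  clustering stage. With all mutation rates at 0 the cap is
  unsatisfiable and the generator raises.

Pairwise identity is identities over alignment columns (gaps included)
under global alignment with BLOSUM62, gap open 10 / extend 1 — PID is
convention-dependent, so the convention is fixed and recorded.
Defaults of 50 families, 5–20 members and lengths 50–300 define the
study conditions used by the acceptance run; family-size and length
distributions of real corpora are not modelled.

What passing tests on this generator do and do not show: the families
are genuinely hard for position-wise comparison (identity ≤ 0.5,
InDel-shifted motifs) and carry exactly the two signal types the
classifier is built for (composition + short motifs). They are *not*
real evolution: divergence is star-shaped from a single ancestor
rather than tree-structured, motif drift is limited to flanking
InDels, and inter-family similarity is only as confusable as the
profile spread makes it. Near-ceiling held-out performance here
validates the machinery, not field performance on real IDRs. Notably,
Smith–Waterman with BLOSUM62 also performs well on these families —
star-shaped divergence at ~0.3 identity is still within alignment's
reach; the paper-scale gap between alignment and k-mer methods emerges
only at deeper, tree-structured divergence than the generator
produces.

## Evaluation conventions

* PR curves are evaluated at every distinct score, ties grouped;
  auPRC is the step-wise (average-precision) integral — no
  interpolation, so a constant scorer's auPRC equals prevalence
  exactly.
* Best-F1 threshold scans the distinct scores; F1 ties resolve to the
  lower threshold.
* Sensitivity is stratified by PID in half-open bins (last bin
  closed), defaulting to 10-point bins over [0, 0.5] plus a ≥ 0.5
  bin — the regime of an identity-capped dataset. Empty bins report
  undefined, never 0.
* The local-alignment baseline uses affine gaps where a gap of length
  L costs open + (L−1)·extend (the PairwiseAligner convention); the
  test suite checks it against an independently written Gotoh DP.
  Substitution matrices load by name or from NCBI/EMBOSS text files.
* External search-tool outputs (BLAST outfmt-6, HMMER tblout) are
  parsed, never executed; an E-value cutoff turns them into binary
  predictions for the same metric suite.

## Reproducibility

One global seed fans out to per-module seeds via a fixed derivation
(SeedSequence over the seed and a CRC of the module name, reduced
below 2³¹). Every generator output is a pure function of its
parameters and seed; CLI commands re-run with the same seed and inputs
produce byte-identical primary outputs, and output directories carry a
provenance JSON (version, effective config, seed, input digests).

## Known limitations

* The distance→similarity transform and the T-score normalisation are
  documented defaults, each isolated behind a single constant.
* k = 1 self-pair features are composition-dependent rather than 1
  (see above); consumers who need a self-score ceiling should use the
  best variant.
* The generator's identity cap is enforced pairwise within a family;
  cross-family identity is controlled only statistically through
  distinct profiles and motifs.
* No gapped k-mers, spaced seeds, reduced alphabets or iterative
  profile search; nucleotide alphabets are out of scope.
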