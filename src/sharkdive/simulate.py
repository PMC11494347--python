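"""Synthetic homolog families with the structure of unalignable orthologs.

Real benchmark families of diverged, mostly disordered segments share
three properties that make them hard for alignment yet learnable for
k-mer scores: a family-specific amino-acid composition bias, a small
set of short conserved motifs, and heavy substitution / InDel
divergence with pairwise identity capped at 50%.  The generator
emulates exactly that:

1. each family draws a composition profile (a Dirichlet perturbation
   of a disordered-like base profile) and a private motif set;
2. an ancestor sequence is sampled from the profile and the motifs are
   implanted at random non-overlapping positions;
3. every member is an independently mutated copy of the ancestor —
   substitutions optionally Grantham-biased toward physicochemically
   similar residues, InDels with geometric lengths outside motif
   spans — re-mutated until all pairwise identities are at or below
   the cap (default 0.5).

Pairwise identity is computed by global alignment (BLOSUM62, gap open
10 / extend 1) as identities over alignment columns, gaps included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .physchem import ALPHABET, default_similarity_matrix

# Disordered-like residue frequencies: enriched S, G, P, Q, E, K;
# depleted W, C, F (order follows ALPHABET = ACDEFGHIKLMNPQRSTVWY).
BASE_COMPOSITION = {
    "A": 0.063, "C": 0.005, "D": 0.055, "E": 0.090, "F": 0.015,
    "G": 0.085, "H": 0.020, "I": 0.030, "K": 0.080, "L": 0.050,
    "M": 0.015, "N": 0.040, "P": 0.085, "Q": 0.075, "R": 0.050,
    "S": 0.110, "T": 0.055, "V": 0.040, "W": 0.005, "Y": 0.032,
}


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str


@dataclass(frozen=True)
class MutationParams:
    """Divergence model for family members.

    Rates are per-residue probabilities; InDel lengths are geometric
    with mean ``mean_indel_length``, truncated at ``max_indel_length``.
    With ``grantham_bias`` substitutions prefer physicochemically
    similar residues (selection pressure on property, not identity).
    """

    substitution_rate: float = 0.40
    insertion_rate: float = 0.03
    deletion_rate: float = 0.03
    max_indel_length: int = 10
    mean_indel_length: float = 2.5
    grantham_bias: bool = True
    bias_sharpness: float = 8.0
    identity_cap: float = 0.5
    max_retries: int = 100
    seed: int = 0

    def __post_init__(self):
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        if self.max_indel_length < 1:
            raise ValueError("max_indel_length must be >= 1")


@dataclass(frozen=True)
class SequenceFamily:
    family_id: str
    members: tuple[SequenceRecord, ...]
    provenance: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple[str, ...]
    validation: tuple[str, ...]
    test: tuple[str, ...]
    seed: int


class GenerationError(RuntimeError):
    """The generator could not satisfy its constraints within the retry budget."""


# ---------------------------------------------------------------------------
# pairwise identity

_PID_ALIGNER: Align.PairwiseAligner | None = None


def _pid_aligner() -> Align.PairwiseAligner:
    global _PID_ALIGNER
    if _PID_ALIGNER is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -1.0
        _PID_ALIGNER = aligner
    return _PID_ALIGNER


def pairwise_identity(s1: str, s2: str) -> float:
    """Global-alignment percent identity in [0, 1].

    Identical aligned positions divided by alignment length, counting
    gap columns in the length; symmetric by construction.
    """
    if not s1 or not s2:
        raise ValueError("pairwise_identity requires non-empty sequences")
    alignment = _pid_aligner().align(s1.upper(), s2.upper())[0]
    identities = alignment.counts().identities
    return identities / alignment.length


# ---------------------------------------------------------------------------
# mutation machinery

def _substitution_table(sharpness: float) -> np.ndarray:
    """Row-stochastic 20x20 replacement distribution, self excluded.

    P(b | a) is proportional to sim(a, b)**sharpness, so high sharpness
    concentrates mass on the most Grantham-similar residues.
    """
    sim = default_similarity_matrix().matrix.copy()
    np.fill_diagonal(sim, 0.0)
    weights = sim ** sharpness
    return weights / weights.sum(axis=1, keepdims=True)


def _draw_sequence(rng: np.random.Generator, length: int,
                   profile: np.ndarray) -> str:
    idx = rng.choice(len(ALPHABET), size=length, p=profile)
    return "".join(ALPHABET[i] for i in idx)


def _geometric_length(rng: np.random.Generator, params: MutationParams) -> int:
    p = 1.0 / params.mean_indel_length
    return min(int(rng.geometric(p)), params.max_indel_length)


def _mutate(ancestor: str, motif_spans: list[tuple[int, int]],
            profile: np.ndarray, params: MutationParams,
            rng: np.random.Generator, sub_table: np.ndarray | None) -> str:
    """One diverged copy of the ancestor.

    Substitutions hit every position at the same rate (motifs included —
    Grantham bias, when on, is what preserves their physicochemistry);
    insertions and deletions are kept outside motif spans so every
    member retains each implanted motif as a contiguous block.
    """
    in_motif = np.zeros(len(ancestor), dtype=bool)
    for start, end in motif_spans:
        in_motif[start:end] = True

    residues: list[str] = []
    i = 0
    while i < len(ancestor):
        # deletion of a block starting here (never inside a motif)
        if not in_motif[i] and rng.random() < params.deletion_rate:
            length = _geometric_length(rng, params)
            j = i
            while j < len(ancestor) and j - i < length and not in_motif[j]:
                j += 1
            i = j
            continue
        a = ancestor[i]
        if rng.random() < params.substitution_rate:
            ai = ALPHABET.index(a)
            if sub_table is not None:
                b = ALPHABET[rng.choice(len(ALPHABET), p=sub_table[ai])]
            else:
                b = ALPHABET[rng.choice(len(ALPHABET))]
                while b == a:
                    b = ALPHABET[rng.choice(len(ALPHABET))]
            residues.append(b)
        else:
            residues.append(a)
        # insertion after this position (never splitting a motif)
        boundary_ok = not in_motif[i] or i + 1 >= len(ancestor) or not in_motif[i + 1]
        if boundary_ok and rng.random() < params.insertion_rate:
            length = _geometric_length(rng, params)
            residues.append(_draw_sequence(rng, length, profile))
        i += 1
    return "".join(residues)


def _profile_vector(profile: dict[str, float] | None) -> np.ndarray:
    profile = profile or BASE_COMPOSITION
    vec = np.array([profile[r] for r in ALPHABET], dtype=float)
    return vec / vec.sum()


def generate_family(n_members: int,
                    length_range: tuple[int, int] = (50, 300),
                    motif_set: tuple[str, ...] = (),
                    composition_profile: dict[str, float] | None = None,
                    params: MutationParams = MutationParams(),
                    family_id: str = "F000",
                    rng: np.random.Generator | None = None) -> SequenceFamily:
    """One homolog family: mutated copies of a motif-bearing ancestor.

    Every member keeps all implanted motifs (as mutated blocks) and all
    pairwise identities are at or below ``params.identity_cap``; members
    violating the cap are re-mutated up to ``params.max_retries`` times.
    """
    if n_members < 2:
        raise ValueError("a family needs at least 2 members")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    lo, hi = length_range
    for motif in motif_set:
        if len(motif) >= lo:
            raise ValueError(f"motif {motif!r} not shorter than min length {lo}")

    profile = _profile_vector(composition_profile)
    sub_table = (_substitution_table(params.bias_sharpness)
                 if params.grantham_bias else None)

    length = int(rng.integers(lo, hi + 1))
    ancestor = _draw_sequence(rng, length, profile)
    motif_spans: list[tuple[int, int]] = []
    for motif in motif_set:
        for _ in range(params.max_retries):
            start = int(rng.integers(0, length - len(motif) + 1))
            span = (start, start + len(motif))
            if all(span[1] <= s or span[0] >= e for s, e in motif_spans):
                break
        else:
            raise GenerationError(
                f"could not place motif {motif!r} without overlap in "
                f"length-{length} ancestor")
        motif_spans.append(span)
        ancestor = ancestor[:span[0]] + motif + ancestor[span[1]:]

    members: list[SequenceRecord] = []
    for m in range(n_members):
        for attempt in range(params.max_retries):
            candidate = _mutate(ancestor, motif_spans, profile, params, rng,
                                sub_table)
            if not candidate:
                continue
            if all(pairwise_identity(candidate, rec.sequence)
                   <= params.identity_cap for rec in members):
                break
        else:
            raise GenerationError(
                f"family {family_id}: member {m} violated the identity cap "
                f"{params.identity_cap} after {params.max_retries} retries "
                f"(substitution_rate={params.substitution_rate}, "
                f"insertion_rate={params.insertion_rate}, "
                f"deletion_rate={params.deletion_rate})")
        members.append(SequenceRecord(id=f"{family_id}|m{m:02d}",
                                      sequence=candidate))

    provenance = {
        "family_id": family_id,
        "motifs": list(motif_set),
        "motif_spans": [list(s) for s in motif_spans],
        "ancestor_length": length,
        "composition_profile": {r: float(p) for r, p in zip(ALPHABET, profile)},
        "mutation_params": {
            "substitution_rate": params.substitution_rate,
            "insertion_rate": params.insertion_rate,
            "deletion_rate": params.deletion_rate,
            "max_indel_length": params.max_indel_length,
            "grantham_bias": params.grantham_bias,
            "identity_cap": params.identity_cap,
            "seed": params.seed,
        },
    }
    return SequenceFamily(family_id=family_id, members=tuple(members),
                          provenance=provenance)


def _draw_motifs(rng: np.random.Generator, profile: np.ndarray,
                 n_motifs: int, length_range: tuple[int, int]) -> tuple[str, ...]:
    lo, hi = length_range
    return tuple(_draw_sequence(rng, int(rng.integers(lo, hi + 1)), profile)
                 for _ in range(n_motifs))


def generate_dataset(n_families: int = 50,
                     members_range: tuple[int, int] = (5, 20),
                     length_range: tuple[int, int] = (50, 300),
                     n_motifs: int = 3,
                     motif_length_range: tuple[int, int] = (6, 10),
                     unrelated_profile_spread: float = 1.0,
                     params: MutationParams = MutationParams(),
                     seed: int = 0) -> list[SequenceFamily]:
    """A list of families with distinct motif sets and composition profiles.

    ``unrelated_profile_spread`` controls how far family composition
    profiles scatter around the disordered-like base profile (Dirichlet
    concentration 50 / spread); 0 disables compositional separation
    with a warning.
    """
    if n_families < 2:
        raise ValueError("need at least 2 families")
    if unrelated_profile_spread < 0:
        raise ValueError("unrelated_profile_spread must be >= 0")
    if unrelated_profile_spread == 0:
        warnings.warn("profile spread 0: inter-family compositional "
                      "separation is not guaranteed")

    base = _profile_vector(None)
    families: list[SequenceFamily] = []
    seen_motifs: set[tuple[str, ...]] = set()
    for f in range(n_families):
        fam_id = f"F{f:03d}"
        rng = np.random.default_rng(np.random.SeedSequence([seed, f]))
        if unrelated_profile_spread > 0:
            conc = 50.0 / unrelated_profile_spread
            profile = rng.dirichlet(base * conc)
            profile = profile / profile.sum()
        else:
            profile = base
        for _ in range(params.max_retries):
            motifs = _draw_motifs(rng, profile, n_motifs, motif_length_range)
            if not motifs or motifs not in seen_motifs:
                break
        else:
            raise GenerationError("could not draw a distinct motif set")
        if motifs:
            seen_motifs.add(motifs)
        n_members = int(rng.integers(members_range[0], members_range[1] + 1))
        families.append(generate_family(
            n_members=n_members, length_range=length_range,
            motif_set=motifs,
            composition_profile={r: float(p) for r, p in zip(ALPHABET, profile)},
            params=replace(params, seed=params.seed),
            family_id=fam_id, rng=rng))
    return families


def split_by_family(families: list[SequenceFamily],
                    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                    seed: int = 0) -> DatasetSplit:
    """Disjoint, exhaustive train/validation/test partition of family ids.

    Families are shuffled with the seed and partitioned with
    largest-remainder rounding of the ratios.
    """
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError("ratios must be three positive numbers")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    ids = [f.family_id for f in families]
    if len(ids) < 3:
        raise ValueError("need at least 3 families to split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(ids))
    n = len(order)
    exact = [r * n for r in ratios]
    sizes = [int(e) for e in exact]
    for _ in range(n - sum(sizes)):
        frac = [e - s for e, s in zip(exact, sizes)]
        sizes[int(np.argmax(frac))] += 1
    a, b = sizes[0], sizes[0] + sizes[1]
    return DatasetSplit(train=tuple(order[:a]), validation=tuple(order[a:b]),
                        test=tuple(order[b:]), seed=seed)
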