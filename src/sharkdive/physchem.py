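"""Grantham amino-acid physicochemistry and the residue similarity matrix.

Every k-mer comparison in this package reduces to a 20x20 residue
similarity matrix derived from the Grantham distance

    D(a, b) = rho * [alpha*(c_a - c_b)^2 + beta*(p_a - p_b)^2
                     + gamma*(v_a - v_b)^2]^(1/2)

where c is side-chain atomic composition, p polarity and v molecular
volume, alpha = 1.833, beta = 0.1018, gamma = 0.000399, and rho scales
the mean of the 190 pairwise distances to 100.  Distances are reported
as integers (the convention of the published table; maximum 215 for
Cys/Trp) and converted to a bounded similarity

    sim(a, b) = 1 - D(a, b) / D_max        (D_max = 215 by default)

so that sim is 1 on the diagonal, 0 at the Cys/Trp extreme, and a
strictly decreasing function of distance.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from itertools import combinations

import numpy as np

#: Canonical amino-acid alphabet, alphabetical by one-letter code.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Grantham formula constants.
ALPHA = 1.833
BETA = 0.1018
GAMMA = 0.000399

#: Maximum distance in the published table (Cys vs Trp); default
#: normalisation constant of the similarity transform.
MAX_GRANTHAM_DISTANCE = 215.0

_NONCANONICAL = set("XBZUO*")


class InvalidResidueError(ValueError):
    """A sequence or residue argument contains a non-canonical code."""


def _load_properties() -> dict[str, tuple[float, float, float]]:
    ref = importlib.resources.files("sharkdive.data") / "grantham_properties.tsv"
    props: dict[str, tuple[float, float, float]] = {}
    with ref.open() as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("residue"):
                continue
            residue, c, p, v = line.split("\t")
            props[residue] = (float(c), float(p), float(v))
    if sorted(props) != sorted(ALPHABET):
        raise RuntimeError("packaged Grantham property table is incomplete")
    return props


#: residue -> (c, p, v) on the Grantham scale.
RESIDUE_PROPERTIES: dict[str, tuple[float, float, float]] = _load_properties()


def _unscaled_distance(a: str, b: str,
                       properties: dict[str, tuple[float, float, float]]) -> float:
    ca, pa, va = properties[a]
    cb, pb, vb = properties[b]
    return float(np.sqrt(ALPHA * (ca - cb) ** 2
                         + BETA * (pa - pb) ** 2
                         + GAMMA * (va - vb) ** 2))


def _compute_rho(properties: dict[str, tuple[float, float, float]]) -> float:
    # rho scales the mean over all 190 unordered pairs to 100.
    raw = [_unscaled_distance(a, b, properties)
           for a, b in combinations(sorted(properties), 2)]
    return 100.0 / float(np.mean(raw))


#: Scale factor fixing the mean pairwise distance at 100.
RHO: float = _compute_rho(RESIDUE_PROPERTIES)


def _check_residue(a: str) -> str:
    a = a.upper()
    if a not in RESIDUE_PROPERTIES:
        hint = " (non-canonical; use sanitize to drop)" if a in _NONCANONICAL else ""
        raise InvalidResidueError(f"invalid residue code {a!r}{hint}")
    return a


def grantham_distance(a: str, b: str, *, rounded: bool = True) -> float:
    """Grantham distance between two residues.

    With ``rounded=True`` (default) the integer value of the published
    table is returned; ``rounded=False`` gives the continuous formula
    value.
    """
    a, b = _check_residue(a), _check_residue(b)
    d = RHO * _unscaled_distance(a, b, RESIDUE_PROPERTIES)
    return float(round(d)) if rounded else d


def residue_similarity(a: str, b: str,
                       normalization_constant: float = MAX_GRANTHAM_DISTANCE) -> float:
    """Bounded similarity ``1 - D(a, b) / D_max`` in [0, 1]."""
    return 1.0 - grantham_distance(a, b) / normalization_constant


@dataclass(frozen=True)
class ResidueSimilarityMatrix:
    """20x20 residue similarity lookup with fast sequence encoding.

    Attributes
    ----------
    residues : str
        Row/column order (the canonical alphabet).
    matrix : numpy.ndarray
        Symmetric similarity matrix with unit diagonal, entries in [0, 1].
    normalization_constant : float
        The D_max used in the distance -> similarity transform.
    """

    residues: str
    matrix: np.ndarray
    normalization_constant: float

    def index(self, residue: str) -> int:
        return self.residues.index(_check_residue(residue))

    def sim(self, a: str, b: str) -> float:
        return float(self.matrix[self.index(a), self.index(b)])

    def encode(self, sequence: str) -> np.ndarray:
        """Map a residue string to integer indices into ``matrix``."""
        sequence = sequence.upper()
        try:
            return np.array([self.residues.index(r) for r in sequence],
                            dtype=np.intp)
        except ValueError:
            bad = sorted({r for r in sequence if r not in self.residues})
            raise InvalidResidueError(
                f"sequence contains invalid residue code(s): {', '.join(bad)}")

    def to_emboss(self) -> str:
        """Render the matrix in NCBI/EMBOSS substitution-matrix text layout."""
        lines = ["# Grantham residue similarity matrix (1 - D/%.0f)"
                 % self.normalization_constant,
                 "   " + "  ".join(f"{r:>6s}" for r in self.residues)]
        for i, r in enumerate(self.residues):
            row = "  ".join(f"{self.matrix[i, j]:6.4f}"
                            for j in range(len(self.residues)))
            lines.append(f"{r}  {row}")
        return "\n".join(lines) + "\n"


def build_similarity_matrix(
        properties: dict[str, tuple[float, float, float]] | None = None,
        normalization_constant: float = MAX_GRANTHAM_DISTANCE,
) -> ResidueSimilarityMatrix:
    """Build the residue similarity matrix from a Grantham property table.

    Raises a configuration error when the property set is incomplete or
    the normalisation constant is below the largest pairwise distance
    (which would produce negative similarities).
    """
    if properties is None:
        properties = RESIDUE_PROPERTIES
        rho = RHO
    else:
        if len(properties) != 20:
            raise ValueError(
                f"property set must cover 20 residues, got {len(properties)}")
        rho = _compute_rho(properties)
    residues = "".join(sorted(properties))
    n = len(residues)
    dist = np.zeros((n, n))
    for i, a in enumerate(residues):
        for j, b in enumerate(residues):
            if j > i:
                dist[i, j] = dist[j, i] = round(
                    rho * _unscaled_distance(a, b, properties))
    if normalization_constant < dist.max():
        raise ValueError(
            f"normalization_constant {normalization_constant} is below the "
            f"maximum pairwise distance {dist.max():.0f}")
    matrix = 1.0 - dist / normalization_constant
    return ResidueSimilarityMatrix(residues=residues, matrix=matrix,
                                   normalization_constant=normalization_constant)


_DEFAULT_MATRIX: ResidueSimilarityMatrix | None = None


def default_similarity_matrix() -> ResidueSimilarityMatrix:
    """The packaged Grantham similarity matrix (memoised)."""
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_MATRIX = build_similarity_matrix()
    return _DEFAULT_MATRIX


def sanitize_sequence(sequence: str, policy: str = "drop") -> str:
    """Handle non-canonical residues (X, B, Z, U, O, ``*``).

    policy "drop" removes them (joining the flanking residues, an
    approximation acceptable for rare ambiguity codes); "error" raises.
    """
    sequence = sequence.upper()
    if policy == "error":
        for r in sequence:
            _check_residue(r)
        return sequence
    if policy == "drop":
        return "".join(r for r in sequence if r in RESIDUE_PROPERTIES)
    raise ValueError(f"unknown sanitize policy {policy!r}")
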