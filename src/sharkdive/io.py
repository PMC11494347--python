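"""FASTA / TSV readers and writers, configuration, seeding, provenance."""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .physchem import RESIDUE_PROPERTIES, sanitize_sequence
from .simulate import SequenceRecord

__version__ = "0.1.0"


def read_fasta(path, sanitize: bool = False) -> list[SequenceRecord]:
    """Read a protein FASTA into SequenceRecords.

    Ids are the first whitespace-delimited header token; sequences are
    upper-cased with wrapped lines joined.  Duplicate ids, empty files
    and (without ``sanitize``) non-canonical residues raise.  With
    ``sanitize`` non-canonical residues (X, B, Z, U, O, ``*``) are
    dropped.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if sanitize:
            seq = sanitize_sequence(seq, policy="drop")
        else:
            bad = sorted({r for r in seq if r not in RESIDUE_PROPERTIES})
            if bad:
                raise ValueError(
                    f"record {rec.id!r} contains non-canonical residue(s) "
                    f"{', '.join(bad)}; rerun with sanitize to drop them")
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path, width: int = 60) -> None:
    """Write SequenceRecords as wrapped FASTA (round-trips read_fasta)."""
    if not records:
        raise ValueError("nothing to write: empty record list")
    bio = [BioSeqRecord(Seq(r.sequence), id=r.id, description="")
           for r in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio)


def read_family_map(path) -> dict[str, str]:
    """sequence_id <tab> family_id, '#' comments allowed."""
    mapping: dict[str, str] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{line_no}: expected 2 tab-separated "
                             f"columns, got {len(parts)}")
        seq_id, fam_id = parts
        if seq_id in mapping:
            raise ValueError(f"{path}:{line_no}: duplicate sequence id "
                             f"{seq_id!r}")
        mapping[seq_id] = fam_id
    if not mapping:
        raise ValueError(f"empty family map {path}")
    return mapping


def write_family_map(mapping: dict[str, str], path) -> None:
    lines = ["#sequence_id\tfamily_id"]
    lines += [f"{sid}\t{fid}" for sid, fid in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def family_of_records(records: list[SequenceRecord]) -> dict[str, str]:
    """Family ids by record-id convention: the part before the first '|'."""
    return {r.id: r.id.split("|", 1)[0] for r in records}


# ---------------------------------------------------------------------------
# configuration

@dataclass
class Config:
    """Validated run configuration with defaults for every field."""

    seed: int = 0
    normalization_constant: float = 215.0
    threshold: float = 0.5
    n_submodels: int = 10
    n_estimators: int = 200
    max_depth: int = 3
    learning_rate: float = 0.1
    negative_ratio: float = 1.0
    n_families: int = 50
    members_range: tuple[int, int] = (5, 20)
    length_range: tuple[int, int] = (50, 300)
    n_motifs: int = 3
    motif_length_range: tuple[int, int] = (6, 10)
    substitution_rate: float = 0.40
    insertion_rate: float = 0.03
    deletion_rate: float = 0.03
    unrelated_profile_spread: float = 1.0
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    explain_k: int = 8
    explain_T: float = 0.85
    background_pairs: int = 10_000
    verbosity: int = 1

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.n_submodels < 2:
            raise ValueError("n_submodels must be >= 2")
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def load_config(path=None, **overrides) -> Config:
    """Defaults <- YAML file <- keyword/CLI overrides, unknown keys rejected."""
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dc_fields(Config)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    for name in ("members_range", "length_range", "motif_length_range",
                 "split_ratios"):
        if name in values and isinstance(values[name], list):
            values[name] = tuple(values[name])
    return Config(**values)


# ---------------------------------------------------------------------------
# seeding and provenance

def derive_seed(seed: int, module: str) -> int:
    """Deterministic per-module seed below 2**31."""
    return int(np.random.SeedSequence(
        [int(seed), zlib.crc32(module.encode())]).generate_state(1)[0] % (2 ** 31))


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_provenance(out_dir, config: Config, inputs: dict | None = None,
                     extra: dict | None = None) -> None:
    """Drop a provenance JSON (version, config, seed, input digests)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {name: _digest(p) for name, p in (inputs or {}).items()
                   if Path(p).exists()},
    }
    payload.update(extra or {})
    (out_dir / "provenance.json").write_text(
        json.dumps(payload, indent=2, default=str) + "\n")
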