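"""Sequence records, FASTA/FASTQ readers/writers, run configuration and RNG management.

All coordinates written by this package are 0-based half-open; coordinates on
circular plasmid constructs wrap modulo the construct length. FASTQ qualities
are Phred+33 throughout.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from Bio import SeqIO

logger = logging.getLogger("amocap")

# IUPAC nucleotide codes plus the 20 amino acids, '*' (stop) and 'X'.
IUPAC_NT = set("ACGTURYSWKMBDHVN")
AA = set("ACDEFGHIKLMNPQRSTVWY*X")
_ALPHABET = IUPAC_NT | AA

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(primer_base: str, template_base: str) -> bool:
    """True when a degenerate primer base is compatible with a template base."""
    return template_base in IUPAC_SETS.get(primer_base, frozenset())


class FormatError(ValueError):
    """Malformed sequence file; message names the offending line when known."""


@dataclass
class SeqRecord:
    """A named sequence with optional Phred qualities and free-form metadata.

    Sequences are normalised to uppercase on construction. ``qual``, when
    present, must match the sequence length (Phred scores, not encoded).
    """

    id: str
    seq: str
    qual: list[int] | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise FormatError(f"record {self.id!r}: non-IUPAC symbols {sorted(bad)}")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.qual)} != sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords (uppercased, no qualities)."""
    path = Path(path)
    _scan_fasta_structure(path)
    return [SeqRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _scan_fasta_structure(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                return
            raise FormatError(f"{path}: line {lineno}: expected '>' header, got {line[:30]!r}")


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read 4-line FASTQ (Phred+33). Truncated or inconsistent records raise."""
    path = Path(path)
    records: list[SeqRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            records.append(
                SeqRecord(rec.id, str(rec.seq), qual=list(rec.letter_annotations["phred_quality"]))
            )
    except ValueError as exc:
        lineno = 4 * len(records) + 1
        raise FormatError(f"{path}: record starting near line {lineno}: {exc}") from exc
    return records


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.qual is None:
                raise FormatError(f"record {rec.id!r}: FASTQ output requires qualities")
            qline = "".join(chr(q + 33) for q in rec.qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qline}\n")


def rng(seed: int, label: str | None = None) -> np.random.Generator:
    """Deterministic random stream; module streams derive from one global seed.

    ``label`` gives an independent substream (e.g. per module or per sample)
    reproducibly keyed by the string.
    """
    if label is None:
        ss = np.random.SeedSequence(seed)
    else:
        ss = np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    return np.random.default_rng(ss)


@dataclass
class RunConfig:
    """Every tunable threshold of the toolkit, with the package defaults.

    Serialisable to/from YAML; workflows log the fully resolved config so any
    run is reproducible from (inputs, RunConfig).
    """

    seed: int = 0
    # probe design
    probe_len: int = 100
    stride: int = 50
    # reference curation
    exclusion_min_identity: float = 0.80
    exclusion_min_cov: float = 0.50
    # mock community
    vector_len: int = 2739
    diluent_len: int = 2786
    insert_lens: tuple[int, ...] = (654, 702, 738, 768, 792, 846)
    contaminant_read_fraction: float = 0.0009
    # fragmentation / library
    frag_len_mean: float = 200.0
    frag_len_sd: float = 30.0
    size_select_min_len: int = 150
    read_len: int = 300
    error_rate: float = 1e-3
    # capture model
    capture_min_overlap: int = 100
    capture_min_identity: float = 0.80
    nonspecific_rate: float = 1e-4
    # PCR model
    pcr_efficiency: float = 0.9
    mismatch_penalty: float = 0.5
    chimera_rate: float = 1e-4
    # QC
    min_qual: int = 20
    min_read_len: int = 100
    dust_threshold: float = 7.0
    hifi_end_trim: int = 20
    hifi_len_min: int = 400
    hifi_len_max: int = 1000
    # homology filter
    search_min_identity: float = 60.0
    search_min_qcov: float = 50.0
    search_min_scov: float = 50.0
    cds_len_min: int = 400
    cds_len_max: int = 1000
    # chimera removal
    chimera_delta: float = 1.5
    # clustering
    cluster_identity: float = 0.97
    cluster_coverage: float = 0.50
    discard_singletons: bool = True
    # mapping / quantification
    seed_len: int = 22
    seed_mismatch: int = 1
    min_aligned_fraction: float = 0.9
    rarefaction_min_mapped: int = 100
    # classification
    taxonomy_floor_identity: float = 75.0

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["insert_lens"] = list(self.insert_lens)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "insert_lens" in data:
            data["insert_lens"] = tuple(data["insert_lens"])
        return cls(**data)

    def log_resolved(self) -> None:
        logger.info("resolved config: %s", dataclasses.asdict(self))


def write_tsv(path: str | Path, header_comment: str, columns: list[str], rows: Iterable[Iterable]) -> None:
    """Tab-separated table with a commented header naming units."""
    with open(path, "w") as fh:
        fh.write(f"# {header_comment}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
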