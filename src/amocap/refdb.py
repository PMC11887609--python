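"""Curated CuMMO reference database: deduplication, rRNA exclusion screen,
and the recruitment-power diagnostic used to explain capture bias.

The database is the substrate for both probe design and the downstream
homology filter. Records carry ``gene_family`` (amoA-AOA, amoA-AOB, pmoA,
other-CuMMO), ``clade`` and ``source`` labels in their metadata.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from ._align import nt_local_identity, shares_kmer
from .io_core import SeqRecord, read_fasta, write_tsv

logger = logging.getLogger("amocap.refdb")

GENE_FAMILIES = ("amoA-AOA", "amoA-AOB", "pmoA", "other-CuMMO")


@dataclass
class ReferenceDB:
    """A deduplicated, exclusion-screened target-gene collection.

    Invariants: no two records share an identical sequence string, and no
    record retains a qualifying local alignment to the exclusion set.
    """

    records: list[SeqRecord]
    n_input: int = 0
    n_after_dedup: int = 0
    n_after_exclusion: int = 0
    removed_log: list[tuple[str, str, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def build(
        cls,
        records: list[SeqRecord],
        exclusion_refs: list[SeqRecord] | None = None,
        min_identity: float = 0.80,
        min_cov: float = 0.50,
    ) -> "ReferenceDB":
        """Run the full curation: exact dedup then exclusion screen."""
        db = cls(records=list(records), n_input=len(records))
        db.records = dedup_exact(db.records)
        db.n_after_dedup = len(db.records)
        if exclusion_refs:
            db.records, db.removed_log = screen_exclusion(
                db.records, exclusion_refs, min_identity=min_identity, min_cov=min_cov
            )
        db.n_after_exclusion = len(db.records)
        logger.info(
            "refdb curation: %d input -> %d after dedup -> %d after exclusion screen",
            db.n_input, db.n_after_dedup, db.n_after_exclusion,
        )
        return db

    @classmethod
    def from_fasta(
        cls,
        fasta_path: str | Path,
        labels_tsv: str | Path | None = None,
        **kwargs,
    ) -> "ReferenceDB":
        """Load sequences plus an optional (id, gene_family, clade) label table."""
        records = read_fasta(fasta_path)
        if labels_tsv is not None:
            labels: dict[str, dict[str, str]] = {}
            with open(labels_tsv) as fh:
                reader = csv.DictReader(
                    (l for l in fh if not l.startswith("#")), delimiter="\t"
                )
                for row in reader:
                    labels[row["id"]] = {
                        "gene_family": row.get("gene_family", ""),
                        "clade": row.get("clade", ""),
                        "source": row.get("source", ""),
                    }
            for rec in records:
                rec.meta.update(labels.get(rec.id, {}))
        return cls.build(records, **kwargs)

    def write_report(self, path: str | Path) -> None:
        write_tsv(
            path,
            "reference curation report; counts are sequence records",
            ["stage", "n_records"],
            [
                ("input", self.n_input),
                ("after_dedup", self.n_after_dedup),
                ("after_exclusion_screen", self.n_after_exclusion),
            ],
        )


def dedup_exact(records: list[SeqRecord]) -> list[SeqRecord]:
    """Keep one representative per identical sequence string (first occurrence).

    Duplicate means exact full-string equality on the forward strand;
    reverse-complement near-duplicates are handled by strand-agnostic search
    downstream.
    """
    seen: set[str] = set()
    kept: list[SeqRecord] = []
    for rec in records:
        if rec.seq not in seen:
            seen.add(rec.seq)
            kept.append(rec)
    return kept


def screen_exclusion(
    records: list[SeqRecord],
    exclusion_refs: list[SeqRecord],
    min_identity: float = 0.80,
    min_cov: float = 0.50,
) -> tuple[list[SeqRecord], list[tuple[str, str, float]]]:
    """Remove records with a qualifying local alignment to any exclusion ref.

    A record is removed when its best local alignment to an exclusion
    reference (either strand) reaches ``min_identity`` over at least
    ``min_cov`` of the shorter sequence. Removals are logged with the best-hit
    identity.
    """
    if not exclusion_refs:
        raise ValueError("exclusion_refs must be non-empty")
    kept: list[SeqRecord] = []
    removed: list[tuple[str, str, float]] = []
    for rec in records:
        hit = None
        for ref in exclusion_refs:
            if not shares_kmer(rec.seq, ref.seq, k=12):
                continue
            identity, coverage = nt_local_identity(rec.seq, ref.seq)
            if identity >= min_identity and coverage >= min_cov:
                hit = (ref.id, identity)
                break
        if hit is None:
            kept.append(rec)
        else:
            removed.append((rec.id, hit[0], round(hit[1], 4)))
            logger.info(
                "exclusion screen removed %s (best hit %s, identity %.3f)",
                rec.id, hit[0], hit[1],
            )
    return kept, removed


def recruitment_power(
    db: ReferenceDB | list[SeqRecord], query_gene: SeqRecord | str, min_identity: float = 0.95
) -> int:
    """Number of database records aligning to the query gene at >= min_identity
    over >= 50% of the shorter sequence.

    A low count signals weak probe recruitment for that lineage: few database
    relatives means few probes able to hybridise, the mechanism behind the
    depletion of poorly represented clades during capture.
    """
    records = db.records if isinstance(db, ReferenceDB) else db
    query = query_gene.seq if isinstance(query_gene, SeqRecord) else query_gene.upper()
    count = 0
    for rec in records:
        if not shares_kmer(query, rec.seq, k=12):
            continue
        identity, coverage = nt_local_identity(query, rec.seq)
        if identity >= min_identity and coverage >= 0.5:
            count += 1
    return count
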