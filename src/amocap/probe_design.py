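"""Tiled 100-mer capture-probe design over a reference database.

Probes are laid on the forward strand at a fixed stride, with the terminal
probe right-anchored at the record end so the 3' end is always covered.
Capture matching downstream is strand-agnostic, which is equivalent for
double-stranded libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .io_core import SeqRecord, write_tsv
from .refdb import ReferenceDB

logger = logging.getLogger("amocap.probe_design")


@dataclass
class Probe:
    probe_id: str
    source_id: str
    offset: int  # 0-based start on the source record
    seq: str


@dataclass
class ProbeSet:
    probes: list[Probe]
    probe_len: int = 100
    stride: int = 50
    coverage_fraction: float = 0.0
    coverage_fraction_pre_dedup: float = 0.0
    per_record_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.probes)

    def sequences(self) -> list[str]:
        return [p.seq for p in self.probes]

    def to_fasta_records(self) -> list[SeqRecord]:
        # probe id encodes source:offset (0-based)
        return [SeqRecord(f"{p.source_id}:{p.offset}", p.seq) for p in self.probes]

    def write_report(self, path: str | Path) -> None:
        write_tsv(
            path,
            f"probe design report; probe_len={self.probe_len} nt, stride={self.stride} nt; "
            "coverage is fraction of database nucleotides under >=1 probe",
            ["record", "n_probes"],
            sorted(self.per_record_counts.items()),
        )


def _records(db: ReferenceDB | list[SeqRecord]) -> list[SeqRecord]:
    return db.records if isinstance(db, ReferenceDB) else db


def tile_probes(db: ReferenceDB | list[SeqRecord], probe_len: int = 100, stride: int = 50) -> ProbeSet:
    """Tile probes at offsets 0, stride, 2*stride, ... plus a final probe ending
    exactly at the record end. Records shorter than ``probe_len`` yield none.
    """
    if probe_len < 1 or stride < 1:
        raise ValueError("probe_len and stride must be >= 1")
    probes: list[Probe] = []
    counts: dict[str, int] = {}
    for rec in _records(db):
        L = len(rec.seq)
        if L < probe_len:
            counts[rec.id] = 0
            continue
        offsets = list(range(0, L - probe_len + 1, stride))
        last = L - probe_len
        if offsets[-1] != last:
            offsets.append(last)  # right-anchored terminal probe
        for off in offsets:
            probes.append(Probe(f"{rec.id}:{off}", rec.id, off, rec.seq[off : off + probe_len]))
        counts[rec.id] = len(offsets)
    pset = ProbeSet(probes, probe_len=probe_len, stride=stride, per_record_counts=counts)
    pset.coverage_fraction_pre_dedup = coverage(pset, db)
    pset.coverage_fraction = pset.coverage_fraction_pre_dedup
    logger.info("tiled %d probes (len %d, stride %d)", len(probes), probe_len, stride)
    return pset


def dedup_probes(pset: ProbeSet, db: ReferenceDB | list[SeqRecord] | None = None) -> ProbeSet:
    """Collapse identical probe sequences to one, keeping the first source.

    Prevents probes shared by multiple genes from being over-represented.
    When ``db`` is given, coverage is recomputed on the deduplicated set while
    the pre-dedup coverage is retained for reporting (both are of interest
    because dedup can uncover positions on records that lost their copy).
    """
    seen: set[str] = set()
    kept: list[Probe] = []
    for probe in pset.probes:
        if probe.seq not in seen:
            seen.add(probe.seq)
            kept.append(probe)
    out = ProbeSet(
        kept,
        probe_len=pset.probe_len,
        stride=pset.stride,
        per_record_counts=dict(pset.per_record_counts),
    )
    out.coverage_fraction_pre_dedup = pset.coverage_fraction_pre_dedup
    out.coverage_fraction = coverage(out, db) if db is not None else pset.coverage_fraction
    return out


def coverage(pset: ProbeSet, db: ReferenceDB | list[SeqRecord]) -> float:
    """Fraction of database nucleotide positions under at least one probe
    footprint (union of intervals, per source record)."""
    records = _records(db)
    total = sum(len(r.seq) for r in records)
    if total == 0:
        return 0.0
    by_source: dict[str, list[tuple[int, int]]] = {}
    for probe in pset.probes:
        by_source.setdefault(probe.source_id, []).append(
            (probe.offset, probe.offset + len(probe.seq))
        )
    lengths = {r.id: len(r.seq) for r in records}
    covered = 0
    for source_id, intervals in by_source.items():
        if source_id not in lengths:
            continue
        intervals.sort()
        cur_start, cur_end = intervals[0]
        for start, end in intervals[1:]:
            if start <= cur_end:
                cur_end = max(cur_end, end)
            else:
                covered += cur_end - cur_start
                cur_start, cur_end = start, end
        covered += min(cur_end, lengths[source_id]) - cur_start
    return covered / total
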