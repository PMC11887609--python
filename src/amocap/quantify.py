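"""Read-to-OTU mapping and abundance estimation.

Abundances are RPKMS: reads per kilobase of gene per million reads sequenced,
with the per-sample denominator taken as the quality-controlled read count.
Mapping follows seed-and-extend semantics with one mismatch tolerated in the
seed; ambiguous equal-best assignments are discarded rather than placed at
random, so abundances carry no tie-breaking noise. Rarefaction uses the exact
hypergeometric expectation instead of resampling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .capture_sim import ReadSet
from .gene_pipeline import Otu
from .io_core import SeqRecord, revcomp

logger = logging.getLogger("amocap.quantify")


@dataclass
class MappingParams:
    seed_len: int = 22
    seed_mismatch: int = 1  # 0 or 1, the "-N" style seed tolerance
    min_aligned_fraction: float = 0.9
    pair_rule: bool = True  # both mates must hit the same OTU

    def __post_init__(self) -> None:
        if self.seed_mismatch not in (0, 1):
            raise ValueError("seed_mismatch must be 0 or 1")


@dataclass
class OtuTable:
    """Per-sample OTU read counts and RPKMS with per-OTU lengths."""

    counts: pd.DataFrame  # samples x OTUs, mapped reads
    rpkms: pd.DataFrame  # samples x OTUs
    totals: dict[str, int] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# OTU table: mapped read counts and RPKMS "
                     "(reads per kilobase of gene per million reads sequenced)\n")
            fh.write("## counts\n")
            self.counts.to_csv(fh, sep="\t")
            fh.write("## rpkms\n")
            self.rpkms.to_csv(fh, sep="\t")


class _OtuIndex:
    """Half-seed k-mer index over OTU representatives (both strands).

    With seed length 2k and at most one seed mismatch, one exact k-mer half
    survives (pigeonhole), so exact k-mer lookup is a complete candidate
    filter for the seed criterion.
    """

    def __init__(self, otus: list[Otu], params: MappingParams):
        self.params = params
        self.otus = otus
        self.k = max(params.seed_len // 2, 8) if params.seed_mismatch else params.seed_len
        self.reps: list[tuple[str, str]] = [
            (otu.representative, revcomp(otu.representative)) for otu in otus
        ]
        self.index: dict[str, set[int]] = {}
        for oi, (fwd, rev) in enumerate(self.reps):
            for strand_seq in (fwd, rev):
                for i in range(len(strand_seq) - self.k + 1):
                    self.index.setdefault(strand_seq[i : i + self.k], set()).add(oi)

    def assign(self, read_seq: str) -> str | None:
        k = self.k
        if len(read_seq) < k:
            return None
        stride = max(1, k // 2)
        positions = list(range(0, len(read_seq) - k + 1, stride))
        candidates: set[int] = set()
        for i in positions:
            hit = self.index.get(read_seq[i : i + k])
            if hit:
                candidates.update(hit)
        if not candidates:
            return None
        max_dist = math.floor(len(read_seq) * (1.0 - self.params.min_aligned_fraction))
        best_dist = None
        best_otus: set[int] = set()
        for oi in candidates:
            fwd, rev = self.reps[oi]
            dist = None
            for target in (fwd, rev):
                if len(read_seq) > len(target):
                    continue
                res = edlib.align(read_seq, target, mode="HW", task="distance", k=max_dist)
                if res["editDistance"] != -1:
                    d = res["editDistance"]
                    dist = d if dist is None else min(dist, d)
            if dist is None:
                continue
            if best_dist is None or dist < best_dist:
                best_dist, best_otus = dist, {oi}
            elif dist == best_dist:
                best_otus.add(oi)
        if best_dist is None or len(best_otus) != 1:
            return None  # unmapped, or ambiguous tie discarded
        return self.otus[next(iter(best_otus))].otu_id


def map_reads(
    reads: ReadSet | list[SeqRecord],
    otus: list[Otu],
    params: MappingParams | None = None,
) -> list[str | None]:
    """Best-scoring OTU per read (None = unassigned).

    Seed-and-extend on both strands; the read must align over at least
    ``min_aligned_fraction`` of its length, which systematically leaves reads
    straddling a gene boundary unassigned. Equal-best ties are discarded.
    """
    params = params or MappingParams()
    if isinstance(reads, ReadSet):
        if reads.layout == "paired" and reads.mates is not None and params.pair_rule:
            return map_pairs(reads.reads, reads.mates, otus, params)
        records = reads.reads
    else:
        records = reads
    if not otus:
        raise ValueError("OTU list must be non-empty")
    index = _OtuIndex(otus, params)
    return [index.assign(rec.seq) for rec in records]


def map_pairs(
    fwd: list[SeqRecord],
    rev: list[SeqRecord],
    otus: list[Otu],
    params: MappingParams | None = None,
) -> list[str | None]:
    """Paired mapping under the same-OTU pair rule: a pair counts only when
    both mates are assigned to the same OTU."""
    params = params or MappingParams()
    if not otus:
        raise ValueError("OTU list must be non-empty")
    index = _OtuIndex(otus, params)
    out: list[str | None] = []
    for f, r in zip(fwd, rev):
        a, b = index.assign(f.seq), index.assign(r.seq)
        out.append(a if (a is not None and a == b) else None)
    return out


def rpkms(
    counts: pd.DataFrame | dict,
    lengths: dict[str, int],
    totals: dict[str, int],
) -> OtuTable:
    """RPKMS = mapped_reads / (gene length in kb * total reads in millions)."""
    counts_df = pd.DataFrame(counts).T if isinstance(counts, dict) else counts.copy()
    for otu_id in counts_df.columns:
        if lengths.get(otu_id, 0) <= 0:
            raise ValueError(f"OTU {otu_id} has zero length")
    values = counts_df.astype(float).copy()
    for sample in values.index:
        total = totals[sample]
        if total <= 0:
            raise ValueError(f"sample {sample} has zero total reads")
        for otu_id in values.columns:
            values.loc[sample, otu_id] = counts_df.loc[sample, otu_id] / (
                (lengths[otu_id] / 1e3) * (total / 1e6)
            )
    return OtuTable(counts=counts_df, rpkms=values, totals=dict(totals), lengths=dict(lengths))


def build_otu_table(
    assignments_by_sample: dict[str, list[str | None]],
    otus: list[Otu],
    totals: dict[str, int] | None = None,
) -> OtuTable:
    """Count assignments per sample and compute RPKMS.

    ``totals`` defaults to the number of reads submitted to mapping per
    sample; pass the QC read counts to follow the per-million-reads-sequenced
    convention when mapping a subset.
    """
    otu_ids = [o.otu_id for o in otus]
    lengths = {o.otu_id: len(o.representative) for o in otus}
    counts = pd.DataFrame(
        0, index=sorted(assignments_by_sample), columns=otu_ids, dtype=int
    )
    resolved_totals: dict[str, int] = {}
    for sample, assignments in assignments_by_sample.items():
        for a in assignments:
            if a is not None:
                counts.loc[sample, a] += 1
        resolved_totals[sample] = (
            totals[sample] if totals is not None else len(assignments)
        )
    return rpkms(counts, lengths, resolved_totals)


def mapped_ratio(assignments: list[str | None], total_reads: int | None = None) -> float:
    """Assigned reads over total QC reads."""
    total = total_reads if total_reads is not None else len(assignments)
    if total == 0:
        return 0.0
    return sum(a is not None for a in assignments) / total


def enrichment_factor(ratio_capture: float, ratio_noncapture: float) -> float:
    """Fold enrichment of the capture arm over the non-capture arm.

    A zero non-capture ratio is reported as infinity (flagged by the caller's
    formatting, not an error)."""
    if ratio_noncapture == 0:
        logger.warning("enrichment_factor: zero non-capture ratio, reporting inf")
        return math.inf
    return ratio_capture / ratio_noncapture


def _log_comb(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(
        np.asarray(n) - np.asarray(k) + 1
    )


def rarefaction(
    per_sample_assignments: dict[str, list[str | None]],
    min_mapped: int = 100,
    n_draws: int = 20,
) -> pd.DataFrame:
    """Expected OTU richness at subsample sizes, per sample.

    Uses the exact hypergeometric expectation
    E[S_m] = S - sum_i C(N - n_i, m) / C(N, m), which removes the resampling
    noise of a draw-based rarefaction. Samples with fewer than ``min_mapped``
    mapped reads are excluded.
    """
    rows = []
    for sample in sorted(per_sample_assignments):
        mapped = [a for a in per_sample_assignments[sample] if a is not None]
        N = len(mapped)
        if N < min_mapped:
            logger.info("rarefaction: excluding %s (%d < %d mapped reads)",
                        sample, N, min_mapped)
            continue
        counts = pd.Series(mapped).value_counts().to_numpy()
        S = len(counts)
        sizes = np.unique(np.linspace(1, N, num=min(n_draws, N), dtype=int))
        for m in sizes:
            absent = np.zeros(S)
            ok = N - counts >= m
            absent[ok] = np.exp(_log_comb(N - counts[ok], m) - _log_comb(N, m))
            rows.append((sample, int(m), float(S - absent.sum())))
    return pd.DataFrame(rows, columns=["sample", "subsample_size", "expected_otus"])


def nlinker_concat(
    readset: ReadSet, linker_len: int = 50
) -> list[SeqRecord]:
    """Concatenate each pair as forward + N-linker + reverse-complement(mate).

    Used as the chimera-screen input for short-read amplicon data, where 2x300
    reads cannot span the whole product.
    """
    if readset.layout != "paired" or readset.mates is None:
        raise ValueError("nlinker_concat expects a paired ReadSet")
    linker = "N" * linker_len
    out = []
    for fwd, rev in zip(readset.reads, readset.mates):
        out.append(
            SeqRecord(fwd.id, fwd.seq + linker + revcomp(rev.seq), meta=dict(fwd.meta))
        )
    return out
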