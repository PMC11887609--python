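"""From raw reads to OTUs: QC, pair merging, greedy assembly, ORF extraction,
CuMMO homology filtering, two-parent chimera removal and 97% centroid
clustering with singleton discard.

Assembly and CDS prediction are deliberately simple deterministic algorithms
(greedy overlap-consensus; six-frame maximal-ORF scan) sized for desk-scale
marker-gene problems; the scientific content of the pipeline is the
filter/cluster/quantify logic, and every stage logs its in/out counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from ._align import aa_local_identity
from .capture_sim import ReadSet
from .io_core import SeqRecord, revcomp
from .refdb import ReferenceDB

logger = logging.getLogger("amocap.gene_pipeline")

START_CODONS = ("ATG", "GTG", "TTG")  # translation table 11
STOP_CODONS = ("TAA", "TAG", "TGA")

# byte -> base code for the triplet complexity statistic (non-ACGT -> 4)
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


@dataclass
class QcParams:
    min_qual: int = 20
    min_len: int = 100
    complexity_screen: bool = True
    dust_threshold: float = 7.0
    hifi_end_trim: int = 20
    hifi_len_range: tuple[int, int] = (400, 1000)


@dataclass
class Contig:
    id: str
    seq: str
    member_reads: int
    sample: str = ""


@dataclass
class CandidateCds:
    id: str
    nt_seq: str
    aa_seq: str
    contig_id: str
    sample: str = ""
    abundance: float = 1.0
    strand: str = "+"
    hit: dict | None = None


@dataclass
class Otu:
    otu_id: str
    representative: str
    rep_id: str
    members: list[str] = field(default_factory=list)
    member_count: int = 0
    total_abundance: float = 0.0


def dust_score(seq: str) -> float:
    """Low-complexity score on a 0-100 scale (100 = homopolymer).

    Triplet-based DUST-style statistic: 100 * sum c_t(c_t-1)/2 over the
    maximum possible pair count for the sequence length.
    """
    n = len(seq)
    if n < 5:
        return 0.0
    x = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int32)
    codes = x[:-2] * 25 + x[1:-1] * 5 + x[2:]
    c = np.bincount(codes, minlength=125)
    pairs = int((c * (c - 1) // 2).sum())
    max_pairs = (n - 2) * (n - 3) / 2
    return 100.0 * pairs / max_pairs if max_pairs > 0 else 0.0


def _trim_low_quality_ends(rec: SeqRecord, min_qual: int) -> SeqRecord:
    if rec.qual is None:
        return rec
    lo, hi = 0, len(rec.seq)
    while lo < hi and rec.qual[lo] < min_qual:
        lo += 1
    while hi > lo and rec.qual[hi - 1] < min_qual:
        hi -= 1
    if lo == 0 and hi == len(rec.seq):
        return rec
    return SeqRecord(rec.id, rec.seq[lo:hi], qual=rec.qual[lo:hi], meta=dict(rec.meta))


def qc_short_reads(readset: ReadSet, params: QcParams | None = None) -> ReadSet:
    """End-trim at Q < min_qual, then drop reads shorter than ``min_len`` or
    failing the complexity screen. Pairs stay synchronised: when one mate
    fails, its partner is dropped too."""
    params = params or QcParams()
    if readset.layout != "paired" or readset.mates is None:
        raise ValueError("qc_short_reads expects a paired ReadSet")

    def passes(rec: SeqRecord) -> SeqRecord | None:
        trimmed = _trim_low_quality_ends(rec, params.min_qual)
        if len(trimmed.seq) < params.min_len:
            return None
        if params.complexity_screen and dust_score(trimmed.seq) >= params.dust_threshold:
            return None
        return trimmed

    out = ReadSet(layout="paired", reads=[], mates=[])
    for fwd, rev in zip(readset.reads, readset.mates):
        t1, t2 = passes(fwd), passes(rev)
        if t1 is not None and t2 is not None:
            out.reads.append(t1)
            out.mates.append(t2)
    logger.info("qc_short_reads: %d -> %d pairs", len(readset.reads), len(out.reads))
    return out


def qc_hifi(readset: ReadSet, params: QcParams | None = None) -> ReadSet:
    """Long-read QC: the [min,max] length filter is applied first, then a fixed
    end-trim (primer removal) on both terminals."""
    params = params or QcParams()
    lo, hi = params.hifi_len_range
    trim = params.hifi_end_trim
    out = ReadSet(layout="single", reads=[], mates=None)
    for rec in readset.reads:
        if not (lo <= len(rec.seq) <= hi):
            continue
        seq = rec.seq[trim : len(rec.seq) - trim]
        qual = rec.qual[trim : len(rec.qual) - trim] if rec.qual else None
        if seq:
            out.reads.append(SeqRecord(rec.id, seq, qual=qual, meta=dict(rec.meta)))
    logger.info("qc_hifi: %d -> %d reads", len(readset.reads), len(out.reads))
    return out


def merge_pairs(
    readset: ReadSet, min_overlap: int = 20, max_mismatch_density: float = 0.1
) -> tuple[ReadSet, ReadSet]:
    """Merge mate pairs by suffix-prefix (or full-containment) overlap.

    Consensus bases take the higher-quality mate (forward wins ties). Returns
    (merged single-end ReadSet, unmerged pairs flagged ``merge_failed``).
    """
    if readset.layout != "paired" or readset.mates is None:
        raise ValueError("merge_pairs expects a paired ReadSet")
    merged = ReadSet(layout="single", reads=[], mates=None)
    unmerged = ReadSet(layout="paired", reads=[], mates=[])
    for fwd, rev in zip(readset.reads, readset.mates):
        r2 = revcomp(rev.seq)
        q2 = rev.qual[::-1] if rev.qual else [30] * len(r2)
        q1 = fwd.qual if fwd.qual else [30] * len(fwd.seq)
        offset = _find_merge_offset(fwd.seq, r2, min_overlap, max_mismatch_density)
        if offset is None:
            f = SeqRecord(fwd.id, fwd.seq, qual=fwd.qual,
                          meta={**fwd.meta, "merge_failed": "1"})
            r = SeqRecord(rev.id, rev.seq, qual=rev.qual,
                          meta={**rev.meta, "merge_failed": "1"})
            unmerged.reads.append(f)
            unmerged.mates.append(r)
            continue
        o = min(len(fwd.seq) - offset, len(r2))
        if fwd.seq[offset : offset + o] == r2[:o]:
            # identical overlap: no per-base consensus needed
            seq_str = fwd.seq[:offset] + r2
            qual = list(q1[: offset + o]) + list(q2[o:])
        else:
            seq = list(fwd.seq[:offset])
            qual = list(q1[:offset])
            for j in range(o):
                b1, b2 = fwd.seq[offset + j], r2[j]
                s1, s2 = q1[offset + j], q2[j]
                seq.append(b1 if (b1 == b2 or s1 >= s2) else b2)
                qual.append(max(s1, s2))
            seq += list(r2[o:])
            qual += list(q2[o:])
            seq_str = "".join(seq)
        merged.reads.append(
            SeqRecord(fwd.id, seq_str, qual=qual, meta={**fwd.meta, "merged": "1"})
        )
    logger.info("merge_pairs: %d pairs -> %d merged, %d unmerged",
                len(readset.reads), len(merged.reads), len(unmerged.reads))
    return merged, unmerged


def _mismatches(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _find_merge_offset(
    r1: str, r2: str, min_overlap: int, max_density: float
) -> int | None:
    """Offset of r2 within the merged coordinate system, or None.

    Candidate offsets come from an exact 16-mer anchor near the start of r2,
    with offset 0 (full containment, the common case for short fragments)
    tried first; a brute-force scan is the last resort.
    """
    n1, n2 = len(r1), len(r2)

    def check(d: int) -> bool:
        if d < 0 or d > n1 - min_overlap:
            return False
        o = min(n1 - d, n2)
        if o < min_overlap:
            return False
        return _mismatches(r1[d:d + o], r2[:o], int(max_density * o)) <= max_density * o

    if check(0):
        return 0
    k = 16
    for anchor_start in (0, k, 2 * k):
        if anchor_start + k > n2:
            break
        anchor = r2[anchor_start : anchor_start + k]
        pos = r1.find(anchor)
        while pos != -1:
            d = pos - anchor_start
            if d > 0 and check(d):
                return d
            pos = r1.find(anchor, pos + 1)
    for d in range(1, n1 - min_overlap + 1):
        if check(d):
            return d
    return None


def _dedup_reads(seqs: list[str]) -> list[tuple[str, int]]:
    counts: dict[str, int] = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    # order: abundance desc, length desc, sequence asc — deterministic
    return sorted(counts.items(), key=lambda kv: (-kv[1], -len(kv[0]), kv[0]))


def assemble(
    reads: ReadSet | list[SeqRecord],
    k: int = 31,
    min_overlap: int = 30,
    sample: str = "",
    min_extension_support: int = 2,
    max_contig_len: int = 20_000,
    absorb_max_divergence: float = 0.02,
) -> list[Contig]:
    """Deterministic greedy overlap-consensus assembly.

    Seeds with the most abundant unused read, extends both directions through
    exact suffix-prefix overlaps of >= ``min_overlap`` nt, taking the
    abundance-weighted majority base per extension column and stopping when
    fewer than ``min_extension_support`` reads support the next column (or on
    circular wrap-around). Reads within ``absorb_max_divergence`` edit
    distance of a finished contig are assigned to it. Contigs supported by
    >= 2 reads are emitted. Reads are assembled as-is on their given strand
    (the upstream merger orients pairs onto the fragment strand).
    """
    records = reads.reads if isinstance(reads, ReadSet) else reads
    unique = _dedup_reads([r.seq for r in records])
    if not unique:
        return []
    n_unique = len(unique)
    fwd_seqs = [s for s, _ in unique]
    counts = [c for _, c in unique]
    rev_seqs = [s[::-1] for s in fwd_seqs]  # for leftward extension
    fwd_index: dict[str, list[int]] = {}
    rev_index: dict[str, list[int]] = {}
    for idx in range(n_unique):
        if len(fwd_seqs[idx]) >= min_overlap:
            fwd_index.setdefault(fwd_seqs[idx][:min_overlap], []).append(idx)
            rev_index.setdefault(rev_seqs[idx][:min_overlap], []).append(idx)
    max_read_len = max(len(s) for s in fwd_seqs)
    used = [False] * n_unique
    contigs: list[Contig] = []

    def extend_right(contig: str, index: dict[str, list[int]], seqs: list[str]) -> str:
        """Grow the contig rightwards until support runs out or it wraps."""
        while len(contig) < max_contig_len:
            lo = max(0, len(contig) - max_read_len)
            hi = len(contig) - min_overlap
            candidates: list[tuple[int, str, int]] = []  # (offset, seq, count)
            for p in range(lo, hi + 1):
                for idx in index.get(contig[p : p + min_overlap], ()):
                    if used[idx]:
                        continue
                    seq = seqs[idx]
                    if p + len(seq) > len(contig) and seq.startswith(contig[p:]):
                        candidates.append((p, seq, counts[idx]))
            if not candidates:
                return contig
            extension: list[str] = []
            col = len(contig)
            while True:
                votes: dict[str, int] = {}
                for p, seq, count in candidates:
                    j = col - p
                    if 0 <= j < len(seq):
                        votes[seq[j]] = votes.get(seq[j], 0) + count
                if not votes or sum(votes.values()) < min_extension_support:
                    break
                extension.append(min(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0])
                col += 1
            if not extension:
                return contig
            contig = contig + "".join(extension)
            # circular wrap-around guard: if the fresh right end already
            # occurs earlier in the contig we have gone around the circle
            tail = contig[-min_overlap:]
            if contig.find(tail) != len(contig) - min_overlap:
                return contig
        return contig

    for seed_idx in range(n_unique):
        if used[seed_idx] or len(fwd_seqs[seed_idx]) < min_overlap:
            continue
        seed_seq, seed_count = fwd_seqs[seed_idx], counts[seed_idx]
        contig = extend_right(seed_seq, fwd_index, fwd_seqs)
        contig = extend_right(contig[::-1], rev_index, rev_seqs)[::-1]

        if len(contig) == len(seed_seq):
            # unextended seed: a duplicated read still counts as a 2-read contig
            used[seed_idx] = True
            if seed_count >= 2:
                contigs.append(
                    Contig(f"{sample or 'asm'}_contig{len(contigs) + 1}",
                           contig, seed_count, sample)
                )
            continue

        # assign members: exact substrings first, then lightly diverged reads
        member_count = 0
        contig_kmers: dict[str, int] = {}
        for p in range(len(contig) - min_overlap + 1):
            contig_kmers.setdefault(contig[p : p + min_overlap], p)
        kscan = 16
        contig_16 = {contig[p : p + kscan] for p in range(len(contig) - kscan + 1)}
        max_err = max(2, int(absorb_max_divergence * max_read_len))
        for idx in range(n_unique):
            if used[idx]:
                continue
            seq = fwd_seqs[idx]
            p = contig_kmers.get(seq[:min_overlap], -1)
            if p >= 0 and contig[p : p + len(seq)] == seq:
                used[idx] = True
                member_count += counts[idx]
                continue
            # tolerant absorption of erroneous copies of contig segments
            hit = any(
                seq[i : i + kscan] in contig_16
                for i in range(0, max(1, len(seq) - kscan + 1), kscan)
            )
            if hit:
                res = edlib.align(seq, contig, mode="HW", task="distance", k=max_err)
                if res["editDistance"] != -1:
                    used[idx] = True
                    member_count += counts[idx]
        if not used[seed_idx]:
            used[seed_idx] = True
            member_count += seed_count
        if member_count >= 2:
            contigs.append(
                Contig(f"{sample or 'asm'}_contig{len(contigs) + 1}",
                       contig, member_count, sample)
            )
    logger.info("assemble[%s]: %d reads -> %d contigs", sample, len(records), len(contigs))
    return contigs


def _orfs_in_frame(seq: str, frame: int, min_aa: int):
    """Yield (start, end, nt) of maximal start->stop ORFs in one frame."""
    start: int | None = None
    for pos in range(frame, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            if start is not None and pos + 3 - start >= 3 * (min_aa + 1):
                yield start, pos + 3, seq[start : pos + 3]
            start = None
        elif start is None and codon in START_CODONS:
            start = pos


def extract_cds(
    contigs: list[Contig], min_aa: int = 100
) -> list[CandidateCds]:
    """Six-frame scan for maximal start->stop ORFs of >= ``min_aa`` residues.

    Start codons follow translation table 11 (ATG/GTG/TTG, translated as M);
    the emitted nucleotide sequence includes the stop codon.
    """
    out: list[CandidateCds] = []
    for contig in contigs:
        n = 0
        for strand, seq in (("+", contig.seq), ("-", revcomp(contig.seq))):
            for frame in range(3):
                for start, end, nt in _orfs_in_frame(seq, frame, min_aa):
                    aa = str(Seq(nt[:-3]).translate(table=11))
                    aa = "M" + aa[1:]  # table 11 alternative starts
                    n += 1
                    out.append(
                        CandidateCds(
                            id=f"{contig.id}|cds{n}",
                            nt_seq=nt,
                            aa_seq=aa,
                            contig_id=contig.id,
                            sample=contig.sample,
                            abundance=float(contig.member_reads),
                            strand=strand,
                        )
                    )
    logger.info("extract_cds: %d contigs -> %d candidate ORFs", len(contigs), len(out))
    return out


def search_cummo(
    cds_list: list[CandidateCds],
    db: ReferenceDB,
    min_id: float = 60.0,
    min_qcov: float = 50.0,
    min_scov: float = 50.0,
    len_window: tuple[int, int] = (400, 1000),
) -> list[CandidateCds]:
    """Protein-level homology filter against the reference database.

    Keeps a CDS only when its best local alignment reaches ``min_id``%
    identity with both query and subject coverage >= 50%, then applies the
    nucleotide length window (the printed 400-1000 bp criterion).
    """
    ref_aa = []
    for rec in db.records:
        nt = rec.seq[: len(rec.seq) - len(rec.seq) % 3]
        ref_aa.append((rec.id, str(Seq(nt).translate(table=11)).rstrip("*"), rec.meta))
    kept: list[CandidateCds] = []
    for cds in cds_list:
        best = None
        for ref_id, aa, meta in ref_aa:
            identity, qcov, scov = aa_local_identity(cds.aa_seq, aa)
            if best is None or identity > best["identity"]:
                best = {"ref_id": ref_id, "identity": identity, "query_cov": qcov,
                        "subject_cov": scov, "ref_meta": meta}
        if best is None or best["identity"] < min_id:
            continue
        if best["query_cov"] < min_qcov or best["subject_cov"] < min_scov:
            continue
        lo, hi = len_window
        if not (lo <= len(cds.nt_seq) <= hi):
            continue
        cds.hit = best
        kept.append(cds)
    logger.info("search_cummo: %d -> %d CDSs", len(cds_list), len(kept))
    return kept


@dataclass
class _MatchProfile:
    """Per-query-position match indicator against one reference sequence."""

    matches: np.ndarray  # bool, length = len(query)

    @property
    def identity(self) -> float:
        return float(self.matches.mean()) if len(self.matches) else 0.0


def _match_profile(query: str, ref: str, aligner: PairwiseAligner) -> _MatchProfile:
    matches = np.zeros(len(query), dtype=bool)
    alignments = aligner.align(ref, query)
    aln = next(iter(alignments), None)
    if aln is not None:
        for (t0, t1), (q0, q1) in zip(aln.aligned[0], aln.aligned[1]):
            for dt in range(t1 - t0):
                if ref[t0 + dt] == query[q0 + dt] and query[q0 + dt] != "N":
                    matches[q0 + dt] = True
    return _MatchProfile(matches)


def remove_chimeras(
    records: list[SeqRecord],
    abundance: list[float] | dict[str, float],
    delta: float = 1.5,
    min_segment: int = 16,
    min_segment_identity: float = 0.80,
) -> tuple[list[SeqRecord], list[str]]:
    """Two-parent chimera detection with a strict improvement margin.

    For each query (ascending abundance) a crossover model is sought among
    strictly more abundant sequences: a split position where the left-segment
    identity to parent A and the right-segment identity to parent B each
    exceed the query's best single-sequence identity by >= ``delta``
    percentage points, and each reach ``min_segment_identity`` in absolute
    terms. Flagged queries are removed. The margin plus the absolute floor
    keep false positives down (real crossover segments match their parent
    near-perfectly; segment-level identity fluctuations between mutually
    unrelated sequences never reach the floor), and a pure sequence can never
    beat its own best single match by the margin.
    """
    if isinstance(abundance, dict):
        ab = [abundance[rec.id] for rec in records]
    else:
        ab = list(abundance)
    if len(ab) != len(records):
        raise ValueError("abundance length mismatch")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    order = sorted(range(len(records)), key=lambda i: (ab[i], records[i].id))
    flagged: set[str] = set()
    delta_f = delta / 100.0
    for qi in order:
        query = records[qi]
        parents = [
            (pi, records[pi]) for pi in range(len(records))
            if ab[pi] > ab[qi] and records[pi].id not in flagged
        ]
        if len(parents) < 2 or len(query.seq) < 2 * min_segment:
            continue
        profiles = {pi: _match_profile(query.seq, p.seq, aligner) for pi, p in parents}
        best_single = max(prof.identity for prof in profiles.values())
        n = len(query.seq)
        cums = {pi: np.concatenate([[0], np.cumsum(prof.matches)]) for pi, prof in profiles.items()}
        found = False
        for ai, _ in parents:
            if found:
                break
            for bi, _ in parents:
                if ai == bi:
                    continue
                ca, cb = cums[ai], cums[bi]
                xs = np.arange(min_segment, n - min_segment + 1)
                left = ca[xs] / xs
                right = (cb[n] - cb[xs]) / (n - xs)
                floor = max(best_single + delta_f, min_segment_identity)
                ok = (left >= floor) & (right >= floor)
                if ok.any():
                    found = True
                    break
        if found:
            flagged.add(query.id)
    kept = [rec for rec in records if rec.id not in flagged]
    logger.info("remove_chimeras: %d -> %d (flagged %d)", len(records), len(kept), len(flagged))
    return kept, sorted(flagged)


def cluster_otus(
    seqs: list[CandidateCds],
    identity: float = 0.97,
    coverage: float = 0.50,
    discard_singletons: bool = True,
) -> list[Otu]:
    """Greedy centroid clustering of pooled candidate CDSs.

    Sequences are processed by decreasing abundance (ties: length descending,
    then id ascending); each joins the first centroid it matches at
    >= ``identity`` over >= ``coverage`` of the shorter sequence, else founds
    a new centroid. Clusters of size 1 are dropped when
    ``discard_singletons``. Identity is measured by aligning the shorter
    sequence as an infix of the longer (coverage of the shorter is then
    complete, which satisfies the coverage floor).
    """
    order = sorted(seqs, key=lambda c: (-c.abundance, -len(c.nt_seq), c.id))
    centroids: list[Otu] = []
    for cds in order:
        placed = False
        for otu in centroids:
            short, long = sorted((cds.nt_seq, otu.representative), key=len)
            max_dist = int(len(short) * (1.0 - identity))
            res = edlib.align(short, long, mode="HW", task="distance", k=max_dist)
            if res["editDistance"] != -1:
                otu.members.append(cds.id)
                otu.member_count += 1
                otu.total_abundance += cds.abundance
                placed = True
                break
        if not placed:
            centroids.append(
                Otu(
                    otu_id=f"OTU_{len(centroids) + 1}",
                    representative=cds.nt_seq,
                    rep_id=cds.id,
                    members=[cds.id],
                    member_count=1,
                    total_abundance=cds.abundance,
                )
            )
    if discard_singletons:
        centroids = [o for o in centroids if o.member_count >= 2]
    for i, otu in enumerate(centroids, start=1):
        otu.otu_id = f"OTU_{i}"
    logger.info("cluster_otus: %d seqs -> %d OTUs", len(seqs), len(centroids))
    return centroids
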