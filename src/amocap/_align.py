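"""Internal alignment helpers shared by curation, pipeline and quantification.

Nucleotide identities are computed with edlib (edit distance); protein local
alignments use Biopython's PairwiseAligner with BLOSUM62. Conventions:

- ``global_identity``: Needleman-Wunsch identity, 1 - dist / max(len).
- ``infix_identity``: the whole shorter sequence aligned inside the longer
  (edlib HW mode); coverage of the shorter sequence is 1 by construction.
- ``nt_local_identity``: best Smith-Waterman local alignment; returns identity
  over the aligned columns and the aligned fraction of the shorter sequence.
"""

from __future__ import annotations

from functools import lru_cache

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

from .io_core import revcomp


def shares_kmer(a: str, b: str, k: int = 12, both_strands: bool = True) -> bool:
    """Fast prescreen: do the two sequences share any exact k-mer?"""
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    for probe in (b, revcomp(b)) if both_strands else (b,):
        if any(probe[i : i + k] in kmers for i in range(len(probe) - k + 1)):
            return True
    return False


def global_identity(a: str, b: str) -> float:
    """Needleman-Wunsch identity between two nucleotide strings."""
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def infix_identity(short: str, long: str) -> float:
    """Identity of the shorter sequence aligned as an infix of the longer.

    End gaps on the longer sequence are free, so this measures how well the
    shorter sequence is contained in the longer one.
    """
    if not short or not long:
        return 0.0
    if len(short) > len(long):
        short, long = long, short
    dist = edlib.align(short, long, mode="HW", task="distance")["editDistance"]
    return 1.0 - dist / len(short)


def best_strand_infix_identity(short: str, long: str) -> float:
    return max(infix_identity(short, long), infix_identity(revcomp(short), long))


@lru_cache(maxsize=4)
def _nt_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    # megablast-like scoring
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


@lru_cache(maxsize=4)
def _aa_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, int, int]:
    """(matches, aligned_columns, query_span, subject_span) of one alignment."""
    matches = 0
    columns = 0
    q_span = 0
    s_span = 0
    qseq, sseq = alignment.query, alignment.target
    # Biopython convention: target is the first sequence passed to align().
    for (t0, t1), (q0, q1) in zip(alignment.aligned[0], alignment.aligned[1]):
        block_t = sseq[t0:t1]
        block_q = qseq[q0:q1]
        matches += sum(x == y for x, y in zip(block_t, block_q))
        columns += t1 - t0
        q_span += q1 - q0
        s_span += t1 - t0
    return matches, columns, q_span, s_span


def nt_local_identity(a: str, b: str, both_strands: bool = True) -> tuple[float, float]:
    """Best local-alignment (identity, coverage-of-shorter) between two nt strings.

    Gap columns are excluded from the identity denominator; coverage is the
    aligned span of the shorter sequence divided by its length.
    """
    if not a or not b:
        return 0.0, 0.0
    aligner = _nt_local_aligner()
    best = (0.0, 0.0)
    for query in (a, revcomp(a)) if both_strands else (a,):
        alignments = aligner.align(b, query)
        aln = next(iter(alignments), None)
        if aln is None or alignments.score <= 0:
            continue
        matches, columns, q_span, s_span = _alignment_stats(aln)
        if columns == 0:
            continue
        identity = matches / columns
        coverage = min(q_span, s_span) / min(len(a), len(b))
        if (identity * coverage, identity) > (best[0] * best[1], best[0]):
            best = (identity, coverage)
    return best


def aa_local_identity(query: str, subject: str) -> tuple[float, float, float]:
    """Protein local alignment: (identity%, query coverage%, subject coverage%)."""
    query = query.rstrip("*")
    subject = subject.rstrip("*")
    if not query or not subject:
        return 0.0, 0.0, 0.0
    aligner = _aa_local_aligner()
    alignments = aligner.align(subject, query)
    aln = next(iter(alignments), None)
    if aln is None or alignments.score <= 0:
        return 0.0, 0.0, 0.0
    matches, columns, q_span, s_span = _alignment_stats(aln)
    if columns == 0:
        return 0.0, 0.0, 0.0
    return (
        100.0 * matches / columns,
        100.0 * q_span / len(query),
        100.0 * s_span / len(subject),
    )
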