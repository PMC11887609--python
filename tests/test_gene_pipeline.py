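"""QC, pair merging, greedy assembly, ORF extraction, homology filtering,
chimera removal and OTU clustering, with brute-force oracles where feasible."""

import itertools

import numpy as np
import pytest
from Bio import Align

from amocap.capture_sim import Fragment, ReadSet, sequence_paired
from amocap.gene_pipeline import (
    CandidateCds,
    Contig,
    QcParams,
    assemble,
    cluster_otus,
    dust_score,
    extract_cds,
    merge_pairs,
    qc_hifi,
    qc_short_reads,
    remove_chimeras,
    search_cummo,
)
from amocap.io_core import SeqRecord, revcomp, rng as make_rng
from amocap.mock_synth import STOP_GUARD
from amocap.refdb import ReferenceDB

from conftest import random_dna


def paired(reads1, reads2):
    return ReadSet(layout="paired", reads=reads1, mates=reads2)


def q(n, score=30):
    return [score] * n


class TestQcShortReads:
    def test_low_quality_tail_trimmed(self, rng):
        seq = random_dna(150, rng)
        rec = SeqRecord("r", seq, qual=q(140) + [10] * 10)
        mate = SeqRecord("r", seq, qual=q(150))
        out = qc_short_reads(paired([rec], [mate]))
        assert out.reads[0].seq == seq[:140]
        assert out.mates[0].seq == seq

    def test_reads_below_min_length_dropped_with_mate(self, rng):
        short = SeqRecord("r", random_dna(120, rng), qual=q(99) + [5] * 21)
        mate = SeqRecord("r", random_dna(150, rng), qual=q(150))
        out = qc_short_reads(paired([short], [mate]))
        assert len(out.reads) == 0  # 99 nt after trim -> pair dropped

    def test_low_complexity_read_dropped(self):
        polya = SeqRecord("r", "A" * 150, qual=q(150))
        mate = SeqRecord("r", random_dna(150, make_rng(1, "qc")), qual=q(150))
        # the declared triplet statistic scores a homopolymer at 100
        assert dust_score(polya.seq) == pytest.approx(100.0)
        assert dust_score(mate.seq) < 7.0
        out = qc_short_reads(paired([polya], [mate]))
        assert len(out.reads) == 0

    def test_dust_statistic_matches_declared_formula(self, rng):
        # independent recomputation of the triplet pair-count statistic
        for seq in (random_dna(80, rng), "ACAC" * 30, "A" * 60):
            counts = {}
            for i in range(len(seq) - 2):
                counts[seq[i : i + 3]] = counts.get(seq[i : i + 3], 0) + 1
            pairs = sum(c * (c - 1) / 2 for c in counts.values())
            expected = 100.0 * pairs / ((len(seq) - 2) * (len(seq) - 3) / 2)
            assert dust_score(seq) == pytest.approx(expected)


class TestQcHifi:
    @pytest.mark.parametrize(
        "length, survives, out_len",
        [(675, True, 635), (399, False, None), (1001, False, None), (400, True, 360)],
    )
    def test_length_filter_then_end_trim(self, rng, length, survives, out_len):
        rec = SeqRecord("r", random_dna(length, rng), qual=q(length, 35))
        out = qc_hifi(ReadSet(layout="single", reads=[rec]))
        if survives:
            assert len(out.reads) == 1
            assert len(out.reads[0].seq) == out_len
            assert out.reads[0].seq == rec.seq[20:-20]
        else:
            assert len(out.reads) == 0


class TestMergePairs:
    def test_fully_overlapping_pair_reconstructs_fragment(self, rng):
        frag = Fragment("c", 0, 200, random_dna(200, rng), False, False, None)
        rs = sequence_paired([frag], error_rate=0.0, rng=rng)
        merged, unmerged = merge_pairs(rs)
        assert len(unmerged.reads) == 0
        assert merged.reads[0].seq == frag.seq

    def test_partial_overlap_merges_to_fragment_length(self, rng):
        frag = Fragment("c", 0, 550, random_dna(550, rng), False, False, None)
        rs = sequence_paired([frag], read_len=300, error_rate=0.0, rng=rng)
        merged, unmerged = merge_pairs(rs)
        assert len(merged.reads) == 1
        assert merged.reads[0].seq == frag.seq  # 50 nt overlap, zero errors

    def test_disjoint_mates_flagged_unmerged(self, rng):
        r1 = SeqRecord("p", random_dna(150, rng), qual=q(150))
        r2 = SeqRecord("p", random_dna(150, rng), qual=q(150))
        merged, unmerged = merge_pairs(paired([r1], [r2]))
        assert len(merged.reads) == 0
        assert unmerged.reads[0].meta["merge_failed"] == "1"

    def test_consensus_takes_higher_quality_base(self, rng):
        seq = random_dna(100, rng)
        fwd = SeqRecord("p", seq, qual=q(100, 20))
        mutated = list(seq)
        mutated[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[50]]
        rev = SeqRecord("p", revcomp("".join(mutated)), qual=q(100, 38))
        merged, _ = merge_pairs(paired([fwd], [rev]))
        assert merged.reads[0].seq[50] == mutated[50]


def tiled_reads(template: str, read_len=200, step=10):
    reads = []
    for start in range(0, len(template) - read_len + 1, step):
        reads.append(template[start : start + read_len])
    if (len(template) - read_len) % step:
        reads.append(template[-read_len:])
    return reads


class TestAssemble:
    def test_error_free_tiling_reconstructs_gene(self, gene_family):
        gene = gene_family[0].seq  # 654 nt
        seqs = tiled_reads(gene) * 2  # ~20x with every column supported twice
        records = [SeqRecord(f"r{i}", s) for i, s in enumerate(seqs)]
        contigs = assemble(records, sample="t")
        assert len(contigs) == 1
        assert contigs[0].seq == gene
        assert contigs[0].member_reads == len(records)

    def test_unrelated_genes_yield_separate_contigs(self, gene_family):
        g1, g2 = gene_family[0].seq, gene_family[1].seq
        shared = {g1[i : i + 30] for i in range(len(g1) - 29)}
        assert not any(g2[i : i + 30] in shared for i in range(len(g2) - 29))
        seqs = (tiled_reads(g1) + tiled_reads(g2)) * 2
        records = [SeqRecord(f"r{i}", s) for i, s in enumerate(seqs)]
        contigs = assemble(records, sample="t")
        assert sorted(c.seq for c in contigs) == sorted([g1, g2])

    def test_empty_input(self):
        assert assemble([]) == []

    def test_sequencing_errors_outvoted_by_consensus(self, gene_family, rng):
        gene = gene_family[2].seq
        seqs = tiled_reads(gene, step=5) * 3
        noisy = []
        for i, s in enumerate(seqs):
            if i % 7 == 0:  # sprinkle substitution errors on some reads
                pos = int(rng.integers(len(s)))
                s = s[:pos] + {"A": "C", "C": "G", "G": "T", "T": "A"}[s[pos]] + s[pos + 1 :]
            noisy.append(SeqRecord(f"r{i}", s))
        contigs = assemble(noisy, sample="t")
        assert contigs[0].seq == gene


class TestExtractCds:
    def test_clean_orf_recovered_exactly(self, gene_family, rng):
        gene = gene_family[0].seq
        contig = Contig("c1", STOP_GUARD + gene + STOP_GUARD, 10, "s")
        cds = extract_cds([contig])
        forward = [c for c in cds if c.strand == "+"]
        assert any(c.nt_seq == gene for c in forward)
        match = next(c for c in forward if c.nt_seq == gene)
        assert match.aa_seq[0] == "M" and "*" not in match.aa_seq
        assert len(match.aa_seq) == len(gene) // 3 - 1

    def test_internal_stop_splits_orf(self, gene_family):
        gene = gene_family[0].seq  # 654 nt = 218 codons
        broken = gene[:327] + "TAA" + gene[330:]
        contig = Contig("c1", STOP_GUARD + broken + STOP_GUARD, 5, "s")
        cds = extract_cds([contig], min_aa=100)
        assert not any(c.nt_seq == broken for c in cds)
        # both halves are ~108 codons, just over the 100 aa floor
        halves = [c for c in cds if c.strand == "+" and len(c.nt_seq) <= 340]
        assert halves

    def test_reverse_strand_orf_annotated(self, gene_family):
        gene = gene_family[1].seq
        contig = Contig("c1", revcomp(STOP_GUARD + gene + STOP_GUARD), 5, "s")
        cds = extract_cds([contig])
        hit = next(c for c in cds if c.nt_seq == gene)
        assert hit.strand == "-"


@pytest.fixture(scope="module")
def mock_refdb(gene_family):
    return ReferenceDB.build(list(gene_family))


def make_cds(seq: str, cds_id="c1", abundance=1.0):
    from Bio.Seq import Seq

    aa = "M" + str(Seq(seq[: len(seq) - len(seq) % 3][:-3]).translate(table=11))[1:]
    return CandidateCds(cds_id, seq, aa, "contig", abundance=abundance)


class TestSearchCummo:
    def test_identical_cds_kept_at_full_identity(self, gene_family, mock_refdb):
        cds = make_cds(gene_family[0].seq)
        kept = search_cummo([cds], mock_refdb)
        assert kept and kept[0].hit["identity"] == pytest.approx(100.0)
        assert kept[0].hit["ref_id"] == "gene1"

    def test_unrelated_cds_dropped(self, mock_refdb, rng):
        # a random ORF-like sequence: far below the 60% identity floor
        junk = "ATG" + random_dna(651, rng)
        kept = search_cummo([make_cds(junk)], mock_refdb)
        assert kept == []

    def test_length_window_excludes_short_perfect_hit(self, gene_family, mock_refdb):
        short = gene_family[0].seq[:399]
        kept = search_cummo([make_cds(short)], mock_refdb)
        assert kept == []

    def test_length_window_excludes_long_cds(self, gene_family, mock_refdb):
        long_seq = gene_family[0].seq + gene_family[0].seq[-348:]
        kept = search_cummo([make_cds(long_seq)], mock_refdb)
        assert kept == []


def point_mutate(seq, n, rng):
    out = list(seq)
    for p in rng.choice(len(seq), size=n, replace=False):
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestRemoveChimeras:
    def test_half_half_join_of_divergent_parents_flagged(self, rng):
        a = random_dna(600, rng)
        b = point_mutate(a, 120, rng)  # parents at 80% identity
        chimera = a[:300] + b[300:]
        records = [SeqRecord("A", a), SeqRecord("B", b), SeqRecord("Q", chimera)]
        kept, flagged = remove_chimeras(records, [10.0, 10.0, 1.0])
        assert flagged == ["Q"]
        assert {r.id for r in kept} == {"A", "B"}

    def test_pure_parents_never_flagged(self, rng):
        a = random_dna(600, rng)
        b = point_mutate(a, 120, rng)
        kept, flagged = remove_chimeras(
            [SeqRecord("A", a), SeqRecord("B", b)], [10.0, 5.0]
        )
        assert flagged == []

    def test_join_of_near_identical_parents_not_flagged(self, rng):
        a = random_dna(600, rng)
        b = point_mutate(a, 6, rng)  # 99% identical parents: signal below delta
        chimera = a[:300] + b[300:]
        records = [SeqRecord("A", a), SeqRecord("B", b), SeqRecord("Q", chimera)]
        kept, flagged = remove_chimeras(records, [10.0, 10.0, 1.0])
        assert flagged == []

    def test_no_false_positives_on_chimera_free_inputs(self, gene_family):
        # repeated audits over chimera-free pools of mutually unrelated genes
        for run in range(20):
            rng = make_rng(run, "chimera-audit")
            records = [
                SeqRecord(g.id, point_mutate(g.seq, int(rng.integers(0, 4)), rng))
                for g in gene_family
            ]
            abundances = list(rng.integers(1, 1000, size=len(records)).astype(float))
            _, flagged = remove_chimeras(records, abundances)
            assert flagged == []


def brute_force_min_clusters(seqs, identity=0.97):
    """Oracle: minimum number of centroid-consistent clusters by exhaustive
    partition search, with identities from an independent aligner."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -0.5

    def ident(a, b):
        aln = next(iter(aligner.align(a, b)))
        matches = sum(
            sum(x == y for x, y in zip(a[t0:t1], b[q0:q1]))
            for (t0, t1), (q0, q1) in zip(aln.aligned[0], aln.aligned[1])
        )
        return matches / min(len(a), len(b))

    n = len(seqs)
    best = n
    # enumerate set partitions via assignment vectors
    for assignment in itertools.product(range(n), repeat=n):
        labels = sorted(set(assignment))
        if labels != list(range(len(labels))):
            continue
        ok = True
        for lab in labels:
            members = [seqs[i] for i in range(n) if assignment[i] == lab]
            if not any(
                all(ident(c, m) >= identity for m in members) for c in members
            ):
                ok = False
                break
        if ok:
            best = min(best, len(labels))
    return best


class TestClusterOtus:
    def test_identical_pair_forms_single_otu(self, rng):
        seq = random_dna(500, rng)
        cds = [make_cds(seq, f"c{i}", abundance=2.0) for i in range(2)]
        otus = cluster_otus(cds)
        assert len(otus) == 1
        assert otus[0].member_count == 2
        assert otus[0].representative == seq

    def test_singleton_discarded(self, rng):
        otus = cluster_otus([make_cds(random_dna(500, rng))])
        assert otus == []

    def test_two_family_instance_matches_brute_force(self, rng):
        a = random_dna(400, rng)
        a_prime = point_mutate(a, 8, rng)  # 98% to a
        b = random_dna(400, rng)  # far from both
        seqs = [a, a_prime, b]
        assert brute_force_min_clusters(seqs) == 2
        cds = []
        for i, s in enumerate([a, a, a_prime, a_prime, b, b]):
            cds.append(make_cds(s, f"c{i}", abundance=6.0 - i))
        otus = cluster_otus(cds)
        assert len(otus) == 2
        assert {o.member_count for o in otus} == {4, 2}

    def test_representatives_mutually_dissimilar(self, gene_family):
        cds = []
        for i, g in enumerate(gene_family):
            cds.append(make_cds(g.seq, f"c{i}a", abundance=10.0))
            cds.append(make_cds(g.seq, f"c{i}b", abundance=9.0))
        otus = cluster_otus(cds)
        assert len(otus) == len(gene_family)
        import edlib

        for i in range(len(otus)):
            for j in range(i + 1, len(otus)):
                short, long = sorted(
                    (otus[i].representative, otus[j].representative), key=len
                )
                dist = edlib.align(short, long, mode="HW", task="distance")["editDistance"]
                assert 1 - dist / len(short) < 0.97

    def test_truncated_copy_joins_full_length_centroid(self, rng):
        full = random_dna(700, rng)
        truncated = full[:420]
        cds = [
            make_cds(full, "full_a", abundance=10.0),
            make_cds(full, "full_b", abundance=9.0),
            make_cds(truncated, "part", abundance=1.0),
        ]
        otus = cluster_otus(cds)
        assert len(otus) == 1
        assert otus[0].member_count == 3
        assert otus[0].representative == full
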