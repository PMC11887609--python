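"""Fragmentation, size selection, hybridisation capture, LM-PCR and
sequencing simulation, checked against closed forms and truth tags."""

import numpy as np
import pytest
from scipy import stats

from amocap.capture_sim import (
    CaptureModel,
    FRANCIS_PRIMERS,
    Fragment,
    PcrModel,
    _best_primer_site,
    fragment_community,
    sample_by_multiplicity,
    sequence_paired,
    simulate_amplicon,
    simulate_capture,
    simulate_pcr,
    size_select,
)
from amocap.io_core import SeqRecord, revcomp, rng as make_rng
from amocap.mock_synth import (
    CommunitySpec,
    PlasmidConstruct,
    expected_contained_fraction,
    expected_insert_fraction,
    plant_primer_sites,
)
from amocap.probe_design import tile_probes

from conftest import random_dna


class TestFragmentation:
    def test_determinism(self, mock_community):
        a = fragment_community(mock_community, 500, rng=make_rng(3, "f"))
        b = fragment_community(mock_community, 500, rng=make_rng(3, "f"))
        assert [(f.source_id, f.start, f.length) for f in a] == [
            (f.source_id, f.start, f.length) for f in b
        ]

    def test_insertless_construct_all_off_target(self, rng):
        construct = PlasmidConstruct("v", random_dna(2786, rng))
        spec = CommunitySpec([(construct, 1.0)])
        frags = fragment_community(spec, 300, rng=rng)
        assert all(not f.on_target and not f.contained for f in frags)

    def test_sequence_is_circular_substring(self, mock_community, rng):
        frags = fragment_community(mock_community, 200, rng=rng)
        constructs = {c.construct_id: c for c in mock_community.constructs()}
        for f in frags:
            assert f.seq == constructs[f.source_id].circular_substring(f.start, f.length)

    def test_monte_carlo_matches_closed_forms(self, mock_community):
        n = 200_000
        frags = fragment_community(
            mock_community, n, frag_len_sd=0.0, rng=make_rng(9, "mc"), with_seq=False
        )
        contained = np.mean([f.contained for f in frags])
        on_target = np.mean([f.on_target for f in frags])
        p_contained = expected_contained_fraction(mock_community, 200)
        se = np.sqrt(p_contained * (1 - p_contained) / n)
        assert abs(contained - p_contained) <= 3 * se
        p_overlap = sum(
            (2.0 / 6.0) * (c.insert_len + 199) for c in mock_community.constructs()
        ) / sum((2.0 / 6.0) * c.total_len for c in mock_community.constructs())
        se2 = np.sqrt(p_overlap * (1 - p_overlap) / n)
        assert abs(on_target - p_overlap) <= 3 * se2

    def test_fragment_longer_than_construct_rejected(self, mock_community):
        with pytest.raises(ValueError):
            fragment_community(mock_community, 10, frag_len_mean=5000)


class TestSizeSelect:
    def test_threshold_is_inclusive(self):
        frags = [
            Fragment("c", 0, n, "A" * n, False, False, None) for n in (140, 150, 160)
        ]
        kept = size_select(frags, min_len=150)
        assert [f.length for f in kept] == [150, 160]

    def test_all_long_unchanged(self):
        frags = [Fragment("c", 0, n, "A" * n, False, False, None) for n in (150, 300)]
        assert size_select(frags) == frags

    def test_removal_fraction_matches_normal_tail(self, mock_community):
        n = 10_000
        frags = fragment_community(
            mock_community, n, frag_len_mean=200, frag_len_sd=30,
            rng=make_rng(4, "sz"), with_seq=False,
        )
        removed = 1 - len(size_select(frags, 150)) / n
        # lengths are rounded to integers, so the tail is P(X < 149.5)
        p = stats.norm.cdf(149.5, loc=200, scale=30)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(removed - p) <= 3 * se


@pytest.fixture(scope="module")
def mock_probes(gene_family):
    return tile_probes(gene_family, probe_len=100, stride=50)


class TestCapture:
    def test_zero_overlap_fragment_dropped_at_zero_nonspecific(self, mock_probes, rng):
        frag = Fragment("x", 0, 200, random_dna(200, rng), False, False, None)
        model = CaptureModel(nonspecific_rate=0.0)
        assert simulate_capture([frag], mock_probes, model, rng) == []

    def test_probe_containing_fragment_always_retained(self, gene_family, mock_probes, rng):
        gene = gene_family[0].seq
        frag = Fragment("g", 0, 200, gene[:200], True, True, "gene1")
        model = CaptureModel(nonspecific_rate=0.0)
        assert simulate_capture([frag], mock_probes, model, rng) == [frag]

    def test_rounds_zero_is_passthrough(self, mock_probes, rng):
        frags = [Fragment("x", 0, 200, random_dna(200, rng), False, False, None)]
        model = CaptureModel(rounds=0)
        assert simulate_capture(frags, mock_probes, model, rng) == frags

    def test_specificity_audit(self, mock_community, mock_probes):
        # with nonspecific_rate = 0 every retained fragment truly overlaps an
        # insert (probes tile only the inserted genes)
        frags = fragment_community(mock_community, 5_000, rng=make_rng(5, "cap"))
        model = CaptureModel(nonspecific_rate=0.0)
        retained = simulate_capture(frags, mock_probes, model, make_rng(5, "cap2"))
        assert retained
        assert all(f.on_target for f in retained)

    def test_enrichment_to_high_on_target_fraction(self, mock_community, mock_probes):
        frags = fragment_community(mock_community, 20_000, rng=make_rng(6, "cap"))
        pre = np.mean([f.on_target for f in frags])
        model = CaptureModel(nonspecific_rate=1e-4)
        post_frags = simulate_capture(frags, mock_probes, model, make_rng(6, "cap2"))
        post = np.mean([f.on_target for f in post_frags])
        assert pre == pytest.approx(0.27, abs=0.02)
        assert post > 0.99

    def test_monotonic_in_rounds_and_nonspecific_rate(self, mock_community, mock_probes):
        frags = fragment_community(mock_community, 4_000, rng=make_rng(7, "cap"))
        fractions = []
        for rounds in (1, 2):
            model = CaptureModel(nonspecific_rate=0.02, rounds=rounds)
            out = simulate_capture(frags, mock_probes, model, make_rng(7, f"r{rounds}"))
            fractions.append(np.mean([f.on_target for f in out]))
        assert fractions[1] >= fractions[0]
        by_rate = []
        for rate in (0.0, 0.05, 0.5):
            model = CaptureModel(nonspecific_rate=rate, rounds=1)
            out = simulate_capture(frags, mock_probes, model, make_rng(7, f"n{rate}"))
            by_rate.append(np.mean([f.on_target for f in out]))
        assert by_rate[0] >= by_rate[1] >= by_rate[2]


class TestPcr:
    def make_frags(self, n, rng, length=200):
        return [
            Fragment("c", 0, length, random_dna(length, rng), False, False, None)
            for _ in range(n)
        ]

    def test_zero_cycles_leaves_multiplicities(self, rng):
        frags = self.make_frags(5, rng)
        out = simulate_pcr(frags, PcrModel(cycles=0), rng)
        assert [f.multiplicity for f in out] == [1] * 5

    def test_perfect_efficiency_doubles_deterministically(self, rng):
        frags = self.make_frags(4, rng)
        out = simulate_pcr(
            frags, PcrModel(cycles=3, efficiency=1.0, chimera_rate=0.0), rng
        )
        assert [f.multiplicity for f in out] == [8] * 4

    def test_branching_process_mean(self, rng):
        n = 10_000
        frags = self.make_frags(n, rng, length=60)
        out = simulate_pcr(
            frags, PcrModel(cycles=5, efficiency=0.9, chimera_rate=0.0), rng
        )
        mult = np.array([f.multiplicity for f in out], dtype=float)
        expected = 1.9**5
        se = mult.std(ddof=1) / np.sqrt(n)
        assert abs(mult.mean() - expected) <= 3 * se

    def test_chimeras_join_at_shared_kmer(self, rng):
        base = random_dna(300, rng)
        # two templates sharing an internal 40 nt block
        a = random_dna(100, rng) + base[:40] + random_dna(100, rng)
        b = random_dna(60, rng) + base[:40] + random_dna(140, rng)
        frags = [
            Fragment("a", 0, len(a), a, False, False, None),
            Fragment("b", 0, len(b), b, False, False, None),
        ]
        out = simulate_pcr(
            frags, PcrModel(cycles=8, efficiency=1.0, chimera_rate=0.05), rng
        )
        chims = [f for f in out if f.chimera]
        assert chims
        for chim in chims:
            # every chimera splits into a prefix of one parent and a suffix of
            # the other around an exact shared k-mer
            assert chim.seq not in (a, b)
            assert any(
                chim.seq[:i] in (a[:i], b[:i]) for i in range(12, len(chim.seq))
            )


class TestSequencing:
    def test_short_fragment_gives_fully_overlapping_pair(self, rng):
        seq = random_dna(200, rng)
        frag = Fragment("c", 0, 200, seq, True, True, "g")
        rs = sequence_paired([frag], read_len=300, error_rate=0.0, rng=rng)
        assert rs.reads[0].seq == seq
        assert rs.mates[0].seq == revcomp(seq)

    def test_error_free_pair_reconstructs_fragment(self, rng):
        seq = random_dna(550, rng)
        frag = Fragment("c", 0, 550, seq, True, True, "g")
        rs = sequence_paired([frag], read_len=300, error_rate=0.0, rng=rng)
        fwd, rev = rs.reads[0].seq, revcomp(rs.mates[0].seq)
        assert fwd == seq[:300]
        assert rev == seq[250:]
        assert fwd[250:] == rev[:50]  # 50 nt agreement in the overlap

    def test_substitution_count_is_binomial(self, rng):
        seq = random_dna(250, rng)
        frags = [Fragment("c", 0, 250, seq, False, False, None)] * 2_000
        rs = sequence_paired(frags, read_len=250, error_rate=1e-3, rng=rng)
        n_bases = 2_000 * 250 * 2
        mismatches = sum(
            sum(x != y for x, y in zip(r.seq, seq)) for r in rs.reads
        ) + sum(
            sum(x != y for x, y in zip(r.seq, revcomp(seq))) for r in rs.mates
        )
        expected = n_bases * 1e-3
        se = np.sqrt(n_bases * 1e-3 * (1 - 1e-3))
        assert abs(mismatches - expected) <= 3 * se

    def test_weighted_resampling_follows_multiplicity(self, rng):
        a = Fragment("a", 0, 50, "A" * 50, False, False, None, multiplicity=90)
        b = Fragment("b", 0, 50, "C" * 50, False, False, None, multiplicity=10)
        picks = sample_by_multiplicity([a, b], 2_000, rng)
        frac_a = np.mean([f.source_id == "a" for f in picks])
        assert frac_a == pytest.approx(0.9, abs=0.03)


class TestAmplicon:
    def test_perfect_sites_give_635_product(self, gene_family, rng):
        gene = plant_primer_sites(
            gene_family[0], FRANCIS_PRIMERS.fwd, FRANCIS_PRIMERS.rev, 0, 0, seed=2
        )
        _, products = simulate_amplicon([gene], n_reads=0, rng=rng)
        assert products[0]["product_len"] == 635
        assert products[0]["mismatch_fwd"] == 0
        assert products[0]["mismatch_rev"] == 0

    def test_iupac_degeneracy_s_matches_c_and_g(self):
        # the degenerate 5' S of the forward primer accepts both C and G
        primer = FRANCIS_PRIMERS.fwd
        for first in "CG":
            template = first + primer[1:]
            site = _best_primer_site(template, primer, reverse=False)
            assert site == (0, 0)
        site = _best_primer_site("A" + primer[1:], primer, reverse=False)
        assert site[1] == 1

    def test_mismatched_templates_lose_product_share(self, gene_family, rng):
        fwd, rev = FRANCIS_PRIMERS.fwd, FRANCIS_PRIMERS.rev
        t0 = plant_primer_sites(gene_family[0], fwd, rev, 0, 0, seed=2)
        t2 = plant_primer_sites(gene_family[1], fwd, rev, 1, 1, seed=2)
        t3 = plant_primer_sites(gene_family[2], fwd, rev, 1, 2, seed=2)
        aob = gene_family[3:6]  # no planted sites: no significant primer match
        reads, products = simulate_amplicon(
            [t0, t2, t3, *aob], pcr_model=PcrModel(cycles=35), n_reads=2_000, rng=rng
        )
        shares = {p["template"]: p["share"] for p in products}
        assert shares[t0.id] >= 0.95
        for gene in aob:
            assert shares[gene.id] == 0.0
        # extra mismatches never increase the share
        assert shares[t0.id] > shares[t2.id] > shares[t3.id]

    def test_long_read_mode_emits_near_perfect_singles(self, gene_family, rng):
        gene = plant_primer_sites(
            gene_family[0], FRANCIS_PRIMERS.fwd, FRANCIS_PRIMERS.rev, 0, 0, seed=2
        )
        rs, products = simulate_amplicon(
            [gene], long_read=True, n_reads=50, hifi_error_rate=0.0, rng=rng
        )
        assert rs.layout == "single"
        assert len(rs.reads) == 50
        product_seq = gene.seq[10 : 10 + 635]
        assert all(r.seq == product_seq for r in rs.reads)
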