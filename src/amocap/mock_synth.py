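"""Synthetic mock communities: marker genes cloned into circular vectors,
molar dilution series, and their closed-form expectations.

The default mock emulates a plasmid mixture of six ammonia-monooxygenase
(amoA) inserts of 654-846 nt in a 2739 nt cloning vector, optionally diluted
with an empty 2786 nt vector, with mass-balance copies-per-ng and
fragment-containment expectations computed analytically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from ._align import global_identity
from .io_core import IUPAC_SETS, SeqRecord, rng as make_rng

logger = logging.getLogger("amocap.mock_synth")

#: mass of one base pair of dsDNA in ng (650 g/mol convention)
BP_MASS_NG = 650.0 / 6.022e23 * 1e9

#: default insert lengths, mean 750 nt, all codon multiples
DEFAULT_INSERT_LENS = (654, 702, 738, 768, 792, 846)

#: stop codons in every frame and on both strands; placed at the cloning
#: junction so a maximal-ORF scan terminates exactly at the insert boundary
STOP_GUARD = "TTAATTAATTAA"

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"


@dataclass
class PlasmidConstruct:
    """A circular cloning vector, optionally carrying one insert.

    The construct sequence is vector followed by insert, so insert coordinates
    are [vector_len, total_len) before circular wrap.
    """

    construct_id: str
    vector_seq: str
    insert: SeqRecord | None = None
    circular: bool = True

    @property
    def vector_len(self) -> int:
        return len(self.vector_seq)

    @property
    def insert_len(self) -> int:
        return len(self.insert.seq) if self.insert else 0

    @property
    def total_len(self) -> int:
        return self.vector_len + self.insert_len

    @property
    def seq(self) -> str:
        return self.vector_seq + (self.insert.seq if self.insert else "")

    def circular_substring(self, start: int, length: int) -> str:
        """Substring wrapping modulo construct length (0-based start)."""
        s = self.seq
        start %= len(s)
        end = start + length
        if end <= len(s):
            return s[start:end]
        return s[start:] + s[: end - len(s)]


@dataclass
class CommunitySpec:
    """Plasmid constructs with (unnormalised) molar ratios."""

    members: list[tuple[PlasmidConstruct, float]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("community must have at least one member")
        if any(ratio <= 0 for _, ratio in self.members):
            raise ValueError("molar ratios must be positive")

    def constructs(self) -> list[PlasmidConstruct]:
        return [c for c, _ in self.members]


@dataclass
class GeneFamilyParams:
    """Controls the synthetic marker-gene family standing in for cloned genes.

    Generated genes are clean ORFs (start codon, stop codon, no internal stop)
    whose pairwise global identities stay below ``pairwise_identity_target`` so
    that each founds its own OTU at the 97% clustering threshold.
    """

    n_genes: int = 6
    lengths: Sequence[int] | None = DEFAULT_INSERT_LENS
    length_range: tuple[int, int] = (400, 1000)
    pairwise_identity_target: float = 0.85
    seed: int = 0
    max_retries: int = 50


def _random_orf(length: int, rng: np.random.Generator) -> str:
    if length % 3 != 0 or length < 9:
        raise ValueError(f"gene length must be a codon multiple >= 9, got {length}")
    n_codons = length // 3 - 2
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list(_BASES), size=3))
        if codon not in _STOPS and codon != "ATG":
            codons.append(codon)
    stop = _STOPS[rng.integers(0, len(_STOPS))]
    return "ATG" + "".join(codons) + stop


def generate_gene_family(params: GeneFamilyParams) -> list[SeqRecord]:
    """Generate ``n_genes`` mutually diverged clean-ORF marker genes.

    Lengths come from ``params.lengths`` (cycled) or are drawn from
    ``length_range`` rounded to codon multiples. Identity constraints are
    verified by global alignment; a gene failing against an earlier one is
    redrawn up to ``max_retries`` times.
    """
    if not (400 <= min(params.length_range) and max(params.length_range) <= 1000):
        raise ValueError("length_range must lie within [400, 1000]")
    rng = make_rng(params.seed, "gene_family")
    genes: list[SeqRecord] = []
    for i in range(params.n_genes):
        if params.lengths is not None:
            length = params.lengths[i % len(params.lengths)]
        else:
            lo, hi = params.length_range
            length = 3 * int(rng.integers(lo // 3 + 1, hi // 3 + 1))
        for attempt in range(params.max_retries):
            seq = _random_orf(length, rng)
            if all(
                global_identity(seq, g.seq) <= params.pairwise_identity_target for g in genes
            ):
                genes.append(SeqRecord(f"gene{i + 1}", seq, meta={"length": str(length)}))
                break
        else:
            raise RuntimeError(
                f"could not reach pairwise identity <= {params.pairwise_identity_target} "
                f"after {params.max_retries} retries"
            )
    return genes


def random_vector(length: int, rng: np.random.Generator, guarded: bool = True) -> str:
    """Random vector backbone; when guarded, both ends carry stop codons in all
    frames (mimicking the translational-stop context of a multiple cloning
    site) so insert ORFs terminate exactly at the cloning junction."""
    core = "".join(rng.choice(list(_BASES), size=length))
    if not guarded:
        return core
    if length < 2 * len(STOP_GUARD):
        raise ValueError("vector too short for junction guards")
    return STOP_GUARD + core[len(STOP_GUARD) : length - len(STOP_GUARD)] + STOP_GUARD


def build_mock(
    genes: Sequence[SeqRecord],
    vector_len: int = 2739,
    diluent_len: int = 2786,
    dilution_ratio: float = 0.0,
    seed: int = 0,
) -> CommunitySpec:
    """Assemble the mock community: one construct per gene at equal molar ratio
    (2 parts in total, matching a 2:x dilution notation) plus, when
    ``dilution_ratio`` > 0, an empty diluent vector at that ratio.

    ``dilution_ratio=0`` reproduces the undiluted mock; 1000 the 2:1000 series
    point, and so on.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    if dilution_ratio < 0:
        raise ValueError("dilution_ratio must be >= 0")
    rng = make_rng(seed, "vectors")
    vector = random_vector(vector_len, rng)
    members: list[tuple[PlasmidConstruct, float]] = []
    per_gene_ratio = 2.0 / len(genes)
    for gene in genes:
        members.append(
            (PlasmidConstruct(f"construct_{gene.id}", vector, insert=gene), per_gene_ratio)
        )
    if dilution_ratio > 0:
        diluent = random_vector(diluent_len, rng)
        members.append((PlasmidConstruct("diluent_vector", diluent), float(dilution_ratio)))
    return CommunitySpec(members)


def copies_per_ng(
    spec: CommunitySpec, gene_predicate: Callable[[SeqRecord], bool] | None = None
) -> float:
    """Mass-balance gene copies per nanogram of community DNA.

    copies/ng = sum(ratio_i * genes_i) / sum(ratio_i * total_len_i * m_bp)
    with m_bp = 650 g/mol / N_A expressed in ng. Deterministic closed form.
    """
    pred = gene_predicate or (lambda g: True)
    n_copies = sum(
        ratio for c, ratio in spec.members if c.insert is not None and pred(c.insert)
    )
    mass = sum(ratio * c.total_len for c, ratio in spec.members) * BP_MASS_NG
    if mass == 0:
        raise ValueError("community has zero total mass")
    return n_copies / mass


def expected_insert_fraction(spec: CommunitySpec) -> float:
    """Fraction of community nucleotides belonging to inserts (molar weighted)."""
    total = sum(ratio * c.total_len for c, ratio in spec.members)
    inserted = sum(ratio * c.insert_len for c, ratio in spec.members)
    return inserted / total if total else 0.0


def expected_contained_fraction(spec: CommunitySpec, frag_len: int) -> float:
    """Probability that a uniformly placed ``frag_len`` fragment on a circular
    construct (construct chosen proportional to ratio * length) lies wholly
    inside the insert: sum ratio_i * max(g_i - L + 1, 0) / sum ratio_i * G_i.

    At L=1 this reduces to the insert base fraction.
    """
    if frag_len < 1:
        raise ValueError("frag_len must be >= 1")
    total = sum(ratio * c.total_len for c, ratio in spec.members)
    contained = sum(
        ratio * max(c.insert_len - frag_len + 1, 0) for c, ratio in spec.members
    )
    return contained / total if total else 0.0


def plant_primer_sites(
    gene: SeqRecord,
    fwd_primer: str,
    rev_primer: str,
    n_mismatch_fwd: int = 0,
    n_mismatch_rev: int = 0,
    amplicon_len: int = 635,
    offset: int = 10,
    seed: int = 0,
) -> SeqRecord:
    """Return a copy of ``gene`` carrying concrete primer-binding sites.

    The forward site starts at ``offset``; the reverse site ends at
    ``offset + amplicon_len`` (its template-strand sequence is the reverse
    complement of the reverse primer). ``n_mismatch_*`` positions are set to
    bases incompatible with the primer's IUPAC code, emulating templates the
    primer binds imperfectly.
    """
    rng = make_rng(seed, f"primer_sites:{gene.id}")
    if offset + amplicon_len > len(gene.seq):
        raise ValueError("amplicon does not fit in gene")

    def realise(primer: str, n_mismatch: int) -> str:
        site = [sorted(IUPAC_SETS[b])[int(rng.integers(len(IUPAC_SETS[b])))] for b in primer]
        positions = rng.choice(len(primer), size=n_mismatch, replace=False)
        for p in positions:
            allowed = IUPAC_SETS[primer[p]]
            site[p] = sorted(set(_BASES) - allowed)[int(rng.integers(4 - len(allowed)))]
        return "".join(site)

    from .io_core import revcomp  # local import to avoid cycle at module load

    fwd_site = realise(fwd_primer, n_mismatch_fwd)
    rev_site = revcomp(realise(rev_primer, n_mismatch_rev))
    seq = list(gene.seq)
    seq[offset : offset + len(fwd_primer)] = fwd_site
    seq[offset + amplicon_len - len(rev_site) : offset + amplicon_len] = rev_site
    return SeqRecord(gene.id, "".join(seq), meta=dict(gene.meta))


def community_table(spec: CommunitySpec) -> list[tuple[str, float, int, int, int]]:
    """(construct, molar ratio, vector nt, insert nt, total nt) rows for reports."""
    return [
        (c.construct_id, ratio, c.vector_len, c.insert_len, c.total_len)
        for c, ratio in spec.members
    ]
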