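"""End-to-end experiment orchestration: the mock-community validation and the
dilution series, wiring the synthetic community, capture simulator and OTU
pipeline together exactly in the order of the wet-lab workflow.

The default mock is six mutually diverged marker genes cloned into one 2739 nt
circular vector, optionally spiked with a seventh low-level contaminant gene
(read fraction 0.09%) and diluted with an empty 2786 nt vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .capture_sim import (
    CAPTURE_PRESETS,
    CaptureModel,
    PcrModel,
    ReadSet,
    fragment_community,
    sample_by_multiplicity,
    sequence_paired,
    simulate_capture,
    simulate_pcr,
    size_select,
)
from .classify import TaxAssignment, assign_ecotype, assign_taxonomy
from .gene_pipeline import (
    CandidateCds,
    Otu,
    QcParams,
    assemble,
    cluster_otus,
    extract_cds,
    merge_pairs,
    qc_short_reads,
    remove_chimeras,
    search_cummo,
)
from .io_core import RunConfig, SeqRecord, rng as make_rng
from .mock_synth import (
    CommunitySpec,
    GeneFamilyParams,
    PlasmidConstruct,
    build_mock,
    copies_per_ng,
    expected_contained_fraction,
    expected_insert_fraction,
    generate_gene_family,
)
from .probe_design import ProbeSet, dedup_probes, tile_probes
from .quantify import MappingParams, OtuTable, build_otu_table, map_reads, mapped_ratio
from .refdb import ReferenceDB

logger = logging.getLogger("amocap.workflows")

#: gene labels for the default mock: three archaeal amoA (one per oceanic
#: ecotype clade), three bacterial lineages, plus the contaminant (archaeal)
DEFAULT_GENE_LABELS = (
    ("amoA-AOA", "NP-γ-2.1"),
    ("amoA-AOA", "NP-ε-2"),
    ("amoA-AOA", "NP-α-2.2.2.1"),
    ("amoA-AOB", "Nitrosomonas"),
    ("amoA-AOB", "Nitrosococcus"),
    ("amoA-AOB", "Nitrospira-comammox"),
    ("amoA-AOA", "NP-γ-2.1"),  # contaminant lineage
)

#: preset key -> published-style sample name for the mock validation
MOCK_SAMPLES = {
    "non-capture": "non-capture_Mock",
    "single-cycle20": "single_Mock-cycle20",
    "double-cycle5/20": "double_Mock-cycle5/20",
    "double-cycle7/14": "double_Mock-cycle7/14",
    "double-cycle7/20": "double_Mock-cycle7/20",
}


@dataclass
class MockSetup:
    genes: list[SeqRecord]
    contaminant: SeqRecord
    community: CommunitySpec
    contaminant_construct: PlasmidConstruct
    refdb: ReferenceDB
    probes: ProbeSet


@dataclass
class SampleRun:
    name: str
    n_qc_pairs: int
    n_merged: int
    cds: list[CandidateCds]
    merged_reads: list[SeqRecord]


@dataclass
class MockValidationResult:
    setup: MockSetup
    samples: list[SampleRun]
    otus: list[Otu]
    taxonomy: list[TaxAssignment]
    otu_table: OtuTable
    mapped_ratios: dict[str, float]
    n_complete_matches: int

    @property
    def n_otus(self) -> int:
        return len(self.otus)

    def metrics_rows(self) -> list[tuple]:
        rows = [("n_otus", self.n_otus), ("n_complete_matches", self.n_complete_matches)]
        rows += [
            (f"mapped_ratio:{name}", round(ratio, 4))
            for name, ratio in sorted(self.mapped_ratios.items())
        ]
        return rows


def build_mock_setup(config: RunConfig, dilution_ratio: float = 0.0) -> MockSetup:
    """Generate genes, constructs, the labelled reference set and probes."""
    n_inserts = len(config.insert_lens)
    params = GeneFamilyParams(
        n_genes=n_inserts + 1,
        lengths=tuple(config.insert_lens) + (750,),
        seed=config.seed,
    )
    family = generate_gene_family(params)
    genes, contaminant = family[:n_inserts], family[n_inserts]
    for gene, (fam, clade) in zip(family, DEFAULT_GENE_LABELS):
        gene.meta.update({"gene_family": fam, "clade": clade})
    community = build_mock(
        genes,
        vector_len=config.vector_len,
        diluent_len=config.diluent_len,
        dilution_ratio=dilution_ratio,
        seed=config.seed,
    )
    vector = community.members[0][0].vector_seq
    contaminant_construct = PlasmidConstruct(
        f"construct_{contaminant.id}", vector, insert=contaminant
    )
    db = ReferenceDB.build(family)
    probes = dedup_probes(
        tile_probes(db, probe_len=config.probe_len, stride=config.stride), db
    )
    return MockSetup(genes, contaminant, community, contaminant_construct, db, probes)


def simulate_sample(
    name: str,
    preset: str,
    community: CommunitySpec,
    probes: ProbeSet,
    config: RunConfig,
    n_pairs: int,
    contaminant_construct: PlasmidConstruct | None = None,
) -> ReadSet:
    """Simulate one library through fragmentation, size selection, LM-PCR,
    the preset's capture rounds and paired-end sequencing.

    Capture arms receive the contaminant spike at
    ``config.contaminant_read_fraction`` of the read pairs, mimicking a trace
    contamination present before hybridisation (it is enriched like any other
    target, hence invisible in the non-capture arm at desk scale).
    """
    if preset not in CAPTURE_PRESETS or "amplicon" in CAPTURE_PRESETS[preset]:
        raise ValueError(f"unknown shotgun preset {preset!r}")
    profile = CAPTURE_PRESETS[preset]
    rounds = profile["rounds"]
    rng = make_rng(config.seed, f"sample:{name}")

    def prepare(spec: CommunitySpec, n_frag: int) -> list:
        frags = fragment_community(
            spec, n_frag, config.frag_len_mean, config.frag_len_sd, rng=rng
        )
        frags = size_select(frags, config.size_select_min_len)
        frags = simulate_pcr(
            frags,
            PcrModel(cycles=profile["pre_cycles"], efficiency=config.pcr_efficiency,
                     chimera_rate=config.chimera_rate),
            rng,
        )
        for round_idx in range(rounds):
            model = CaptureModel(
                min_overlap=config.capture_min_overlap,
                min_identity=config.capture_min_identity,
                nonspecific_rate=config.nonspecific_rate,
                rounds=1,
            )
            frags = simulate_capture(frags, probes, model, rng)
            frags = simulate_pcr(
                frags,
                PcrModel(cycles=profile["post_cycles"][round_idx],
                         efficiency=config.pcr_efficiency,
                         chimera_rate=config.chimera_rate),
                rng,
            )
        return frags

    oversample = 1.25 if rounds == 0 else 5.0
    pool = prepare(community, int(n_pairs * oversample))
    n_cont = 0
    if rounds > 0 and contaminant_construct is not None and config.contaminant_read_fraction > 0:
        n_cont = int(round(n_pairs * config.contaminant_read_fraction))
    templates = sample_by_multiplicity(pool, n_pairs - n_cont, rng)
    if n_cont > 0:
        cont_pool = prepare(
            CommunitySpec([(contaminant_construct, 1.0)]), max(8 * n_cont, 400)
        )
        templates += sample_by_multiplicity(cont_pool, n_cont, rng)
    return sequence_paired(
        templates, read_len=config.read_len, error_rate=config.error_rate,
        rng=rng, sample=name,
    )


def process_sample(name: str, reads: ReadSet, db: ReferenceDB, config: RunConfig) -> SampleRun:
    """QC, merge, assemble and homology-filter one sample's reads."""
    qc_params = QcParams(
        min_qual=config.min_qual,
        min_len=config.min_read_len,
        dust_threshold=config.dust_threshold,
        hifi_end_trim=config.hifi_end_trim,
        hifi_len_range=(config.hifi_len_min, config.hifi_len_max),
    )
    qc = qc_short_reads(reads, qc_params)
    merged, unmerged = merge_pairs(qc)
    n_qc_pairs = len(merged.reads) + len(unmerged.reads)
    contigs = assemble(merged, sample=name)
    cds = extract_cds(contigs)
    cds = search_cummo(
        cds, db,
        min_id=config.search_min_identity,
        min_qcov=config.search_min_qcov,
        min_scov=config.search_min_scov,
        len_window=(config.cds_len_min, config.cds_len_max),
    )
    return SampleRun(name, n_qc_pairs, len(merged.reads), cds, merged.reads)


def pool_and_cluster(samples: list[SampleRun], config: RunConfig) -> list[Otu]:
    """Pool candidate CDSs across samples (sample concatenating), remove
    chimeras, cluster at the OTU threshold and discard singletons."""
    all_cds = [c for run in samples for c in run.cds]
    records = [SeqRecord(c.id, c.nt_seq) for c in all_cds]
    kept, _ = remove_chimeras(
        records, [c.abundance for c in all_cds], delta=config.chimera_delta
    )
    kept_ids = {r.id for r in kept}
    survivors = [c for c in all_cds if c.id in kept_ids]
    return cluster_otus(
        survivors,
        identity=config.cluster_identity,
        coverage=config.cluster_coverage,
        discard_singletons=config.discard_singletons,
    )


def run_mock_validation(
    seed: int = 0,
    n_pairs: int = 50_000,
    config: RunConfig | None = None,
    presets: tuple[str, ...] = (
        "single-cycle20", "double-cycle5/20", "double-cycle7/14", "double-cycle7/20",
        "non-capture",
    ),
) -> MockValidationResult:
    """The full mock validation: simulate the capture and non-capture arms,
    run the OTU pipeline on the pooled samples and report recovery metrics.

    ``n_complete_matches`` counts inserted genes whose full CDS appears
    verbatim as an OTU representative.
    """
    config = config or RunConfig(seed=seed)
    if config.seed != seed:
        config.seed = seed
    config.log_resolved()
    setup = build_mock_setup(config)
    runs: list[SampleRun] = []
    for preset in presets:
        name = MOCK_SAMPLES.get(preset, preset)
        reads = simulate_sample(
            name, preset, setup.community, setup.probes, config, n_pairs,
            contaminant_construct=setup.contaminant_construct,
        )
        runs.append(process_sample(name, reads, setup.refdb, config))
    otus = pool_and_cluster(runs, config)

    mapping = MappingParams(
        seed_len=config.seed_len,
        seed_mismatch=config.seed_mismatch,
        min_aligned_fraction=config.min_aligned_fraction,
    )
    assignments_by_sample: dict[str, list[str | None]] = {}
    totals: dict[str, int] = {}
    ratios: dict[str, float] = {}
    for run in runs:
        assignments = map_reads(run.merged_reads, otus, mapping) if otus else []
        assignments_by_sample[run.name] = assignments
        totals[run.name] = run.n_qc_pairs
        ratios[run.name] = mapped_ratio(assignments, run.n_qc_pairs)
    otu_table = build_otu_table(assignments_by_sample, otus, totals) if otus else None

    matches = 0
    rep_seqs = {o.representative for o in otus}
    for gene in setup.genes:
        if gene.seq in rep_seqs:
            matches += 1
    taxonomy = [assign_ecotype(a) for a in assign_taxonomy(otus, setup.refdb)] if otus else []
    return MockValidationResult(
        setup=setup,
        samples=runs,
        otus=otus,
        taxonomy=taxonomy,
        otu_table=otu_table,
        mapped_ratios=ratios,
        n_complete_matches=matches,
    )


@dataclass
class DilutionPoint:
    dilution_ratio: float
    copies_per_ng: float
    expected_insert_fraction: float
    expected_contained_fraction: float
    mapped_ratio_capture: float | None = None
    mapped_ratio_noncapture: float | None = None


def dilution_expectations(
    config: RunConfig | None = None,
    ratios: tuple[float, ...] = (1000.0, 10_000.0, 100_000.0),
) -> list[DilutionPoint]:
    """Closed-form expectations for the dilution series (no simulation):
    copies/ng by mass balance and the insert/containment fractions."""
    config = config or RunConfig()
    setup_genes = generate_gene_family(
        GeneFamilyParams(n_genes=len(config.insert_lens),
                         lengths=config.insert_lens, seed=config.seed)
    )
    points = []
    for ratio in ratios:
        spec = build_mock(
            setup_genes, vector_len=config.vector_len,
            diluent_len=config.diluent_len, dilution_ratio=ratio, seed=config.seed,
        )
        points.append(
            DilutionPoint(
                dilution_ratio=ratio,
                copies_per_ng=copies_per_ng(spec),
                expected_insert_fraction=expected_insert_fraction(spec),
                expected_contained_fraction=expected_contained_fraction(
                    spec, int(config.frag_len_mean)
                ),
            )
        )
    return points
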