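"""In-silico library preparation: sonication-style fragmentation, size
selection, solution hybrid selection (probe capture), LM-PCR with chimera
formation, paired-end short-read sequencing and degenerate-primer amplicon PCR.

Hybridisation is modelled as alignment overlap/identity rather than
thermodynamics: a fragment is captured when its best probe alignment (either
strand) covers at least ``min_overlap`` nt at ``min_identity``, else it
survives a round only at ``nonspecific_rate``. This reproduces the
mismatch-tolerance of solution hybrid selection without melting-temperature
physics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import edlib
import numpy as np

from .io_core import SeqRecord, iupac_match, revcomp
from .mock_synth import CommunitySpec
from .probe_design import ProbeSet

logger = logging.getLogger("amocap.capture_sim")


@dataclass(slots=True)
class Fragment:
    """A library fragment with ground-truth provenance for truth-aware tests.

    ``start`` is a 0-based circular coordinate on the source construct;
    ``on_target`` means >=1 nt overlap with an insert, ``contained`` that the
    whole fragment lies inside the insert. ``multiplicity`` carries PCR copy
    numbers.
    """

    source_id: str
    start: int
    length: int
    seq: str
    on_target: bool
    contained: bool
    source_gene: str | None
    multiplicity: int = 1
    chimera: bool = False


@dataclass
class CaptureModel:
    min_overlap: int = 100
    min_identity: float = 0.80
    nonspecific_rate: float = 1e-4
    rounds: int = 1  # 0 = the pass-through "non-capture" arm

    def __post_init__(self) -> None:
        if self.rounds not in (0, 1, 2):
            raise ValueError("rounds must be 0, 1 or 2")


@dataclass
class PcrModel:
    cycles: int = 20
    efficiency: float = 0.9  # per-cycle duplication probability
    mismatch_penalty: float = 0.5  # multiplicative per primer mismatch
    chimera_rate: float = 1e-4  # per duplication event
    chimera_kmer: int = 12
    max_chimera_templates: int = 1000  # distinct chimera sequences materialised


@dataclass
class PrimerPair:
    """Degenerate PCR primer pair (IUPAC codes honoured, e.g. S = C or G)."""

    fwd: str = "STAATGGTCTGGCTTAGACG"
    rev: str = "GCGGCCATCCATCTGTATGT"
    max_mismatch: int = 3


#: the Arch-amoAF/R pair amplifying a 635 bp archaeal amoA region
FRANCIS_PRIMERS = PrimerPair()

#: experiment profiles: capture rounds and LM-PCR cycle settings, named after
#: the mock-validation sample conventions
CAPTURE_PRESETS: dict[str, dict] = {
    "non-capture": {"rounds": 0, "pre_cycles": 9, "post_cycles": []},
    "single-cycle20": {"rounds": 1, "pre_cycles": 9, "post_cycles": [20]},
    "double-cycle5/20": {"rounds": 2, "pre_cycles": 9, "post_cycles": [5, 20]},
    "double-cycle7/14": {"rounds": 2, "pre_cycles": 9, "post_cycles": [7, 14]},
    "double-cycle7/20": {"rounds": 2, "pre_cycles": 9, "post_cycles": [7, 20]},
    "amplicon-short": {"amplicon": True, "cycles": 40, "long_read": False},
    "amplicon-long": {"amplicon": True, "cycles": 35, "long_read": True},
}


@dataclass
class ReadSet:
    """Sequencing reads with qualities and provenance tags in ``meta``."""

    layout: str  # "paired" or "single"
    reads: list[SeqRecord] = field(default_factory=list)
    mates: list[SeqRecord] | None = None

    def __len__(self) -> int:
        return len(self.reads)

    def truth_rows(self) -> list[tuple]:
        rows = []
        for rec in self.reads:
            rows.append(
                (
                    rec.id,
                    rec.meta.get("source_id", ""),
                    rec.meta.get("source_gene", ""),
                    rec.meta.get("on_target", ""),
                    rec.meta.get("contained", ""),
                )
            )
        return rows


def fragment_community(
    spec: CommunitySpec,
    n_fragments: int,
    frag_len_mean: float = 200.0,
    frag_len_sd: float = 30.0,
    rng: np.random.Generator | None = None,
    with_seq: bool = True,
) -> list[Fragment]:
    """Draw fragments from the community: source construct with probability
    proportional to ratio * total length, start uniform on the circle, lengths
    from a (rounded, truncated) normal around the mean.

    ``with_seq=False`` skips sequence materialisation for counting-only
    Monte-Carlo runs.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    constructs = [c for c, _ in spec.members]
    min_total = min(c.total_len for c in constructs)
    if frag_len_mean >= min_total:
        raise ValueError("fragment length must be below the shortest construct")
    weights = np.array([ratio * c.total_len for c, ratio in spec.members], dtype=float)
    weights /= weights.sum()
    choices = rng.choice(len(constructs), size=n_fragments, p=weights)
    if frag_len_sd > 0:
        lengths = np.rint(rng.normal(frag_len_mean, frag_len_sd, size=n_fragments)).astype(int)
    else:
        lengths = np.full(n_fragments, int(round(frag_len_mean)))
    starts = rng.random(n_fragments)  # scaled per construct below

    # construct sequences doubled so circular substrings are single slices
    doubled = [c.seq + c.seq if with_seq else "" for c in constructs]
    totals = [c.total_len for c in constructs]
    vlens = [c.vector_len for c in constructs]
    glens = [c.insert_len for c in constructs]
    gene_ids = [c.insert.id if c.insert else None for c in constructs]

    fragments: list[Fragment] = []
    for idx in range(n_fragments):
        ci = choices[idx]
        G, V, g = totals[ci], vlens[ci], glens[ci]
        length = int(min(max(lengths[idx], 1), G - 1))
        start = int(starts[idx] * G)
        # insert occupies [V, G); overlap/containment on the circle
        if g > 0:
            contained = start >= V and start + length <= G
            if contained:
                on_target = True
            else:
                end = start + length
                # linear overlap with [V, G) of the two arcs [start, min(end,G)) and [0, end-G)
                ov = max(0, min(end, G) - max(start, V))
                if end > G:
                    ov += max(0, min(end - G, G) - V) if end - G > V else 0
                on_target = ov > 0
        else:
            contained = on_target = False
        seq = doubled[ci][start : start + length] if with_seq else ""
        fragments.append(
            Fragment(
                source_id=constructs[ci].construct_id,
                start=start,
                length=length,
                seq=seq,
                on_target=on_target,
                contained=contained,
                source_gene=gene_ids[ci] if on_target else None,
            )
        )
    return fragments


def size_select(fragments: list[Fragment], min_len: int = 150) -> list[Fragment]:
    """Remove fragments shorter than ``min_len`` (>= retained)."""
    return [f for f in fragments if f.length >= min_len]


class _ProbeIndex:
    """k-mer index over probe sequences (both strands) with edlib verification."""

    def __init__(self, probeset: ProbeSet, model: CaptureModel, k: int = 16):
        self.k = k
        self.model = model
        self.windows: list[str] = []
        index: dict[str, set[int]] = {}
        for probe in probeset.probes:
            pseq = probe.seq
            if model.min_overlap >= len(pseq):
                subwindows = [pseq]
            else:
                subwindows = [pseq[: model.min_overlap], pseq[-model.min_overlap :]]
            for w in subwindows:
                for oriented in (w, revcomp(w)):
                    wi = len(self.windows)
                    self.windows.append(oriented)
                    for i in range(0, len(oriented) - k + 1):
                        index.setdefault(oriented[i : i + k], set()).add(wi)
        self.index = index
        # sampling stride for fragment k-mers: a shared run of min_overlap nt
        # contains >= min_overlap - k + 1 consecutive shared k-mers, so a
        # stride of 8 cannot miss it at the default sizes
        self.scan_stride = 8

    def matches(self, frag_seq: str) -> bool:
        k = self.k
        if len(frag_seq) < k:
            return False
        candidates: set[int] = set()
        positions = list(range(0, len(frag_seq) - k + 1, self.scan_stride))
        if positions[-1] != len(frag_seq) - k:
            positions.append(len(frag_seq) - k)
        for i in positions:
            hit = self.index.get(frag_seq[i : i + k])
            if hit:
                candidates.update(hit)
        for wi in candidates:
            w = self.windows[wi]
            if len(frag_seq) < len(w):
                continue
            max_dist = math.floor(len(w) * (1.0 - self.model.min_identity))
            res = edlib.align(w, frag_seq, mode="HW", task="distance", k=max_dist)
            if res["editDistance"] != -1:
                return True
        return False


def simulate_capture(
    fragments: list[Fragment],
    probeset: ProbeSet,
    model: CaptureModel,
    rng: np.random.Generator | None = None,
) -> list[Fragment]:
    """Apply ``model.rounds`` rounds of hybridisation capture.

    Probe matching is deterministic per fragment, so repeated rounds only
    compound the non-specific carry-through (rate per fragment per round).
    ``rounds=0`` returns the input unchanged (the non-capture arm).
    """
    if model.rounds == 0:
        return list(fragments)
    rng = rng if rng is not None else np.random.default_rng(0)
    index = _ProbeIndex(probeset, model)
    retained: list[Fragment] = []
    for frag in fragments:
        if index.matches(frag.seq):
            retained.append(frag)
        elif model.nonspecific_rate > 0 and all(
            rng.random() < model.nonspecific_rate for _ in range(model.rounds)
        ):
            retained.append(frag)
    logger.info(
        "capture (%d round%s): %d/%d fragments retained",
        model.rounds, "s" if model.rounds > 1 else "", len(retained), len(fragments),
    )
    return retained


def _make_chimera(
    a: Fragment, b: Fragment, k: int, rng: np.random.Generator
) -> Fragment | None:
    """Join a prefix of ``a`` to a suffix of ``b`` at an exact shared k-mer."""
    if len(a.seq) < k or len(b.seq) < k:
        return None
    b_kmers: dict[str, int] = {}
    for j in range(len(b.seq) - k + 1):
        b_kmers.setdefault(b.seq[j : j + k], j)
    starts = rng.permutation(len(a.seq) - k + 1)
    for i in starts[:50]:
        j = b_kmers.get(a.seq[i : i + k])
        if j is not None:
            seq = a.seq[: i + k] + b.seq[j + k :]
            if len(seq) < k or seq == a.seq or seq == b.seq:
                return None
            genes = "+".join(sorted({g for g in (a.source_gene, b.source_gene) if g}))
            return Fragment(
                source_id=f"chimera:{a.source_id}|{b.source_id}",
                start=a.start,
                length=len(seq),
                seq=seq,
                on_target=a.on_target or b.on_target,
                contained=False,
                source_gene=genes or None,
                multiplicity=1,
                chimera=True,
            )
    return None


def simulate_pcr(
    fragments: list[Fragment],
    model: PcrModel,
    rng: np.random.Generator | None = None,
) -> list[Fragment]:
    """Per-cycle Bernoulli-doubling branching process on template copy numbers.

    Each cycle every copy duplicates with probability ``efficiency``; each
    duplication event forms a chimera with probability ``chimera_rate`` by
    joining two templates at a shared k-mer. Distinct chimera sequences are
    capped at ``max_chimera_templates`` per run; beyond the cap, events are
    aggregated into the existing templates' copy numbers so the chimeric read
    fraction is preserved.
    """
    if model.cycles < 0:
        raise ValueError("cycles must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(0)
    templates = list(fragments)
    copies = np.array([f.multiplicity for f in templates], dtype=np.int64)
    for _ in range(model.cycles):
        new = rng.binomial(copies, model.efficiency)
        if model.chimera_rate > 0 and new.sum() > 0:
            n_events = rng.binomial(int(new.sum()), model.chimera_rate)
            if n_events > 0:
                budget = model.max_chimera_templates - sum(t.chimera for t in templates)
                n_distinct = min(n_events, max(budget, 0))
                per_template = n_events // n_distinct if n_distinct else 0
                extra: list[Fragment] = []
                extra_copies: list[int] = []
                p = copies / copies.sum()
                for _ in range(n_distinct):
                    ia, ib = rng.choice(len(templates), size=2, p=p)
                    chim = _make_chimera(templates[ia], templates[ib], model.chimera_kmer, rng)
                    if chim is not None:
                        extra.append(chim)
                        extra_copies.append(max(per_template, 1))
                if extra:
                    templates.extend(extra)
                    copies = np.concatenate([copies, np.array(extra_copies, dtype=np.int64)])
                    new = np.concatenate([new, np.zeros(len(extra), dtype=new.dtype)])
        copies = copies + new
    out: list[Fragment] = []
    for frag, c in zip(templates, copies):
        frag.multiplicity = int(c)
        out.append(frag)
    return out


def sample_by_multiplicity(
    fragments: list[Fragment], n: int, rng: np.random.Generator
) -> list[Fragment]:
    """Sample ``n`` templates with replacement, weighted by PCR multiplicity
    (the sequencing step sees amplified libraries, not unique templates)."""
    if not fragments:
        return []
    weights = np.array([f.multiplicity for f in fragments], dtype=float)
    weights /= weights.sum()
    idx = rng.choice(len(fragments), size=n, p=weights)
    return [fragments[i] for i in idx]


def _phred_from_error(error_rate: float) -> int:
    if error_rate <= 0:
        return 40
    return min(40, int(round(-10.0 * math.log10(error_rate))))


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0 or not seq:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != out[p]]
        out[p] = alternatives[int(rng.integers(3))]
    return "".join(out)


def sequence_paired(
    fragments: list[Fragment],
    read_len: int = 300,
    error_rate: float = 1e-3,
    rng: np.random.Generator | None = None,
    sample: str = "S",
) -> ReadSet:
    """2 x ``read_len`` paired-end reads from fragment ends.

    Fragments shorter than the read length yield full-length mates (pairs from
    200 bp fragments therefore overlap completely; adapter read-through
    trimming is implicit). Substitution errors are uniform at ``error_rate``
    with qualities consistent with that rate.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    q = _phred_from_error(error_rate)
    reads: list[SeqRecord] = []
    mates: list[SeqRecord] = []
    for i, frag in enumerate(fragments):
        n = min(read_len, frag.length)
        fwd = _mutate(frag.seq[:n], error_rate, rng)
        rev = _mutate(revcomp(frag.seq)[:n], error_rate, rng)
        meta = {
            "sample": sample,
            "source_id": frag.source_id,
            "start": str(frag.start),
            "length": str(frag.length),
            "on_target": str(int(frag.on_target)),
            "contained": str(int(frag.contained)),
            "source_gene": frag.source_gene or "",
            "chimera": str(int(frag.chimera)),
        }
        reads.append(SeqRecord(f"{sample}_frag{i}", fwd, qual=[q] * len(fwd), meta=dict(meta)))
        mates.append(SeqRecord(f"{sample}_frag{i}", rev, qual=[q] * len(rev), meta=dict(meta)))
    return ReadSet(layout="paired", reads=reads, mates=mates)


def _best_primer_site(seq: str, primer: str, reverse: bool) -> tuple[int, int] | None:
    """(position, mismatches) of the best primer annealing site.

    Forward sites are compared on the plus strand; reverse sites compare the
    primer against the reverse complement of the template window. Position is
    the 0-based window start on the plus strand.
    """
    m = len(primer)
    best: tuple[int, int] | None = None
    for o in range(len(seq) - m + 1):
        window = seq[o : o + m]
        if reverse:
            window = revcomp(window)
        mm = sum(not iupac_match(p, b) for p, b in zip(primer, window))
        if best is None or mm < best[1]:
            best = (o, mm)
            if mm == 0:
                break
    return best


def simulate_amplicon(
    templates: list[SeqRecord],
    primers: PrimerPair = FRANCIS_PRIMERS,
    pcr_model: PcrModel | None = None,
    long_read: bool = False,
    n_reads: int = 10_000,
    read_len: int = 300,
    error_rate: float = 1e-3,
    hifi_error_rate: float = 2e-3,
    rng: np.random.Generator | None = None,
) -> tuple[ReadSet, list[dict]]:
    """Two-step PCR amplicon simulation with degenerate-primer bias.

    Per template the best forward/reverse primer sites are located (IUPAC
    degeneracy honoured, <= ``max_mismatch`` each); the amplification weight is
    (1 + efficiency * mismatch_penalty^(mf+mr))^cycles, so every extra
    mismatch shrinks a template's product share. Templates without both sites
    yield no product. ``long_read=True`` emits one near-perfect read per
    product (HiFi-style, >=99% accuracy), else 2 x ``read_len`` pairs.

    Returns the reads and a per-template product table (mismatches, weight,
    product share).
    """
    pcr_model = pcr_model or PcrModel(cycles=35)
    rng = rng if rng is not None else np.random.default_rng(0)
    products: list[dict] = []
    for rec in templates:
        fwd = _best_primer_site(rec.seq, primers.fwd, reverse=False)
        entry = {
            "template": rec.id, "product_len": 0, "mismatch_fwd": None,
            "mismatch_rev": None, "weight": 0.0, "share": 0.0, "seq": None,
        }
        if fwd is not None and fwd[1] <= primers.max_mismatch:
            sub = rec.seq[fwd[0] + len(primers.fwd) :]
            rev = _best_primer_site(sub, primers.rev, reverse=True)
            if rev is not None and rev[1] <= primers.max_mismatch:
                start = fwd[0]
                end = fwd[0] + len(primers.fwd) + rev[0] + len(primers.rev)
                mf, mr = fwd[1], rev[1]
                weight = (
                    1.0 + pcr_model.efficiency * pcr_model.mismatch_penalty ** (mf + mr)
                ) ** pcr_model.cycles
                entry.update(
                    product_len=end - start, mismatch_fwd=mf, mismatch_rev=mr,
                    weight=weight, seq=rec.seq[start:end],
                )
        products.append(entry)
    total_weight = sum(p["weight"] for p in products)
    if total_weight > 0:
        for p in products:
            p["share"] = p["weight"] / total_weight

    amplified = [p for p in products if p["weight"] > 0]
    readset = ReadSet(layout="single" if long_read else "paired",
                      reads=[], mates=None if long_read else [])
    if amplified and n_reads > 0:
        shares = np.array([p["share"] for p in amplified])
        counts = rng.multinomial(n_reads, shares / shares.sum())
        frags = []
        for p, c in zip(amplified, counts):
            for _ in range(c):
                frags.append(
                    Fragment(
                        source_id=p["template"], start=0, length=p["product_len"],
                        seq=p["seq"], on_target=True, contained=True,
                        source_gene=p["template"],
                    )
                )
        if long_read:
            q = _phred_from_error(hifi_error_rate)
            for i, frag in enumerate(frags):
                seq = _mutate(frag.seq, hifi_error_rate, rng)
                readset.reads.append(
                    SeqRecord(
                        f"ccs_{i}", seq, qual=[q] * len(seq),
                        meta={"source_gene": frag.source_gene or "", "source_id": frag.source_id,
                              "on_target": "1", "contained": "1"},
                    )
                )
        else:
            readset = sequence_paired(frags, read_len=read_len, error_rate=error_rate,
                                      rng=rng, sample="amplicon")
    for p in products:
        p.pop("seq", None)
    return readset, products
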