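# Methods

This note documents the models behind `amocap`, the defaults and why they
were chosen, and what the synthetic benchmark does and does not demonstrate.

## The simulated experiment

The package models a plasmid mock community: marker genes (default six, of
654/702/738/768/792/846 nt, mean 750 nt) cloned into a circular 2739 nt
vector, one gene per construct, mixed at equal molar ratio and optionally
diluted with an empty 2786 nt vector at 2:x molar ratios. Construct
sequences are random with one biological constraint: the cloning junction is
flanked by a stop-in-all-frames block (`TTAATTAATTAA`), mirroring the
translational-stop context of a real multiple cloning site. This makes the
maximal-ORF scan terminate exactly at the insert boundary, so a correctly
assembled contig yields the insert CDS verbatim — which is what the
validation asserts.

Three closed forms anchor the simulation. With insert length *g*, total
construct length *G* and molar ratio *r* per construct:

* insert base fraction = Σ r·g / Σ r·G (0.2150 for the default mock);
* fragment containment probability for fragment length *L* =
  Σ r·max(g−L+1, 0) / Σ r·G (0.1579 at L=200). The gap between the two is
  the boundary effect: fragments straddling a gene edge carry vector
  sequence and fail to map;
* copies/ng = Σ r·(genes per construct) / (Σ r·G·m_bp) with
  m_bp = 650 g/mol / N_A ≈ 1.079×10⁻¹² ng. The 650 g/mol dsDNA convention is
  standard; the order-of-magnitude conclusions are insensitive to any choice
  in 615–660 (checked in tests).

Monte-Carlo fragment draws (construct ∝ ratio×length, start uniform on the
circle, lengths normal around 200 nt, sd 30 nt, rounded) converge to both
closed forms; the test suite checks this at 3 standard errors.

## Capture, PCR and sequencing models

Hybridisation is modelled as alignment, not thermodynamics: a fragment is
captured when some probe aligns (either strand) over ≥`min_overlap` nt
(default 100, one probe length) at ≥`min_identity` (default 0.80), else it
survives a round with probability `nonspecific_rate` (default 10⁻⁴ per
fragment per round). The identity floor reproduces the mismatch tolerance
that lets capture recover diverged targets; all three knobs are exposed.
The implementation prefilters candidates with an exact 16-mer index and
confirms with banded edit-distance alignment, which is exact for the
criterion because pre-PCR fragments are exact construct substrings.

LM-PCR is a branching process: each template copy duplicates per cycle with
probability `efficiency` (default 0.9), so a perfect template expects
(1.9)^cycles copies. Each duplication event may form a chimera
(`chimera_rate`, default 10⁻⁴) by joining a prefix of one template to the
suffix of another at an exact shared 12-mer (template switching). Because
late-cycle event counts grow into the 10⁹ range, the simulator materialises
at most `max_chimera_templates` (default 1000) distinct chimera sequences
per reaction and carries the remaining events as copy numbers on those
templates — the chimeric read *fraction* is preserved while memory stays
bounded. Cycle-count profiles (pre-capture 9; post-capture 20, 5/20, 7/14,
7/20; amplicon 35/40) are named presets matching the validation samples.

Sequencing emits 2×300 nt pairs from fragment ends (fragments shorter than
the read length yield full-length, fully overlapping mates — implicit
adapter trimming), with uniform substitution errors (default 10⁻³) and
qualities consistent with the error rate. Amplicon mode locates degenerate
primer sites (IUPAC-aware, ≤3 mismatches per primer), weights templates by
(1 + efficiency·0.5^mismatches)^cycles, and emits either read pairs or
near-perfect long reads (HiFi-style, default error 2×10⁻³).

## Pipeline algorithms and numerical choices

* **QC**: Q<20 end-trim, drop <100 nt, triplet DUST-style complexity score
  ≥7 (0–100 scale; homopolymer = 100, random ≈ 1). Pairs stay synchronised.
  Long-read QC applies the 400–1000 nt window first, then trims 20 nt per
  terminal (primer removal), matching the published order of operations.
* **Merging** tries full containment (offset 0) first — the generic case for
  ~200 bp fragments — then exact 16-mer anchors, then a brute-force scan;
  consensus takes the higher-quality base, forward mate winning ties.
* **Assembly** is a deterministic greedy overlap-consensus assembler:
  deduplicate reads, seed with the most abundant unused read, extend both
  directions through exact ≥30 nt suffix–prefix overlaps with
  abundance-weighted majority voting per extension column, stop when
  support falls below 2 reads or when the contig's fresh end re-occurs
  earlier (circular wrap-around guard). Reads within 2% edit distance of a
  finished contig are absorbed as members; contigs need ≥2 supporting
  reads. Reads are assembled on their given strand (the merger orients
  pairs onto the fragment strand). This replaces a de Bruijn metagenome
  assembler deliberately: at desk scale (≤10 genes, ≤10⁵ reads) exactness
  and determinism matter more than heuristic scalability.
* **CDS extraction** is a six-frame maximal-ORF scan (table 11 starts
  ATG/GTG/TTG, translated as M; emitted nt includes the stop codon),
  standing in for a trained gene finder for the same reason.
* **Homology filter**: best protein local alignment (BLOSUM62) must reach
  60% identity with both query and subject coverage ≥50%, then the 400–1000
  bp nucleotide window applies. An e-value threshold would be
  database-size-dependent; at these lengths the identity/coverage pair
  dominates the decision, so the e-value criterion is dropped.
* **Chimera removal** seeks, per query in ascending abundance, a crossover
  position where the left-segment identity to one strictly-more-abundant
  parent and the right-segment identity to another each beat the query's
  best single-sequence identity by ≥1.5 percentage points *and* reach 80%
  absolute identity. The absolute floor exists because segment-level
  identity between mutually unrelated sequences fluctuates several points
  around its ~48% background, which would otherwise let the margin rule
  false-flag pure sequences; real crossover segments match their parent
  near-perfectly, so the floor costs no sensitivity. A 20-run audit of
  chimera-free pools asserts zero false positives.
* **Clustering** is greedy centroid clustering: order by abundance
  (ties: length descending, then id ascending), join the first centroid
  reached at ≥97% identity, else found a new one; singletons are discarded.
  Identity is measured by aligning the shorter sequence as an infix of the
  longer (edlib HW), which makes coverage of the shorter sequence complete —
  at least as strict as "≥97% over ≥50% coverage of the shorter" and free of
  tie-breaking ambiguity. The ≥ operator is used at the threshold.
* **Mapping** uses half-seed k-mer candidate lookup (exact 11-mers, the
  pigeonhole complement of a 22 nt seed with ≤1 mismatch) and accepts a read
  when its full length aligns within 10% edit distance inside a
  representative. Equal-best ties are discarded rather than randomly placed,
  so abundances carry no tie-break noise; reads straddling an insert
  boundary are systematically unassigned, which is why the non-capture
  mapped ratio lands at the containment fraction (15.8%) rather than the
  base fraction (21%).
* **RPKMS** uses the per-sample QC read count as the "per million reads
  sequenced" denominator. **Rarefaction** is the exact hypergeometric
  expectation E[S_m] = S − Σᵢ C(N−nᵢ, m)/C(N, m) — no resampling seed.
  Samples under 100 mapped reads are excluded.
* **Taxonomy** is best-global-alignment label transfer (strand-agnostic;
  ties transfer the deepest label shared by all tied hits; <75% identity →
  unclassified CuMMO). The working **tree** is neighbor joining on
  Jukes–Cantor distances (p clamped below the ¾ saturation point); a
  maximum-likelihood tree with model selection is out of scope — the newick
  output lets users re-estimate externally.

## Scale of the shipped benchmarks

The full validation runs five samples (four capture presets, one
non-capture) at 5×10⁴ read pairs each with a 0.09% contaminant spike in the
capture arms, recovering exactly 7 OTUs (6 verbatim insert matches plus the
contaminant) in ~2.5 minutes on one core. The acceptance script's
Monte-Carlo uses 10⁶ fragments. Unit tests use 10³–2×10⁵-sized draws with
3-standard-error tolerances.

## What the synthetic benchmark does not show

The generator emulates composition, geometry and the main stochastic
processes (fragmentation, capture retention, PCR duplication/chimerism,
substitution errors), not the full physics or messiness of real data:
no melting-temperature or bead-kinetics model (capture efficiency is a
knob, not a prediction), no indel or quality-degradation error profiles, no
GC or strand bias, random backbones rather than real vector/host sequence,
and uniform fragment placement. Passing the validation therefore shows the
*bioinformatics* recovers what the *modelled* chemistry delivers, and that
the arithmetic of enrichment matches theory — it does not certify
performance on real libraries, where assembler and gene-caller choices,
error spectra and reference completeness dominate. The assembler is also
single-strand and desk-scale by design; it is not a general-purpose
metagenome assembler.
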