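"""Degenerate-primer PCR bias: why amplicon surveys miss most lineages.

Six templates share the community, but only three carry annealing sites for
the archaeal amoA primer pair (the classic 635 bp assay): one perfect match,
one with 2 summed primer mismatches and one with 3. After 35 cycles the
perfect-match template monopolises the product pool and the site-free
(bacterial-type) templates vanish entirely — the bias that enrichment by
hybridisation capture avoids.
"""

from amocap import FRANCIS_PRIMERS, GeneFamilyParams, PcrModel, generate_gene_family, simulate_amplicon
from amocap.io_core import rng as make_rng
from amocap.mock_synth import plant_primer_sites

genes = generate_gene_family(GeneFamilyParams(seed=1))
fwd, rev = FRANCIS_PRIMERS.fwd, FRANCIS_PRIMERS.rev
templates = [
    plant_primer_sites(genes[0], fwd, rev, 0, 0, seed=1),  # perfect match
    plant_primer_sites(genes[1], fwd, rev, 1, 1, seed=1),  # 2 mismatches total
    plant_primer_sites(genes[2], fwd, rev, 1, 2, seed=1),  # 3 mismatches total
    *genes[3:6],  # no primer sites at all
]

_, products = simulate_amplicon(
    templates, FRANCIS_PRIMERS, PcrModel(cycles=35), n_reads=0,
    rng=make_rng(1, "example:amplicon"),
)

print(f"{'template':<10}{'product':>9}{'mm_fwd':>8}{'mm_rev':>8}{'share':>10}")
for p in products:
    mm_f = "-" if p["mismatch_fwd"] is None else p["mismatch_fwd"]
    mm_r = "-" if p["mismatch_rev"] is None else p["mismatch_rev"]
    print(f"{p['template']:<10}{p['product_len']:>9}{mm_f:>8}{mm_r:>8}{p['share']:>10.4f}")
print()
print("Each primer mismatch halves the per-cycle annealing advantage, so over")
print("35 cycles even 2-3 mismatches cost orders of magnitude of product;")
print("templates without sites never amplify, exactly as bacterial amoA genes")
print("escape archaeal-primer surveys.")
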