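"""Hybridisation capture turns a mostly-vector library into a target library.

Fragments the mock community (~200 bp, sonication-style), applies one round
of probe capture and prints the on-target fraction before and after, using
the simulator's ground-truth tags. The pre-capture fraction matches the
closed-form overlap probability; capture lifts it to ~1 while non-specific
carry-through stays at the configured floor.
"""

import numpy as np

from amocap import (
    CaptureModel,
    GeneFamilyParams,
    build_mock,
    dedup_probes,
    fragment_community,
    generate_gene_family,
    simulate_capture,
    size_select,
    tile_probes,
)
from amocap.io_core import rng as make_rng

genes = generate_gene_family(GeneFamilyParams(seed=1))
mock = build_mock(genes, seed=1)
probes = dedup_probes(tile_probes(genes), genes)

rng = make_rng(1, "example:capture")
fragments = size_select(fragment_community(mock, 30_000, rng=rng), 150)
pre = np.mean([f.on_target for f in fragments])

captured = simulate_capture(fragments, probes, CaptureModel(nonspecific_rate=1e-4), rng)
post = np.mean([f.on_target for f in captured])

print(f"fragments after size selection: {len(fragments)}")
print(f"on-target fraction pre-capture:  {pre:.3f}  (expected ~0.27: genes are a")
print("                                         minority of each plasmid)")
print(f"fragments retained by capture:  {len(captured)}")
print(f"on-target fraction post-capture: {post:.3f}")
print()
print("Capture retains a fragment when it shares >= 100 nt at >= 80% identity")
print("with a probe, so the library collapses onto the gene inserts while a")
print("1e-4 per-fragment non-specific rate leaks a trace of vector through.")
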