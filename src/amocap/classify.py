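"""Taxonomy and ecotype assignment for OTUs, plus a working phylogeny.

Oceanic ammonia-oxidising archaea fall into three ecotypes mapped one-to-one
onto Nitrosopumilales clades: water column cluster A (WCA) = NP-ε-2, water
column cluster B (WCB) = NP-α-2.2.2.1 and the Nitrosopumilus maritimus-like
cluster (NMC) = NP-γ-2.1. The working tree is neighbor joining on
Jukes-Cantor-corrected pairwise distances — adequate for grouping and
visual inspection at desk scale; the newick output lets users re-estimate a
maximum-likelihood tree externally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from skbio import DistanceMatrix
from skbio.tree import nj

from ._align import global_identity
from .gene_pipeline import Otu
from .refdb import ReferenceDB
from .io_core import revcomp, write_tsv

logger = logging.getLogger("amocap.classify")

#: the three-way ecotype correspondence; clades outside the map get no ecotype
ECOTYPE_MAP: dict[str, str] = {
    "NP-ε-2": "WCA",
    "NP-α-2.2.2.1": "WCB",
    "NP-γ-2.1": "NMC",
}


@dataclass
class TaxAssignment:
    otu_id: str
    best_ref: str
    identity: float  # percent, 0-100
    clade: str
    ecotype: str | None = None
    gene_family: str = ""


def _shared_prefix_label(labels: list[str]) -> str:
    """Most specific hyphen-delimited label shared by all tied hits."""
    if not labels:
        return ""
    parts = [lab.split("-") for lab in labels]
    shared: list[str] = []
    for components in zip(*parts):
        if len(set(components)) == 1:
            shared.append(components[0])
        else:
            break
    return "-".join(shared)


def assign_taxonomy(
    otus: list[Otu],
    labelled_refdb: ReferenceDB,
    floor_identity: float = 75.0,
) -> list[TaxAssignment]:
    """Best-alignment label transfer from a clade-labelled reference set.

    Identity is a strand-agnostic global alignment percentage. Below
    ``floor_identity`` the OTU is reported as unclassified CuMMO. When several
    references tie at the best identity, only the deepest label shared by all
    of them is transferred.
    """
    out: list[TaxAssignment] = []
    for otu in otus:
        best_identity = -1.0
        best_hits: list = []
        for rec in labelled_refdb.records:
            ident = max(
                global_identity(otu.representative, rec.seq),
                global_identity(revcomp(otu.representative), rec.seq),
            ) * 100.0
            if ident > best_identity + 1e-9:
                best_identity, best_hits = ident, [rec]
            elif abs(ident - best_identity) <= 1e-9:
                best_hits.append(rec)
        if not best_hits or best_identity < floor_identity:
            out.append(
                TaxAssignment(otu.otu_id, best_hits[0].id if best_hits else "",
                              round(max(best_identity, 0.0), 2),
                              clade="unclassified CuMMO", gene_family="unclassified CuMMO")
            )
            continue
        clade = _shared_prefix_label([h.meta.get("clade", "") for h in best_hits])
        family_labels = {h.meta.get("gene_family", "") for h in best_hits}
        family = family_labels.pop() if len(family_labels) == 1 else ""
        out.append(
            TaxAssignment(
                otu.otu_id,
                best_hits[0].id,
                round(best_identity, 2),
                clade=clade,
                gene_family=family,
            )
        )
    return out


def assign_ecotype(
    assignment: TaxAssignment, ecotype_map: dict[str, str] | None = None
) -> TaxAssignment:
    """Fill the ecotype field; only archaeal amoA OTUs carry an ecotype."""
    mapping = ECOTYPE_MAP if ecotype_map is None else ecotype_map
    if assignment.gene_family == "amoA-AOA":
        assignment.ecotype = mapping.get(assignment.clade)
    else:
        assignment.ecotype = None
    return assignment


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor corrected distance from a raw mismatch proportion.

    Proportions at or beyond the saturation point (3/4) are clamped just
    below it, giving a large but finite distance."""
    p = min(max(p, 0.0), 0.749)
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def build_tree(otus: list[Otu]) -> str:
    """Neighbor-joining newick tree over OTU representatives.

    Distances are Jukes-Cantor-corrected global-alignment mismatch
    proportions. Deterministic given the input, and (ties aside) the unrooted
    topology does not depend on input order.
    """
    if len(otus) < 3:
        raise ValueError("build_tree requires at least 3 OTUs")
    ids = [o.otu_id for o in otus]
    n = len(otus)
    matrix = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            p = 1.0 - global_identity(otus[i].representative, otus[j].representative)
            d = jukes_cantor(p)
            matrix[i][j] = matrix[j][i] = d
    dm = DistanceMatrix(matrix, ids)
    tree = nj(dm)
    return str(tree).strip()


def write_taxonomy(assignments: list[TaxAssignment], path) -> None:
    write_tsv(
        path,
        "OTU taxonomy; identity in percent of global alignment",
        ["otu_id", "best_ref", "identity_pct", "clade", "ecotype", "gene_family"],
        [
            (a.otu_id, a.best_ref, a.identity, a.clade, a.ecotype or "", a.gene_family)
            for a in assignments
        ],
    )
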