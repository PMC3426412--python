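"""Genomic-context classification of ECF41 sigma-factor loci.

ECF41 genes are not linked to anti-sigma factor genes.  Instead a gene for a
carboxymuconolactone decarboxylase, an oxidoreductase, or an epimerase
("COE") usually sits directly up- or downstream.  This module types a
neighbor protein as COE from its Pfam-style domain names, classifies each
ECF41 gene's neighborhood into one of five conserved arrangements (arrow
notation relative to the ECF gene's own strand) plus ``ungrouped``, and
tabulates per-category counts and promoter occurrences.

Arrangements::

    ECF_alone       >ECF>                no COE neighbor
    COE_up_same     >COE> >ECF>          COE upstream, same strand
    COE_down_same   >ECF> >COE>          COE downstream, same strand
    convergent      >ECF> <COE<          genes pointing at each other
    divergent       <ECF< >COE>          genes pointing apart, shared
                                         upstream region
    ungrouped       hypothetical-product neighbor, no COE
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

# Category labels in the fixed reporting order.
CATEGORIES = (
    "ECF_alone",
    "COE_up_same",
    "COE_down_same",
    "convergent",
    "divergent",
    "ungrouped",
)

ARROWS = {
    "ECF_alone": ">ECF>",
    "COE_up_same": ">COE> >ECF>",
    "COE_down_same": ">ECF> >COE>",
    "convergent": ">ECF> <COE<",
    "divergent": "<ECF< >COE>",
    "ungrouped": "ungrouped",
}

# Domain vocabularies for COE typing.  Oxidoreductases are recognized by any
# of the flavin/NAD(P)H-associated families; epimerases by NmrA (PF05368) or
# Epimerase (PF01370); carboxymuconolactone decarboxylases by PF02627 (CMD).
CARBOXYMUCONOLACTONE_DOMAINS = frozenset({"PF02627", "CMD"})
OXIDOREDUCTASE_DOMAINS = frozenset(
    {
        "Oxidored_FMN",
        "Flavodoxin_2",
        "Pyr_redox",
        "Pyr_redox_2",
        "FAD_binding_2",
        "FAD_binding_3",
        "FAD_binding_4",
        "Amino_oxidase",
        "Pyridox_oxidase",
        "FMN_red",
    }
)
EPIMERASE_DOMAINS = frozenset({"NmrA", "PF05368", "Epimerase", "PF01370"})

COE_CLASSES = (
    "carboxymuconolactone_decarboxylase",
    "oxidoreductase",
    "epimerase",
    "cupin_hypothetical",
    "none",
)

#: COE classes that make a neighbor a bona fide COE partner.  Cupin-domain
#: hypotheticals are typed for reporting but do not define a COE context.
PARTNER_CLASSES = frozenset(COE_CLASSES[:3])


@dataclass(frozen=True)
class GeneRecord:
    """An annotated gene: 1-based inclusive coordinates on a replicon."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    role: str = "other"
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"invalid coordinates for {self.gene_id}: {self.start}..{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class LocusContext:
    """Classified neighborhood of one ECF41 gene (one summary-table row)."""

    ecf_gene_id: str
    category: str
    partner_gene_id: Optional[str] = None
    partner_coe_class: str = "none"
    promoter_on_ecf: bool = False
    promoter_on_coe: Optional[bool] = None  # None == not applicable

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        partnerless = self.category in {"ECF_alone", "ungrouped"}
        if partnerless != (self.partner_gene_id is None):
            raise ValueError(
                f"{self.ecf_gene_id}: partner_gene_id must be None iff the "
                f"category is ECF_alone or ungrouped (got {self.category})"
            )
        if self.partner_gene_id is None:
            self.promoter_on_coe = None


def classify_coe(domains: Iterable[str]) -> str:
    """Type a protein as COE from its set of Pfam-style domain names.

    When domains from several families co-occur, the precedence is
    carboxymuconolactone decarboxylase > oxidoreductase > epimerase >
    cupin_hypothetical.  Unknown domains map to ``"none"``.
    """
    names = set(domains)
    if names & CARBOXYMUCONOLACTONE_DOMAINS:
        return "carboxymuconolactone_decarboxylase"
    if names & OXIDOREDUCTASE_DOMAINS:
        return "oxidoreductase"
    if names & EPIMERASE_DOMAINS:
        return "epimerase"
    if any(name.startswith("Cupin") for name in names):
        return "cupin_hypothetical"
    return "none"


def _is_hypothetical(gene: GeneRecord) -> bool:
    return "hypothetical" in gene.product.lower()


def classify_context(
    ecf: GeneRecord,
    annotation: Sequence[GeneRecord],
    domain_table: Mapping[str, Iterable[str]],
    max_partner_rank: int = 1,
) -> LocusContext:
    """Classify the genomic context of one ECF41 gene.

    The nearest COE-typed gene within ``max_partner_rank`` neighbors on
    either side determines the category; upstream (relative to the ECF
    gene's own strand) is preferred at equal rank.  With no COE partner, an
    immediate neighbor annotated as a hypothetical product yields
    ``ungrouped``; otherwise the locus is an orphan (``ECF_alone``).  Genes
    on other replicons are never neighbors.
    """
    if ecf.role != "ECF41":
        raise ValueError(f"{ecf.gene_id} is not an ECF41 gene")
    same_replicon = sorted(
        (g for g in annotation if g.replicon_id == ecf.replicon_id),
        key=lambda g: (g.start, g.end, g.gene_id),
    )
    try:
        idx = next(
            i for i, g in enumerate(same_replicon) if g.gene_id == ecf.gene_id
        )
    except StopIteration:
        raise KeyError(f"ECF gene {ecf.gene_id} absent from annotation") from None

    def neighbor(side: str, rank: int) -> Optional[GeneRecord]:
        # side is "left"/"right" in forward coordinates
        j = idx - rank if side == "left" else idx + rank
        if 0 <= j < len(same_replicon):
            return same_replicon[j]
        return None

    # Upstream of the ECF gene is to the left in forward coordinates for a
    # + strand gene and to the right for a - strand gene.
    up_side, down_side = ("left", "right") if ecf.strand == "+" else ("right", "left")

    for rank in range(1, max_partner_rank + 1):
        for side, is_upstream in ((up_side, True), (down_side, False)):
            gene = neighbor(side, rank)
            if gene is None:
                continue
            coe_class = classify_coe(domain_table.get(gene.gene_id, ()))
            if coe_class not in PARTNER_CLASSES:
                continue
            same_strand = gene.strand == ecf.strand
            if same_strand:
                category = "COE_up_same" if is_upstream else "COE_down_same"
            else:
                category = "divergent" if is_upstream else "convergent"
            return LocusContext(
                ecf_gene_id=ecf.gene_id,
                category=category,
                partner_gene_id=gene.gene_id,
                partner_coe_class=coe_class,
            )

    for side in (up_side, down_side):
        gene = neighbor(side, 1)
        if gene is not None and _is_hypothetical(gene):
            return LocusContext(ecf_gene_id=ecf.gene_id, category="ungrouped")
    return LocusContext(ecf_gene_id=ecf.gene_id, category="ECF_alone")


def tabulate_contexts(loci: Sequence[LocusContext]) -> pd.DataFrame:
    """Per-category counts, integer percentages, and promoter tallies.

    Returns a DataFrame in the fixed category order with columns
    ``category, arrows, count, pct, p_ecf, p_coe``; ``p_*`` columns count
    loci whose ECF/COE gene carries the promoter motif (``p_coe`` is NA for
    partnerless categories).
    """
    if len(loci) == 0:
        raise ValueError("no loci to tabulate")
    total = len(loci)
    rows = []
    for category in CATEGORIES:
        members = [lc for lc in loci if lc.category == category]
        p_ecf = sum(lc.promoter_on_ecf for lc in members)
        coe_flags = [lc.promoter_on_coe for lc in members if lc.promoter_on_coe is not None]
        rows.append(
            {
                "category": category,
                "arrows": ARROWS[category],
                "count": len(members),
                "pct": round(100.0 * len(members) / total),
                "p_ecf": p_ecf,
                "p_coe": sum(coe_flags) if coe_flags else pd.NA,
            }
        )
    return pd.DataFrame(rows)


def _default_species_key(organism: str) -> str:
    # genus + species epithet; the remainder of the label names the strain
    return " ".join(organism.split()[:2])


def dereplicate(
    proteins: Iterable[tuple],
    species_key=_default_species_key,
) -> list:
    """Drop redundant proteins, keeping one sequenced strain per species.

    ``proteins`` holds ``(protein_id, organism, sequence)`` tuples where the
    organism label carries the strain (e.g. ``"Bacillus licheniformis
    DSM13"``).  For each species (default key: first two tokens of the
    label) only the strain with the lexicographically smallest full label
    is retained; input order is preserved otherwise.
    """
    records = list(proteins)
    keep_strain: dict[str, str] = {}
    for _pid, organism, _seq in records:
        sp = species_key(organism)
        if sp not in keep_strain or organism < keep_strain[sp]:
            keep_strain[sp] = organism
    return [r for r in records if keep_strain[species_key(r[1])] == r[1]]
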