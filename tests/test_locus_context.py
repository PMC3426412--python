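"""Neighborhood classification, COE typing, tabulation, dereplication."""

import pandas as pd
import pytest

from ecf41.locus_context import (
    GeneRecord,
    LocusContext,
    classify_coe,
    classify_context,
    dereplicate,
    tabulate_contexts,
)


@pytest.mark.parametrize(
    "domains, expected",
    [
        ({"PF02627"}, "carboxymuconolactone_decarboxylase"),
        ({"FAD_binding_3", "Pyridox_oxidase"}, "oxidoreductase"),
        ({"NmrA"}, "epimerase"),
        ({"PF01370"}, "epimerase"),
        ({"Cupin_2"}, "cupin_hypothetical"),
        (set(), "none"),
        ({"DUF1234", "ABC_tran"}, "none"),
        # precedence when families co-occur
        ({"PF02627", "NmrA", "FMN_red"}, "carboxymuconolactone_decarboxylase"),
        ({"Epimerase", "Oxidored_FMN"}, "oxidoreductase"),
    ],
)
def test_classify_coe(domains, expected):
    assert classify_coe(domains) == expected


def _gene(gid, start, end, strand, role="other", product="MFS permease"):
    return GeneRecord(gid, "chr", start, end, strand, role, product)


DOMAINS = {"coe": ["PF02627"]}


@pytest.mark.parametrize(
    "ecf_strand, coe_strand, coe_first, expected",
    [
        # COE left of a + strand ECF gene == upstream
        ("+", "+", True, "COE_up_same"),
        ("+", "+", False, "COE_down_same"),
        ("+", "-", False, "convergent"),   # >ECF> <COE<
        ("+", "-", True, "divergent"),     # <COE< >ECF> read as <ECF< >COE>
        # mirror images on the - strand (upstream is to the right)
        ("-", "-", False, "COE_up_same"),
        ("-", "-", True, "COE_down_same"),
        ("-", "+", True, "convergent"),
        ("-", "+", False, "divergent"),
    ],
)
def test_classify_context_arrangements(ecf_strand, coe_strand, coe_first, expected):
    if coe_first:
        coe = _gene("coe", 1000, 1800, coe_strand)
        ecf = _gene("ecf", 1900, 2600, ecf_strand, role="ECF41")
    else:
        ecf = _gene("ecf", 1000, 1800, ecf_strand, role="ECF41")
        coe = _gene("coe", 1900, 2600, coe_strand)
    lc = classify_context(ecf, [ecf, coe], DOMAINS)
    assert lc.category == expected
    assert lc.partner_gene_id == "coe"
    assert lc.partner_coe_class == "carboxymuconolactone_decarboxylase"


def test_lone_ecf_gene_is_orphan():
    ecf = _gene("ecf", 500, 1200, "+", role="ECF41")
    lc = classify_context(ecf, [ecf], {})
    assert lc.category == "ECF_alone" and lc.partner_gene_id is None


def test_hypothetical_neighbor_without_coe_is_ungrouped():
    ecf = _gene("ecf", 1000, 1700, "+", role="ECF41")
    hyp = _gene("hyp", 1750, 2300, "+", product="conserved hypothetical protein")
    lc = classify_context(ecf, [ecf, hyp], {})
    assert lc.category == "ungrouped" and lc.partner_gene_id is None


def test_non_coe_non_hypothetical_neighbor_is_orphan():
    ecf = _gene("ecf", 1000, 1700, "+", role="ECF41")
    other = _gene("oth", 1750, 2300, "+", product="ABC transporter")
    assert classify_context(ecf, [ecf, other], {}).category == "ECF_alone"


def test_partner_beyond_rank_found_only_with_larger_rank():
    ecf = _gene("ecf", 1000, 1700, "+", role="ECF41")
    mid = _gene("mid", 1750, 2200, "+", product="conserved hypothetical protein")
    coe = _gene("coe", 2250, 2900, "+")
    ann = [ecf, mid, coe]
    assert classify_context(ecf, ann, DOMAINS, max_partner_rank=1).category == "ungrouped"
    assert classify_context(ecf, ann, DOMAINS, max_partner_rank=2).category == "COE_down_same"


def test_genes_on_other_replicons_are_not_neighbors():
    ecf = _gene("ecf", 1000, 1700, "+", role="ECF41")
    coe = GeneRecord("coe", "chr2", 1750, 2400, "+", "other", "x")
    assert classify_context(ecf, [ecf, coe], DOMAINS).category == "ECF_alone"


def test_missing_ecf_gene_raises():
    ecf = _gene("ecf", 1000, 1700, "+", role="ECF41")
    with pytest.raises(KeyError):
        classify_context(ecf, [], DOMAINS)


def test_non_ecf_query_rejected():
    gene = _gene("g", 1, 10, "+")
    with pytest.raises(ValueError):
        classify_context(gene, [gene], {})


def _flip(genes, length):
    """Reverse-complement a replicon's annotation."""
    return [
        GeneRecord(
            g.gene_id, g.replicon_id,
            length - g.end + 1, length - g.start + 1,
            "-" if g.strand == "+" else "+",
            g.role, g.product,
        )
        for g in genes
    ]


def test_classification_invariant_under_reverse_complement(dataset_small):
    length = dataset_small.config.replicon_length
    genes = dataset_small.genes
    flipped = _flip(genes, length)
    flipped_by_id = {g.gene_id: g for g in flipped}
    by_id = {g.gene_id: g for g in genes}
    for lt in dataset_small.truth.loci:
        fwd = classify_context(by_id[lt.ecf_gene_id], genes, dataset_small.domains)
        rev = classify_context(
            flipped_by_id[lt.ecf_gene_id], flipped, dataset_small.domains
        )
        assert fwd.category == rev.category
        assert fwd.partner_gene_id == rev.partner_gene_id


def test_noiseless_classification_recovers_every_truth_category(dataset_1000):
    by_id = {g.gene_id: g for g in dataset_1000.genes}
    for lt in dataset_1000.truth.loci:
        lc = classify_context(by_id[lt.ecf_gene_id], dataset_1000.genes,
                              dataset_1000.domains)
        assert lc.category == lt.category
        assert lc.partner_gene_id == lt.partner_gene_id


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------

def _loci_from_counts(table: pd.DataFrame):
    """Expand the printed count table into LocusContext objects."""
    loci = []
    k = 0
    for row in table.to_dict("records"):
        partnered = row["category"] not in {"ECF_alone", "ungrouped"}
        p_ecf = 0 if pd.isna(row["p_ecf"]) else int(row["p_ecf"])
        p_coe = 0 if pd.isna(row["p_coe"]) else int(row["p_coe"])
        for i in range(int(row["count"])):
            loci.append(
                LocusContext(
                    ecf_gene_id=f"ecf{k:04d}",
                    category=row["category"],
                    partner_gene_id=f"coe{k:04d}" if partnered else None,
                    promoter_on_ecf=i < p_ecf,
                    promoter_on_coe=(i < p_coe) if partnered else None,
                )
            )
            k += 1
    return loci


def test_tabulate_printed_context_counts(context_counts):
    loci = _loci_from_counts(context_counts)
    summary = tabulate_contexts(loci)
    assert summary["count"].sum() == 373
    row = summary.set_index("category")
    assert row.loc["ECF_alone", "count"] == 126
    assert row.loc["ECF_alone", "pct"] == 34
    assert row.loc["COE_up_same", "pct"] == 29
    assert row.loc["divergent", "p_ecf"] == 36
    assert row.loc["COE_up_same", "p_coe"] == 97
    # percentages sum to 100 up to rounding
    assert abs(summary["pct"].sum() - 100) <= len(summary) // 2


def test_tabulate_counts_conserved(dataset_small):
    by_id = {g.gene_id: g for g in dataset_small.genes}
    loci = [
        classify_context(by_id[lt.ecf_gene_id], dataset_small.genes,
                         dataset_small.domains)
        for lt in dataset_small.truth.loci
    ]
    summary = tabulate_contexts(loci)
    assert summary["count"].sum() == len(loci)


def test_tabulate_single_locus():
    lc = LocusContext("e1", "divergent", "c1")
    summary = tabulate_contexts([lc]).set_index("category")
    assert summary.loc["divergent", "pct"] == 100
    assert (summary.drop("divergent")["count"] == 0).all()


def test_tabulate_empty_raises():
    with pytest.raises(ValueError):
        tabulate_contexts([])


# ---------------------------------------------------------------------------
# dereplication
# ---------------------------------------------------------------------------

def test_dereplicate_keeps_one_strain_per_species():
    records = [
        ("p1", "Bacillus licheniformis DSM13", "MA"),
        ("p2", "Bacillus licheniformis ATCC14580", "MA"),
        ("p3", "Rhodobacter sphaeroides 2.4.1", "MC"),
    ]
    kept = dereplicate(records)
    assert [r[0] for r in kept] == ["p2", "p3"]  # ATCC14580 < DSM13


def test_dereplicate_distinct_species_is_identity():
    records = [
        ("p1", "Bacillus licheniformis DSM13", "MA"),
        ("p2", "Bacillus subtilis W168", "MC"),
        ("p3", "Rhodobacter sphaeroides 2.4.1", "MD"),
    ]
    assert dereplicate(records) == records


def test_dereplicate_five_species_three_strains_two_proteins():
    records = [
        (f"sp{s}_st{t}_p{p}", f"Genus species{s} strain{t}", "M")
        for s in range(5)
        for t in range(3)
        for p in range(2)
    ]
    kept = dereplicate(records)
    assert len(kept) == 10
    assert all("strain0" in r[1] for r in kept)
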