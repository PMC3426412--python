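"""Plain-text readers and writers shared across the pipeline.

Everything the pipeline persists between stages is diffable text: FASTA,
GFF3 (1-based inclusive, strand in column 7), tab-separated tables, JSON.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ecf41.locus_context import GeneRecord


def read_fasta(path) -> dict[str, str]:
    """FASTA records as an ordered id -> sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path, width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_alignment_fasta(path) -> list[tuple[str, str]]:
    """Aligned FASTA as (id, sequence) pairs, order preserved."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_gff3(
    genes: Sequence[GeneRecord],
    path,
    replicon_lengths: Mapping[str, int] | None = None,
    source: str = "ecf41",
) -> None:
    """Write gene features as GFF3 with ID/product/role attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if replicon_lengths:
            for rid, length in replicon_lengths.items():
                fh.write(f"##sequence-region {rid} 1 {length}\n")
        for g in sorted(genes, key=lambda g: (g.replicon_id, g.start, g.gene_id)):
            attrs = f"ID={g.gene_id};product={g.product};role={g.role}"
            fh.write(
                f"{g.replicon_id}\t{source}\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_gff3(path) -> list[GeneRecord]:
    """Read gene features from GFF3 (via gffutils, in-memory database)."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        genes.append(
            GeneRecord(
                gene_id=feat.id,
                replicon_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                role=feat.attributes.get("role", ["other"])[0],
                product=feat.attributes.get("product", [""])[0],
            )
        )
    return genes


def write_domain_table(domains: Mapping[str, Sequence[str]], path) -> None:
    """TSV of protein_id and comma-separated domain names."""
    with open(path, "w") as fh:
        fh.write("protein_id\tdomains\n")
        for pid in sorted(domains):
            fh.write(f"{pid}\t{','.join(domains[pid])}\n")


def read_domain_table(path) -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_id"):
            raise ValueError(f"{path}: missing domain-table header")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            pid, _, names = line.partition("\t")
            table[pid] = [n for n in names.split(",") if n]
    return table


def write_label_table(labels: Mapping[str, str], path, value_name: str = "phylum") -> None:
    with open(path, "w") as fh:
        fh.write(f"id\t{value_name}\n")
        for key in sorted(labels):
            fh.write(f"{key}\t{labels[key]}\n")


def read_label_table(path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path) as fh:
        fh.readline()  # header
        for line in fh:
            line = line.rstrip("\n")
            if line:
                key, _, value = line.partition("\t")
                labels[key] = value
    return labels


def write_hits_bed(hits, path) -> None:
    """BED-like TSV (replicon, start0, end, name, score, strand)."""
    with open(path, "w") as fh:
        for i, h in enumerate(hits, 1):
            fh.write(
                f"{h.replicon_id}\t{h.start - 1}\t{h.end}\thit{i:05d}\t"
                f"{h.relative_score:.4f}\t{h.strand}\n"
            )


def write_hits_table(hits, path) -> None:
    """Detailed hit TSV with spacer, sequence, target, and UTR proxy."""
    cols = [
        "replicon_id", "strand", "start", "end", "minus35_start", "spacer",
        "score", "relative_score", "site_sequence", "target_gene_id", "utr_proxy",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            values = [getattr(h, c) for c in cols]
            fh.write(
                "\t".join(
                    f"{v:.4f}" if isinstance(v, float) else ("" if v is None else str(v))
                    for v in values
                )
                + "\n"
            )
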