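"""Loaders for the packaged reference tables.

Three small text fixtures ship with the package: the per-phylum
distribution of the 373 dereplicated ECF41 proteins, the genomic-context /
promoter-occurrence counts, and the 19 candidate target promoter sequences
(15 from *Bacillus licheniformis*, 4 from *Rhodobacter sphaeroides*) with
their aligned spacing (hyphens) and 5'UTR lengths, plus the C-terminal
truncation coordinates of the two experimentally dissected proteins.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd
from Bio import SeqIO

MINUS35_WIDTH = 7
MINUS10_WIDTH = 4


def _data_path(name: str):
    return resources.files("ecf41.data").joinpath(name)


def load_phylum_distribution() -> pd.DataFrame:
    """Per-phylum counts of ECF41 proteins and species coverage."""
    with resources.as_file(_data_path("phylum_distribution.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_context_counts() -> pd.DataFrame:
    """Genomic-context category counts with promoter-occurrence tallies."""
    with resources.as_file(_data_path("context_counts.tsv")) as path:
        return pd.read_csv(path, sep="\t")


@dataclass(frozen=True)
class CandidatePromoter:
    """One candidate target promoter from the genome-wide scan tables."""

    gene: str
    organism: str
    utr: int
    aligned_sequence: str  # hyphens pad the spacer to the common width
    tested: bool

    @property
    def sequence(self) -> str:
        return self.aligned_sequence.replace("-", "")

    @property
    def minus35(self) -> str:
        return self.sequence[:MINUS35_WIDTH]

    @property
    def minus10(self) -> str:
        return self.sequence[-MINUS10_WIDTH:]

    @property
    def spacer(self) -> int:
        return len(self.sequence) - MINUS35_WIDTH - MINUS10_WIDTH


def load_candidate_promoters(organism: str | None = None) -> list[CandidatePromoter]:
    """The printed candidate promoters, optionally filtered by organism
    (``"Bacillus_licheniformis"`` or ``"Rhodobacter_sphaeroides"``)."""
    out = []
    with resources.as_file(_data_path("candidate_promoters.fasta")) as path:
        for rec in SeqIO.parse(str(path), "fasta"):
            fields = dict(
                kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
            )
            out.append(
                CandidatePromoter(
                    gene=rec.id,
                    organism=fields["organism"],
                    utr=int(fields["utr"]),
                    aligned_sequence=str(rec.seq),
                    tested=fields.get("tested") == "yes",
                )
            )
    if organism is not None:
        out = [c for c in out if c.organism == organism]
    return out


def load_truncation_table() -> pd.DataFrame:
    """Sigma4 boundaries and C-terminal truncation points of the two
    experimentally dissected ECF41 proteins."""
    with resources.as_file(_data_path("ecf41_truncations.tsv")) as path:
        return pd.read_csv(path, sep="\t")
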