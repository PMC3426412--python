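"""Signature features of ECF41 sigma-factor proteins.

ECF sigma factors carry only the sigma2 and sigma4 domains.  The ECF41
group adds two diagnostics: a highly conserved WLPEP motif in the
sigma2-sigma4 linker, and a C-terminal extension of roughly 100 residues
beyond sigma4 containing several conserved blocks.  Domain boundaries are
user-provided annotations (e.g. from SMART-style architecture calls), not
inferred here; block detection is generic conservation calling over an
alignment, with no hard-coded block sequences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class ArchitectureAnnotation:
    """Region boundaries of one ECF41 protein (1-based residue indices)."""

    protein_id: str
    sigma2_end: int
    sigma4_end: int
    extension_end: int
    source: str = "provided"

    def __post_init__(self) -> None:
        if not 0 < self.sigma2_end < self.sigma4_end <= self.extension_end:
            raise ValueError(
                f"{self.protein_id}: boundaries must satisfy "
                "0 < sigma2_end < sigma4_end <= extension_end"
            )


@dataclass
class ConservedBlock:
    """A maximal run of conserved alignment columns (1-based, inclusive)."""

    start_column: int
    end_column: int
    mean_conservation: float
    consensus: str

    @property
    def width(self) -> int:
        return self.end_column - self.start_column + 1


def find_linker_motif(
    sequence: str, pattern: str = "WLPEP", max_mismatch: int = 0
) -> Optional[int]:
    """Leftmost 1-based position of ``pattern`` allowing up to
    ``max_mismatch`` substitutions, or None.

    Position-equivariant: prepending k residues shifts the result by k.
    """
    seq = sequence.upper()
    pat = pattern.upper()
    if len(pat) > len(seq):
        return None
    for i in range(len(seq) - len(pat) + 1):
        mism = 0
        for a, b in zip(seq[i : i + len(pat)], pat):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        if mism <= max_mismatch:
            return i + 1
    return None


def column_conservation(records: Sequence[tuple[str, str]]) -> list[float]:
    """Per-column plurality-residue frequency (gap-plurality columns score 0)."""
    if not records:
        raise ValueError("empty alignment")
    length = len(records[0][1])
    if any(len(seq) != length for _id, seq in records):
        raise ValueError("aligned sequences must have equal length")
    n = len(records)
    scores = []
    for j in range(length):
        counts = Counter(seq[j].upper() for _id, seq in records)
        residue_counts = {c: k for c, k in counts.items() if c not in GAP_CHARS}
        scores.append(max(residue_counts.values()) / n if residue_counts else 0.0)
    return scores


def conservation_blocks(
    records: Sequence[tuple[str, str]],
    window: int = 6,
    threshold: float = 0.8,
) -> list[ConservedBlock]:
    """Maximal runs of >= ``window`` consecutive columns whose plurality
    frequency is >= ``threshold``, as conserved blocks with a plurality
    consensus string."""
    if len(records) < 5:
        raise ValueError("conservation calling needs at least 5 sequences")
    scores = column_conservation(records)
    blocks: list[ConservedBlock] = []
    run_start = None
    for j, score in enumerate(scores + [-1.0]):  # sentinel closes final run
        if score >= threshold:
            if run_start is None:
                run_start = j
            continue
        if run_start is not None and j - run_start >= window:
            cols = range(run_start, j)
            cons = "".join(
                Counter(
                    seq[c].upper() for _id, seq in records
                    if seq[c] not in GAP_CHARS
                ).most_common(1)[0][0]
                for c in cols
            )
            blocks.append(
                ConservedBlock(
                    start_column=run_start + 1,
                    end_column=j,
                    mean_conservation=sum(scores[c] for c in cols) / len(cols),
                    consensus=cons,
                )
            )
        run_start = None
    return blocks


def c_terminal_extension_length(
    sequence: str, architecture: ArchitectureAnnotation
) -> int:
    """Residue count beyond sigma4: ``len(sequence) - sigma4_end``."""
    if architecture.sigma4_end > len(sequence):
        raise ValueError(
            f"{architecture.protein_id}: sigma4_end {architecture.sigma4_end} "
            f"exceeds protein length {len(sequence)}"
        )
    return len(sequence) - architecture.sigma4_end
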