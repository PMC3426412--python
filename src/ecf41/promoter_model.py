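"""Bipartite -35/-10 promoter model: discovery, PWMs, and genome scanning.

The ECF41 target promoter is a two-block motif -- a 7 bp -35 element with
consensus TGTCACA and a 4 bp -10 element with consensus CGTC -- separated by
a variable spacer of 16 +/- 1 bp.  The model here is a pair of position
weight matrices plus a spacer length distribution and a background base
composition.  Scanning scores every (position, spacer, strand) as the summed
log2 odds of both blocks plus the log2 spacer probability, and reports hits
above a fraction of the attainable score range.

Scoring scale
-------------
A hit's raw score is ``sum log2(p/bg)`` over the two blocks (the spacer
sequence itself is not scored) plus ``log2 P(spacer)``.  The reporting
threshold is relative: a hit is kept when ``(score - min) / (max - min) >=
threshold``, where ``min``/``max`` are the worst/best attainable raw scores.
This min-max normalisation is the convention of PWM pattern scanners (e.g.
Virtual Footprint / PRODORIC); for sharp matrices a threshold on the raw
maximum alone would reject every site carrying even one substitution.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from ecf41.locus_context import GeneRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# minimal IUPAC code for a non-empty subset of {A,C,G,T}
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

UNIFORM_BACKGROUND = np.full(4, 0.25)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as integers (A=0 C=1 G=2 T=3, anything else 4)."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def build_pwm(
    sites: Sequence[str],
    background: Optional[np.ndarray] = None,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Estimate a PWM (width x 4, columns sum to 1) from aligned sites.

    Column probability for base ``b`` is
    ``(count_b + pseudocount * background_b) / (n + pseudocount)``, i.e. the
    pseudocount mass is distributed over the bases by the background.
    """
    if not sites:
        raise ValueError("no sites")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("aligned sites must have equal length")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    counts = np.zeros((width, 4))
    for s in sites:
        su = s.upper()
        if any(c not in _BASE_INDEX for c in su):
            raise ValueError(f"non-ACGT character in site {s!r}")
        for j, c in enumerate(su):
            counts[j, _BASE_INDEX[c]] += 1
    return (counts + pseudocount * bg) / (len(sites) + pseudocount)


def information_content(pwm: np.ndarray, background: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-position information content in bits: ``sum p*log2(p/bg)``."""
    pwm = np.asarray(pwm, float)
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pwm > 0, pwm * np.log2(pwm / bg), 0.0)
    return terms.sum(axis=1)


def consensus(pwm: np.ndarray, majority_threshold: float = 0.6) -> str:
    """Minimal IUPAC string covering, per column, every base whose
    probability is at least ``majority_threshold`` times the column maximum."""
    pwm = np.asarray(pwm, float)
    out = []
    for col in pwm:
        cutoff = majority_threshold * col.max()
        members = frozenset(BASES[i] for i in range(4) if col[i] >= cutoff)
        out.append(_IUPAC[members])
    return "".join(out)


@dataclass
class BipartiteMotifModel:
    """Two PWMs plus spacer distribution and background composition."""

    pwm35: np.ndarray
    pwm10: np.ndarray
    spacer_probs: dict[int, float]
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.pwm35 = np.asarray(self.pwm35, float)
        self.pwm10 = np.asarray(self.pwm10, float)
        self.background = np.asarray(self.background, float)
        for name, pwm in (("pwm35", self.pwm35), ("pwm10", self.pwm10)):
            if pwm.ndim != 2 or pwm.shape[1] != 4:
                raise ValueError(f"{name} must be width x 4")
            if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} columns must sum to 1")
            if (pwm < 0).any():
                raise ValueError(f"{name} has negative probabilities")
        if not math.isclose(sum(self.spacer_probs.values()), 1.0, abs_tol=1e-9):
            raise ValueError("spacer probabilities must sum to 1")

    @property
    def w35(self) -> int:
        return self.pwm35.shape[0]

    @property
    def w10(self) -> int:
        return self.pwm10.shape[0]

    @property
    def spacers(self) -> list[int]:
        return sorted(self.spacer_probs)

    def span(self, spacer: int) -> int:
        return self.w35 + spacer + self.w10

    @property
    def max_span(self) -> int:
        return self.span(max(self.spacers))

    #: per-position log-odds floor in bits; keeps zero-probability columns
    #: (possible in noiseless generator models) from dominating the score
    #: range used for min-max normalisation
    LOG_ODDS_FLOOR = -10.0

    def _log_odds(self, pwm: np.ndarray) -> np.ndarray:
        # rows 0..3 real bases, row 4 = N scores as background (0 log odds)
        with np.errstate(divide="ignore"):
            lo = np.log2(np.maximum(pwm, 1e-300) / self.background)
        lo = np.maximum(lo, self.LOG_ODDS_FLOOR)
        return np.vstack([lo.T, np.zeros(pwm.shape[0])])  # shape (5, width)

    def score_range(self, flat_spacer: bool = False) -> tuple[float, float]:
        """Worst and best attainable raw scores over all spacers."""
        lo35, lo10 = self._log_odds(self.pwm35), self._log_odds(self.pwm10)
        block_min = lo35[:4].min(axis=0).sum() + lo10[:4].min(axis=0).sum()
        block_max = lo35[:4].max(axis=0).sum() + lo10[:4].max(axis=0).sum()
        if flat_spacer:
            return block_min, block_max
        sp = np.log2([self.spacer_probs[s] for s in self.spacers])
        return block_min + sp.min(), block_max + sp.max()

    def consensus35(self, majority_threshold: float = 0.6) -> str:
        return consensus(self.pwm35, majority_threshold)

    def consensus10(self, majority_threshold: float = 0.6) -> str:
        return consensus(self.pwm10, majority_threshold)

    def total_information(self) -> float:
        return float(
            information_content(self.pwm35, self.background).sum()
            + information_content(self.pwm10, self.background).sum()
        )

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "pwm35": self.pwm35.tolist(),
            "pwm10": self.pwm10.tolist(),
            "spacer_probs": {str(k): v for k, v in self.spacer_probs.items()},
            "background": self.background.tolist(),
            "pseudocount": self.pseudocount,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, data: Mapping) -> "BipartiteMotifModel":
        return cls(
            pwm35=np.asarray(data["pwm35"], float),
            pwm10=np.asarray(data["pwm10"], float),
            spacer_probs={int(k): float(v) for k, v in data["spacer_probs"].items()},
            background=np.asarray(data["background"], float),
            pseudocount=float(data.get("pseudocount", 0.5)),
        )

    @classmethod
    def from_json(cls, path) -> "BipartiteMotifModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_meme(self) -> str:
        """MEME minimal-format text for both blocks (two MOTIF entries)."""
        lines = [
            "MEME version 4",
            "",
            "ALPHABET= ACGT",
            "",
            "Background letter frequencies",
            " ".join(f"{b} {f:.4f}" for b, f in zip(BASES, self.background)),
            "",
        ]
        for name, pwm in (("minus35", self.pwm35), ("minus10", self.pwm10)):
            lines.append(f"MOTIF {name}")
            lines.append(f"letter-probability matrix: alength= 4 w= {pwm.shape[0]}")
            for row in pwm:
                lines.append(" ".join(f"{p:.6f}" for p in row))
            lines.append("")
        return "\n".join(lines)


@dataclass
class PromoterSite:
    """A scored bipartite hit; coordinates 1-based inclusive, forward strand.

    ``minus35_start`` is the 5'-most base of the -35 element on the hit's own
    strand (equal to ``start`` on +, to ``end`` on -).  ``utr_proxy`` is the
    number of bases between the last -10 base and the start codon of the
    assigned gene; it stands in for the printed 5'UTR lengths, which were
    measured from experimentally mapped transcription starts.
    """

    replicon_id: str
    strand: str
    start: int
    end: int
    minus35_start: int
    spacer: int
    score: float
    relative_score: float
    site_sequence: str
    target_gene_id: Optional[str] = None
    utr_proxy: Optional[int] = None


@dataclass
class UpstreamWindow:
    """Sequence immediately upstream of a gene, 5'->3' on the gene's strand."""

    gene_id: str
    sequence: str
    window_length: int
    offset_of_window_end_from_start_codon: int = 0


def extract_upstream(gene: GeneRecord, replicon_seq: str, window: int = 250) -> UpstreamWindow:
    """Extract up to ``window`` bp upstream of a gene, truncating at the
    replicon boundary (a gene flush with the boundary yields a zero-length
    window)."""
    n = len(replicon_seq)
    if gene.end > n:
        raise ValueError(f"{gene.gene_id} extends beyond its replicon")
    if gene.strand == "+":
        lo = max(1, gene.start - window)
        seq = replicon_seq[lo - 1 : gene.start - 1]
    else:
        hi = min(n, gene.end + window)
        seq = reverse_complement(replicon_seq[gene.end : hi])
    return UpstreamWindow(gene_id=gene.gene_id, sequence=seq, window_length=len(seq))


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _block_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Raw scores of every placement of one block along an encoded sequence."""
    width = log_odds.shape[1]
    n = codes.size - width + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for j in range(width):
        scores += log_odds[codes[j : j + n], j]
    return scores


def _spacer_score_arrays(
    model: BipartiteMotifModel, codes: np.ndarray, flat_spacer: bool
) -> dict[int, np.ndarray]:
    """Raw scores of every placement, per spacer, on one strand."""
    lo35 = model._log_odds(model.pwm35)
    lo10 = model._log_odds(model.pwm10)
    s35 = _block_scores(codes, lo35)
    s10 = _block_scores(codes, lo10)
    out: dict[int, np.ndarray] = {}
    for spacer in model.spacers:
        offset = model.w35 + spacer
        n = codes.size - model.span(spacer) + 1
        if n <= 0:
            continue
        total = s35[:n] + s10[offset : offset + n]
        if not flat_spacer:
            total = total + math.log2(model.spacer_probs[spacer])
        out[spacer] = total
    return out


def scan(
    model: BipartiteMotifModel,
    replicon_seq: str,
    replicon_id: str = "",
    threshold: float = 0.8,
    both_strands: bool = True,
    flat_spacer: bool = False,
) -> list[PromoterSite]:
    """Scan a replicon for bipartite promoter hits.

    Hits with relative score (min-max normalised raw log-odds, see module
    docstring) at or above ``threshold`` are reported, sorted by position.
    Overlapping hits on the same strand are resolved by keeping the higher
    score, ties going to the smaller coordinate (then smaller spacer).
    Ambiguity characters score as background.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    smin, smax = model.score_range(flat_spacer)
    span_range = smax - smin
    raw_cutoff = smin + threshold * span_range
    L = len(replicon_seq)
    candidates: list[PromoterSite] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        seq = replicon_seq if strand == "+" else reverse_complement(replicon_seq)
        codes = encode(seq)
        for spacer, totals in _spacer_score_arrays(model, codes, flat_spacer).items():
            span = model.span(spacer)
            for i in np.nonzero(totals >= raw_cutoff)[0]:
                i = int(i)
                raw = float(totals[i])
                if strand == "+":
                    start, end = i + 1, i + span
                else:
                    start, end = L - (i + span) + 1, L - i
                candidates.append(
                    PromoterSite(
                        replicon_id=replicon_id,
                        strand=strand,
                        start=start,
                        end=end,
                        minus35_start=start if strand == "+" else end,
                        spacer=spacer,
                        score=raw,
                        relative_score=(raw - smin) / span_range,
                        site_sequence=seq[i : i + span],
                    )
                )
    return resolve_overlaps(candidates)


def resolve_overlaps(candidates: Sequence[PromoterSite]) -> list[PromoterSite]:
    """Keep the best hit among same-strand overlapping hits.

    Greedy by descending score, ties broken by smaller coordinate then
    smaller spacer; surviving hits are returned sorted by position.
    """
    kept: list[PromoterSite] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    ordered = sorted(candidates, key=lambda h: (-h.score, h.start, h.spacer))
    for hit in ordered:
        spans = occupied.setdefault((hit.replicon_id, hit.strand), [])
        if any(hit.start <= e and hit.end >= s for s, e in spans):
            continue
        spans.append((hit.start, hit.end))
        kept.append(hit)
    return sorted(kept, key=lambda h: (h.replicon_id, h.start, h.strand))


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------

def _window_sequences(windows: Sequence) -> list[str]:
    return [
        (w.sequence if isinstance(w, UpstreamWindow) else str(w)).upper()
        for w in windows
    ]


def _most_frequent_kmer(seqs: Sequence[str], k: int) -> str:
    counts: Counter = Counter()
    for s in seqs:
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if all(c in _BASE_INDEX for c in kmer):
                counts[kmer] += 1
    if not counts:
        raise ValueError("windows contain no scorable k-mers")
    best = max(counts.values())
    return min(k for k, v in counts.items() if v == best)


def _estimate_background(seqs: Sequence[str]) -> np.ndarray:
    counts = np.zeros(4)
    for s in seqs:
        codes = encode(s)
        for i in range(4):
            counts[i] += int((codes == i).sum())
    total = counts.sum()
    return counts / total if total else UNIFORM_BACKGROUND.copy()


def _placement_raw_score(
    model: BipartiteMotifModel, codes: np.ndarray, pos: int, spacer: int
) -> float:
    lo35 = model._log_odds(model.pwm35)
    lo10 = model._log_odds(model.pwm10)
    return float(
        sum(lo35[codes[pos + j], j] for j in range(model.w35))
        + sum(lo10[codes[pos + model.w35 + spacer + j], j] for j in range(model.w10))
        + math.log2(model.spacer_probs[spacer])
    )


def _best_placement(
    model: BipartiteMotifModel, codes: np.ndarray
) -> tuple[int, int]:
    """Best-scoring (0-based position, spacer) in one window; ties go to the
    smaller position, then the smaller spacer."""
    best = None
    for spacer, totals in _spacer_score_arrays(model, codes, False).items():
        i = int(np.argmax(totals))  # first (smallest-position) maximum
        key = (-float(totals[i]), i, spacer)
        if best is None or key < best[0]:
            best = (key, i, spacer)
    if best is None:
        raise ValueError("window shorter than the minimal site span")
    return best[1], best[2]


def _model_from_placements(
    seqs: Sequence[str],
    placements: Sequence[tuple[int, int]],
    w35: int,
    w10: int,
    spacers: Sequence[int],
    background: np.ndarray,
    pseudocount: float,
) -> BipartiteMotifModel:
    sites35, sites10, spacer_counts = [], [], Counter()
    for seq, (pos, spacer) in zip(seqs, placements):
        sites35.append(seq[pos : pos + w35])
        sites10.append(seq[pos + w35 + spacer : pos + w35 + spacer + w10])
        spacer_counts[spacer] += 1
    n = len(placements)
    spacer_probs = {
        s: (spacer_counts[s] + 1.0) / (n + len(spacers)) for s in spacers
    }
    return BipartiteMotifModel(
        pwm35=build_pwm(sites35, background, pseudocount),
        pwm10=build_pwm(sites10, background, pseudocount),
        spacer_probs=spacer_probs,
        background=background,
        pseudocount=pseudocount,
    )


def discover_bipartite_motif(
    windows: Sequence,
    w35: int = 7,
    w10: int = 4,
    spacer_range: tuple[int, int] = (15, 17),
    n_iters: int = 50,
    rng: Optional[np.random.Generator] = None,
    pseudocount: float = 0.5,
    background: Optional[np.ndarray] = None,
    low_information_threshold: float = 5.0,
    support_threshold: float = 0.5,
    _compute_null: bool = True,
) -> tuple[BipartiteMotifModel, list[tuple[int, int, int]], dict]:
    """Discover the bipartite motif by enumeration-seeded greedy refinement.

    The -35 block is seeded from the most frequent exact ``w35``-mer across
    the windows; the -10 block from the most frequent ``w10``-mer found at a
    valid spacer distance downstream of the seed occurrences.  Refinement
    then alternates (a) picking the best-scoring placement over all spacers
    in every window and (b) re-estimating both PWMs and the spacer
    distribution, until placements are stable or ``n_iters`` is reached.
    Because not every upstream window need contain the motif, a second
    phase restricts the model estimate to supporting windows -- those whose
    placement scores at least ``support_threshold`` times the best
    placement's raw log-odds -- and iterates that filter to stability, so
    motif-free windows stop diluting the matrices.  Deterministic; ``rng`` is accepted for interface symmetry
    with the stochastic modules but unused by the greedy refinement.

    Returns ``(model, placements, info)`` where placements are 1-based
    ``(window_index, position, spacer)`` covering every window,
    ``info["support"]`` lists the 1-based indices of supporting windows,
    and ``info`` also flags convergence and low information content.

    Greedy alignment inflates information content even on motif-free
    sequence (the best placements of anything align), so the noise level is
    estimated empirically: the same procedure is run once on letter-shuffled
    copies of the windows, and the model is flagged ``low_information`` when
    its total information exceeds that null by less than
    ``low_information_threshold`` bits.
    """
    seqs = _window_sequences(windows)
    spacers = list(range(spacer_range[0], spacer_range[1] + 1))
    min_len = w35 + max(spacers) + w10
    if len(seqs) < 5:
        raise ValueError("motif discovery needs at least 5 windows")
    if any(len(s) < w35 + min(spacers) + w10 for s in seqs):
        raise ValueError(f"all windows must be at least {w35 + min(spacers) + w10} bp")
    bg = _estimate_background(seqs) if background is None else np.asarray(background, float)

    seed35 = _most_frequent_kmer(seqs, w35)
    # initial alignment: anchor on the leftmost seed occurrence per window
    anchored: list[tuple[int, int]] = []  # (window index, position)
    ten_mers: Counter = Counter()
    for wi, s in enumerate(seqs):
        pos = s.find(seed35)
        if pos < 0:
            continue
        anchored.append((wi, pos))
        for sp in spacers:
            j = pos + w35 + sp
            if j + w10 <= len(s):
                ten_mers[s[j : j + w10]] += 1
    init_placements: dict[int, tuple[int, int]] = {}
    if anchored and ten_mers:
        best = max(ten_mers.values())
        seed10 = min(k for k, v in ten_mers.items() if v == best)
        for wi, pos in anchored:
            # spacer whose -10 word is closest to the seed (Hamming), ties low
            choices = []
            for sp in spacers:
                j = pos + w35 + sp
                if j + w10 <= len(seqs[wi]):
                    word = seqs[wi][j : j + w10]
                    ham = sum(a != b for a, b in zip(word, seed10))
                    choices.append((ham, sp))
            if choices:
                init_placements[wi] = (pos, min(choices)[1])
    if not init_placements:
        # no exact seed anywhere: fall back to position 1, smallest spacer
        init_placements = {wi: (0, spacers[0]) for wi in range(len(seqs))}

    used = sorted(init_placements)
    model = _model_from_placements(
        [seqs[i] for i in used],
        [init_placements[i] for i in used],
        w35, w10, spacers, bg, pseudocount,
    )

    codes = [encode(s) for s in seqs]
    placements = [None] * len(seqs)
    converged = False
    iterations = 0
    for iterations in range(1, n_iters + 1):
        new = [_best_placement(model, c) for c in codes]
        model = _model_from_placements(seqs, new, w35, w10, spacers, bg, pseudocount)
        if new == placements:
            converged = True
            break
        placements = new

    # phase 2: restrict the estimate to supporting windows
    support = list(range(len(seqs)))
    for _ in range(n_iters):
        raws = [
            _placement_raw_score(model, codes[wi], *placements[wi])
            for wi in range(len(seqs))
        ]
        best = max(raws)
        if best <= 0:
            break  # nothing scores above background; keep the full estimate
        cutoff = support_threshold * best
        new_support = [
            wi for wi in range(len(seqs)) if raws[wi] >= cutoff and raws[wi] > 0
        ]
        if len(new_support) < 5:
            break  # too few confident windows to re-estimate from
        candidate = _model_from_placements(
            [seqs[wi] for wi in new_support],
            [placements[wi] for wi in new_support],
            w35, w10, spacers, bg, pseudocount,
        )
        new_placements = [_best_placement(candidate, c) for c in codes]
        stable = new_support == support and new_placements == placements
        model, placements, support = candidate, new_placements, new_support
        if stable:
            break

    total_ic = model.total_information()
    noise_ic = None
    if _compute_null:
        shuffle_rng = rng if rng is not None else np.random.default_rng(0)
        shuffled = ["".join(shuffle_rng.permutation(list(s))) for s in seqs]
        null_model, _, _ = discover_bipartite_motif(
            shuffled, w35=w35, w10=w10, spacer_range=spacer_range,
            n_iters=n_iters, pseudocount=pseudocount, background=bg,
            support_threshold=support_threshold, _compute_null=False,
        )
        noise_ic = null_model.total_information()
    info = {
        "converged": converged,
        "iterations": iterations,
        "support": [wi + 1 for wi in support],
        "total_information_bits": total_ic,
        "noise_ic_bits": noise_ic,
        "low_information": (
            noise_ic is not None
            and total_ic < noise_ic + low_information_threshold
        ),
    }
    result = [(wi + 1, pos + 1, spacer) for wi, (pos, spacer) in enumerate(placements)]
    return model, result, info


# ---------------------------------------------------------------------------
# summaries and gene assignment
# ---------------------------------------------------------------------------

def spacer_stats(sites: Sequence) -> dict:
    """Integer histogram plus median/mode/range of spacer lengths.

    Accepts PromoterSites, ``(window, pos, spacer)`` placements, or bare
    integers.
    """
    spacers = []
    for s in sites:
        if isinstance(s, PromoterSite):
            spacers.append(s.spacer)
        elif isinstance(s, (tuple, list)):
            spacers.append(int(s[-1]))
        else:
            spacers.append(int(s))
    if not spacers:
        raise ValueError("no spacers to summarise")
    counts = dict(sorted(Counter(spacers).items()))
    modal = max(counts.values())
    return {
        "counts": counts,
        "median": float(np.median(spacers)),
        "mode": min(k for k, v in counts.items() if v == modal),
        "min": min(spacers),
        "max": max(spacers),
        "n": len(spacers),
    }


def assign_hits(
    sites: Sequence[PromoterSite],
    annotation: Sequence[GeneRecord],
    window: int = 250,
) -> list[PromoterSite]:
    """Assign each hit to the gene whose upstream window wholly contains it.

    A hit qualifies for a gene only on the gene's own strand.  When several
    genes qualify, the nearest start codon wins (ties by gene id).
    ``utr_proxy`` is the base count between the -10 element's last base and
    the start codon.  Unassigned hits keep ``target_gene_id=None``.
    """
    out = []
    for hit in sites:
        best = None
        for gene in annotation:
            if gene.replicon_id != hit.replicon_id or gene.strand != hit.strand:
                continue
            if gene.strand == "+":
                lo, hi = max(1, gene.start - window), gene.start - 1
                dist = gene.start - hit.end - 1
            else:
                lo, hi = gene.end + 1, gene.end + window
                dist = hit.start - gene.end - 1
            if hit.start >= lo and hit.end <= hi:
                key = (dist, gene.gene_id)
                if best is None or key < best[0]:
                    best = (key, gene, dist)
        if best is None:
            out.append(replace(hit, target_gene_id=None, utr_proxy=None))
        else:
            out.append(replace(hit, target_gene_id=best[1].gene_id, utr_proxy=best[2]))
    return out
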