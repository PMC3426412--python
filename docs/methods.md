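# Methods

## The analysis in one paragraph

ECF41-group σ factors are classified by their gene neighborhood (a COE
partner gene — carboxymuconolactone decarboxylase, oxidoreductase, or
epimerase — up- or downstream, co-oriented or not, or absent), their target
promoter is modeled as a bipartite motif (7 bp −35 block, 4 bp −10 block,
15–17 bp spacer) learned from 250 bp upstream windows and scanned
genome-wide as a log-odds profile, and their protein sequences are placed
on a neighbor-joining tree to ask whether they cluster by phylum.  Because
the original protein collection is a 2010 database snapshot that cannot be
re-retrieved, the pipeline runs on synthetic genomes whose statistical
structure matches the published tabulations, with printed tables and
promoter sequences shipped as fixtures for the desk-scale checks.

## Genomic-context classification

A neighbor qualifies as a COE partner when its domain set intersects one of
three vocabularies: PF02627/CMD (carboxymuconolactone decarboxylases); the
flavin/NAD(P)H families Oxidored_FMN, Flavodoxin_2, Pyr_redox(_2),
FAD_binding_2/3/4, Amino_oxidase, Pyridox_oxidase, FMN_red
(oxidoreductases); NmrA (PF05368) or Epimerase (PF01370).  When families
co-occur the class is resolved by the fixed precedence carboxymuconolactone
> oxidoreductase > epimerase > cupin, chosen purely for determinism.
Cupin-domain hypotheticals are typed for reporting but do not define a COE
context — the arrangement table treats them like other hypothetical-product
neighbors.

Orientation is evaluated relative to the ECF gene's own strand, so
classification is invariant under reverse-complementing a replicon (a
tested property).  The partner search looks `max_partner_rank` genes to
each side (default 1, i.e. immediate neighbors; rank 2 captures
"gene-between" arrangements), preferring upstream at equal rank — the
upstream-first preference is this package's tie-break, not an established
rule.  With no COE in range, an immediate neighbor whose product contains
"hypothetical" (case-insensitive) yields `ungrouped`; otherwise the locus
is an orphan.  Dereplication keeps one strain per species, selecting the
lexicographically smallest strain label; the species key defaults to the
first two tokens of the organism name.

## The bipartite promoter model

The model is two PWMs plus a spacer distribution over {15, 16, 17} and a
background base composition.  Estimation uses
`p(b) = (count_b + λ·bg_b) / (n + λ)` with pseudocount λ = 0.5 distributed
by the background, so probabilities are positive whenever λ > 0.  Column
information content is the Kullback–Leibler divergence from background in
bits.  A consensus letter covers every base whose probability reaches 0.6×
the column maximum (the 0.6 keeps a 7/15-vs-4/15 plurality column a single
letter rather than an ambiguity code, which matches how the candidate-table
heptamers read).

**Scanning.**  A placement's raw score is the summed log₂ odds of both
blocks (the spacer sequence itself is not scored) plus log₂ P(spacer), so a
16 bp spacer outranks 15/17 at equal block match; a flag switches to flat
spacer scoring.  Per-position log-odds are floored at −10 bits so that
zero-probability columns (possible in noiseless generator models) do not
dominate the score range.  Hits are reported above a *relative* score
threshold: `(raw − min) / (max − min) ≥ t` with t = 0.8 by default, where
min/max are the worst/best attainable raw scores.  This min-max
normalisation is the convention of PWM pattern scanners (Virtual
Footprint-style "relative score"); thresholding on the raw maximum alone
would reject any site carrying a single substitution under a sharp matrix
and makes high recall on noisy sites unattainable.  The default t = 0.8 is
deliberately permissive (it tolerates roughly two substitutions): recall of
planted sites at 5% per-position noise stays ≥ 95–99%, at the cost of
background hits that a stricter t (≈ 0.9) removes.  Overlapping same-strand
hits are resolved greedily by score, ties to the smaller coordinate, then
the smaller spacer.  Ambiguity characters score zero (background).  The
scanner is verified against a brute-force enumeration oracle on every
fixture up to 5 kb.

**Discovery.**  Enumeration-seeded greedy refinement: the −35 is seeded
from the most frequent exact 7-mer across windows, the −10 from the most
frequent 4-mer at a valid spacer distance downstream of the seed
occurrences; refinement alternates best-placement assignment (all spacers,
ties to smaller position/spacer) and re-estimation until placements are
stable (cap 50 iterations).  Since not every upstream window contains the
motif, a second phase restricts the estimate to *supporting* windows —
those whose placement scores at least half the best placement's raw
log-odds — and iterates that filter to stability.  This mirrors building
the final matrix only from the regions where the motif was actually found,
and without it the matrices are visibly diluted by motif-free windows.
Greedy alignment inflates information content even on random sequence, so
the noise level is measured empirically: the identical procedure runs once
on letter-shuffled copies of the windows, and the result is flagged
low-information when it beats that null by less than 5 bits.  The whole
procedure is deterministic; the `rng` argument only feeds the shuffle null.

**Hit assignment.**  A hit belongs to a gene iff it lies wholly inside the
gene's 250 bp upstream window on the gene's strand; the nearest start codon
wins ties.  The reported `utr_proxy` is the distance from the last −10 base
to the start codon.  It is *not* a 5′UTR: transcription starts are mapped
experimentally and are not modeled here, so the proxy only brackets the
printed UTR lengths (promoter-to-ATG ≥ TSS-to-ATG).

## Phylogeny

Columns containing any gap are removed before distances are computed
(matching the gapless-alignment workflow of desk phylogenetics tools).  Two
distance models are provided: the uncorrected p-distance and its Poisson
correction −ln(1 − p), flagged infinite at saturation.  These are
documented stand-ins for Protdist's JTT model — the downstream question
(do tips cluster by phylum?) needs relative, not absolute, distances — and
are labelled as such.  Neighbor joining is the classical Saitou–Nei
agglomeration on the Q-criterion, with Q-ties broken by the smallest (i, j)
node pair, negative branch estimates clamped to zero with a warning, and
exact recovery of additive matrices (tested on 4- and 5-taxon cases and
cross-checked against an independent NJ implementation).  The
phylum-clustering score — the fraction of tips whose nearest tip by
patristic distance shares the phylum label, ties to the lexicographically
smallest tip — is an invented quantification of a qualitative by-eye claim
and is labelled as such in all outputs.  Tips from singleton phyla can
never match, which bounds the score below 1 on realistic draws.

## The synthetic genomes

The generator emulates the features the analysis depends on, with defaults
set to the published study conditions:

| parameter | default | basis |
|---|---|---|
| category proportions | 34/29/14/2/15/6 % | observed context distribution |
| promoter occurrence | per (category, role), e.g. 97/107 for COE in `>COE> >ECF>` | observed occurrence counts |
| spacer distribution | {15: 0.2, 16: 0.6, 17: 0.2} | 16 ± 1 bp, 16 modal; exact proportions unpublished |
| upstream window | 250 bp | the window the original screen used |
| planted blocks | TGTCACA / CGTC | the published consensus |
| phylum proportions | 252/84/15/11/4/2/2/1/1/1 of 373 | observed phylum counts |
| site mutation rate | 0 (noiseless) | noise level is an experiment knob |
| GC content | 0.45 | mid-range bacterial composition |

Gene geometry (lengths uniform on 300–1500 bp, operon gaps 20–80 bp,
inter-locus gaps 300–600 bp with a background gene always separating
consecutive loci, divergent pairs sharing a 160–300 bp region split in half
for planting) is invented — no gene geometry is published — and chosen so
that upstream windows of distinct same-strand genes stay disjoint, making
noiseless classification and hit assignment exactly recoverable.  Site
mutation replaces each position with probability μ by a uniformly random
base (so a fully mutated site still matches at ~25% of positions), which
makes the generator PWM `p = μ/4 + (1−μ)·δ(consensus)`.  Decoys are
isolated −35 or −10 half-sites kept at least one full site span away from
real sites and each other, so any full-site false positive is the
scanner's doing.  Promoter placement within the window is uniform.  ECF
proteins are drawn per phylum from independent random ancestors (length
270; σ2 end 80, σ4 end 170, hence a 100-residue extension) with 10%
within-phylum divergence and the WLPEP linker pinned — enough structure
for the tree and feature stages, nothing more.

What the generator does **not** emulate: codon structure, operonic
transcription, expression levels, realistic protein evolution (no
substitution matrix, no indels, star phylogenies within phyla), promoter
placement preferences, or any wet-lab readout.  Passing tests therefore
demonstrate that the implementations are correct and internally consistent
under the stated statistical assumptions — not that the method would
perform identically on real genomes, where neighbor spacing, domain
annotation noise, and motif degeneracy are all harsher.

## Numerical and design notes

* One RNG stream per simulation, seeded from the config; outputs are byte
  identical across runs at a fixed seed (tested).
* Coordinates are 1-based inclusive everywhere in I/O (GFF3 convention);
  reverse-strand site coordinates record the −35's 5′ base on the site's
  own strand.
* `tabulate_contexts` rounds percentages to integers, so they sum to 100
  only up to rounding, as in the reference table.
* The candidate-promoter fixture encodes the printed spacer-adjustment
  dashes; en-dashes of ambiguous width were resolved to two hyphens, which
  pads all 19 sequences to a common 28-column alignment.  All geometry
  statistics strip the dashes first, so this choice affects nothing
  measured.
* NJ is O(n³); the pipeline subsamples trees above 200 taxa (the analysis
  drivers and acceptance runs use 40–150 taxa, which build in seconds).
* Known limitation: with `max_partner_rank` > 1 on dense annotations, a
  neighbor locus's COE can be captured; the default rank 1 cannot.
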