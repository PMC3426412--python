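# ecf41 — genomic context, target promoters, and phylogeny of ECF41 σ factors

ECF41 is a widely distributed group of extracytoplasmic-function (ECF)
alternative σ factors with two oddities: no anti-σ factor gene nearby, and a
~100-residue C-terminal extension fused to the σ2–σ4 core.  Their structural
genes sit next to genes for carboxymuconolactone decarboxylases,
oxidoreductases, or epimerases (collectively **COE**), and the only known
targets of ECF41-dependent transcription are preceded by a distinctive
bipartite promoter:

```
-35 element        spacer        -10 element
 TGTCACA        n = 16 ± 1 bp       CGTC
```

This package re-implements the comparative-genomics side of that analysis as
a tested, reusable pipeline:

* **`ecf41.locus_context`** — classify each ECF41 gene's neighborhood into
  the five conserved arrangements (`>ECF>`, `>COE> >ECF>`, `>ECF> >COE>`,
  `>ECF> <COE<`, `<ECF< >COE>`) plus *ungrouped*, typing partners as COE
  from Pfam-style domain content; tabulate counts, percentages, and
  promoter occurrence.
* **`ecf41.promoter_model`** — discover the two-block motif with variable
  spacer from upstream windows, build position weight matrices
  (`p = (count + λ·bg) / (n + λ)`), compute per-position information
  content `IC_j = Σ_b p_b log₂(p_b/bg_b)`, scan genomes with the summed
  log-odds score plus `log₂ P(spacer)`, and assign hits to downstream genes.
* **`ecf41.phylogeny`** — strip gapped columns, compute p-distances (or the
  Poisson correction `−ln(1−p)`), build a Saitou–Nei neighbor-joining tree,
  and score how strongly tips cluster by phylum.
* **`ecf41.protein_features`** — find the conserved WLPEP linker motif and
  conserved C-terminal blocks in alignments.
* **`ecf41.synthetic_data`** — a genome simulator that plants loci at the
  observed category proportions and bipartite sites inside 250 bp upstream
  windows, with full ground truth, so every stage is testable end to end.

The printed reference tables (context counts, phylum distribution, the 19
candidate promoter sequences with their 5′UTRs) ship as plain-text fixtures
under `ecf41.fixtures`.

## Worked example

Run the numbered drivers in `analysis/` (each is a thin script over the
library; outputs land in `results/`):

```bash
cd analysis
python 01_simulate_genomes.py
python 02_classify_contexts.py
python 03_discover_promoter_motif.py
```

On the default study conditions (two 100 kb replicons, 40 loci, seed 42)
the discovery step prints:

```
windows: 62 (supporting: 26)
consensus: TGTCACA [n{15,16,17}] CGTC
spacer distribution: {15: 2, 16: 18, 17: 6} (median 16)
total information: 19.5 bits (shuffled-window null: 11.0)
```

i.e. from nothing but upstream windows the discovery recovers the planted
TGTCACA/CGTC consensus, a modal 16 bp spacer, and a model whose information
content stands well above the shuffled-sequence noise floor.  The scanning
step (`04_scan_for_targets.py`) then reports perfect recall of the planted
sites with perfect gene assignment:

```
recall: 23/23
assignment accuracy on recovered sites: 23/23
```

and `05_build_phylogeny.py` builds the neighbor-joining tree of the ECF41
proteins, whose tips cluster by phylum (nearest-neighbor label agreement
0.950 — two tips are their phylum's sole representative and can never
match).  `06_reference_tables.py` recomputes the printed-table arithmetic:
373 loci in total, 34% orphans (30% of which still carry the promoter), 43%
operon-like same-direction pairs, and a 68% actinobacterial share.

The same functionality is exposed as a CLI (`ecf41 simulate|classify|
discover|scan|tree|features|run-all|report`) for use on real FASTA/GFF3
inputs.

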