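"""Discover the bipartite promoter motif from upstream windows.

Extracts the 250 bp regions upstream of every ECF41 and partner COE gene,
runs enumeration-seeded discovery of the -35/-10 motif with a 15-17 bp
spacer, and writes the model (JSON + MEME minimal format) with its
per-position information content.  The same discovery is then applied to
the printed candidate promoter sequences as an external sanity check.
"""

import os

import pandas as pd

from common import RESULTS, ensure_bundle
from ecf41 import fixtures
from ecf41 import io as ecf_io
from ecf41.promoter_model import (
    discover_bipartite_motif,
    extract_upstream,
    information_content,
    spacer_stats,
)
from ecf41.synthetic_data import read_truth

bundle = ensure_bundle()
replicons = ecf_io.read_fasta(os.path.join(bundle, "genome.fasta"))
genes = ecf_io.read_gff3(os.path.join(bundle, "annotation.gff3"))
truth = read_truth(bundle)

by_id = {g.gene_id: g for g in genes}
target_ids = sorted(
    {lt.ecf_gene_id for lt in truth.loci}
    | {lt.partner_gene_id for lt in truth.loci if lt.partner_gene_id}
)
windows = [extract_upstream(by_id[g], replicons[by_id[g].replicon_id]) for g in target_ids]
windows = [w for w in windows if w.window_length >= 28]

model, placements, info = discover_bipartite_motif(windows)
model.to_json(os.path.join(RESULTS, "motif_model.json"))
with open(os.path.join(RESULTS, "motif_model.meme.txt"), "w") as fh:
    fh.write(model.to_meme())

support = set(info["support"])
stats = spacer_stats([p for p in placements if p[0] in support])
ic35 = information_content(model.pwm35, model.background)
ic10 = information_content(model.pwm10, model.background)
pd.DataFrame(
    {
        "element": ["-35"] * 7 + ["-10"] * 4,
        "position": list(range(1, 8)) + list(range(1, 5)),
        "information_bits": list(ic35) + list(ic10),
    }
).to_csv(os.path.join(RESULTS, "logo_information.tsv"), sep="\t", index=False)

print(f"windows: {len(windows)} (supporting: {len(support)})")
print(f"consensus: {model.consensus35()} [n{{15,16,17}}] {model.consensus10()}")
print(f"spacer distribution: {stats['counts']} (median {stats['median']:.0f})")
print(f"total information: {info['total_information_bits']:.1f} bits "
      f"(shuffled-window null: {info['noise_ic_bits']:.1f})")

candidates = fixtures.load_candidate_promoters("Bacillus_licheniformis")
cmodel, cplace, cinfo = discover_bipartite_motif([c.sequence for c in candidates])
print(f"\nprinted candidates: consensus {cmodel.consensus35()} / "
      f"{cmodel.consensus10()}, spacer median "
      f"{spacer_stats(cplace)['median']:.0f}")
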