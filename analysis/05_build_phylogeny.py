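"""Neighbor-joining tree of the ECF41 proteins, scored by phylum.

The synthetic proteins are equal-length and ungapped, so they double as
their own alignment; gap-column stripping is still applied for form.  The
tree is built from p-distances and written as newick; the phylum-
clustering score (fraction of tips whose nearest tip shares the phylum
label -- our quantification of by-eye clade coloring) is reported.
"""

import os
from collections import Counter

from common import RESULTS, ensure_bundle
from ecf41 import io as ecf_io
from ecf41.phylogeny import (
    distances,
    neighbor_joining,
    phylum_clustering_score,
    strip_gap_columns,
    write_newick,
)
from ecf41.synthetic_data import read_truth

bundle = ensure_bundle()
proteins = ecf_io.read_fasta(os.path.join(bundle, "proteins.fasta"))
truth = read_truth(bundle)
labels = {lt.ecf_gene_id: lt.phylum for lt in truth.loci}

records = strip_gap_columns(sorted(proteins.items()))
dm = distances(records, model="p_distance")
tree = neighbor_joining(dm)
out = os.path.join(RESULTS, "tree.nwk")
write_newick(tree, out)
score = phylum_clustering_score(tree, labels)

sizes = Counter(labels[r[0]] for r in records)
singletons = sum(1 for r in records if sizes[labels[r[0]]] == 1)

print(f"taxa: {len(records)}; alignment length {len(records[0][1])}")
print("phylum sizes:", dict(sizes))
print(f"phylum clustering score (nearest-neighbor label agreement): {score:.3f}")
if singletons:
    print(f"note: {singletons} tip(s) are their phylum's only representative "
          "and can never score a match")
print(f"wrote {out}")
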