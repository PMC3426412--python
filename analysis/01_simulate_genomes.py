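"""Generate the synthetic study genomes.

Two 100 kb replicons host 40 ECF41 loci drawn at the observed genomic-
context proportions; each locus gene carries the bipartite promoter with
the category-specific occurrence probability, placed inside its 250 bp
upstream window.  Everything downstream (classification, discovery,
scanning, phylogeny) runs from the files this script writes.
"""

import os
from collections import Counter

from common import BUNDLE, STUDY_CONFIG, ensure_bundle
from ecf41.synthetic_data import read_truth

ensure_bundle()
truth = read_truth(BUNDLE)

print(f"bundle: {BUNDLE}")
print(f"replicons: {STUDY_CONFIG.n_replicons} x {STUDY_CONFIG.replicon_length:,} bp")
print(f"loci: {len(truth.loci)}; planted promoter sites: {len(truth.sites)}")
print("category counts:", dict(Counter(lt.category for lt in truth.loci)))
print("phyla:", dict(Counter(lt.phylum for lt in truth.loci)))
print("files:", sorted(os.listdir(BUNDLE)))
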