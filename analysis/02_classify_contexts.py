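"""Classify every ECF41 gene's genomic neighborhood from the annotation.

Reads the GFF3 and the domain table exactly as a user would, classifies
each ECF41 gene into the five conserved arrangements plus ungrouped, adds
the promoter-occurrence flags from the planted-site truth, and writes the
context summary table.  On this noiseless dataset classification must
match the generator's truth for every locus.
"""

import os

from common import RESULTS, ensure_bundle
from ecf41 import io as ecf_io
from ecf41.locus_context import classify_context, tabulate_contexts
from ecf41.synthetic_data import read_truth

bundle = ensure_bundle()
genes = ecf_io.read_gff3(os.path.join(bundle, "annotation.gff3"))
domains = ecf_io.read_domain_table(os.path.join(bundle, "domains.tsv"))
truth = read_truth(bundle)

by_id = {g.gene_id: g for g in genes}
has_site = {st.target_gene_id for st in truth.sites}
loci, correct = [], 0
for lt in truth.loci:
    lc = classify_context(by_id[lt.ecf_gene_id], genes, domains)
    lc.promoter_on_ecf = lt.ecf_gene_id in has_site
    if lc.partner_gene_id is not None:
        lc.promoter_on_coe = lc.partner_gene_id in has_site
    loci.append(lc)
    correct += lc.category == lt.category

summary = tabulate_contexts(loci)
out = os.path.join(RESULTS, "context_summary.tsv")
summary.to_csv(out, sep="\t", index=False)

print(summary.to_string(index=False))
print(f"\nclassification vs truth: {correct}/{len(loci)} correct")
print(f"wrote {out}")
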