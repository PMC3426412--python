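"""Arithmetic over the packaged in-print tables.

Recomputes, through the package's own tabulation and PWM code, the
headline fractions of the reference tables: the genomic-context
distribution (sum 373, one third orphans, under half same-direction
operon-like pairs), the phylum distribution (two thirds actinobacterial),
and the candidate-promoter geometry (TGTCAC prefix, 16 +/- 1 spacer,
TGTCACA consensus).
"""

import os

from common import RESULTS
from ecf41 import fixtures
from ecf41.promoter_model import build_pwm, consensus, spacer_stats

os.makedirs(RESULTS, exist_ok=True)

table4 = fixtures.load_context_counts().set_index("category")
total = table4["count"].sum()
same = table4.loc[["COE_up_same", "COE_down_same"], "count"].sum()
opposite = table4.loc[["convergent", "divergent"], "count"].sum()
orphans = table4.loc["ECF_alone", "count"]
print(f"loci total: {total}")
print(f"orphans (>ECF> alone): {orphans} = {100 * orphans / total:.0f}%")
print(f"same direction (operon-like): {same} = {100 * same / total:.0f}%")
print(f"opposite orientation: {opposite} = {100 * opposite / total:.0f}%")
p_orphan = table4.loc["ECF_alone", "p_ecf"]
print(f"orphans carrying the promoter: {p_orphan}/{orphans} "
      f"= {100 * p_orphan / orphans:.0f}%")

table3 = fixtures.load_phylum_distribution().set_index("phylum")
actino = table3.loc["Actinobacteria", "n_proteins"]
print(f"\nactinobacterial fraction: {actino}/{table3['n_proteins'].sum()} "
      f"= {100 * actino / table3['n_proteins'].sum():.0f}%")

candidates = fixtures.load_candidate_promoters("Bacillus_licheniformis")
stats = spacer_stats([c.spacer for c in candidates])
pwm = build_pwm([c.minus35 for c in candidates])
print(f"\ncandidate promoters (B. licheniformis): {len(candidates)}")
print(f"all start TGTCAC: {all(c.sequence.startswith('TGTCAC') for c in candidates)}")
print(f"spacer counts {stats['counts']}, median {stats['median']:.0f}")
print(f"-35 consensus: {consensus(pwm)}")
print(f"5'UTR range: {min(c.utr for c in candidates)}-"
      f"{max(c.utr for c in candidates)} nt")
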