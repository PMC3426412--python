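"""Shared paths and the study-condition dataset for the analysis scripts."""

import os

from ecf41.synthetic_data import SimulationConfig, simulate

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
RESULTS = os.path.join(ROOT, "results")
BUNDLE = os.path.join(RESULTS, "synthetic")

#: The study conditions: two 100 kb replicons, 40 ECF41 loci drawn at the
#: observed category proportions, promoter occurrence at the observed
#: per-category rates, noiseless sites.
STUDY_CONFIG = SimulationConfig(seed=42)


def ensure_bundle():
    """Generate (once) and return the on-disk synthetic bundle directory."""
    if not os.path.exists(os.path.join(BUNDLE, "truth_loci.tsv")):
        os.makedirs(RESULTS, exist_ok=True)
        simulate(STUDY_CONFIG, outdir=BUNDLE)
    return BUNDLE
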