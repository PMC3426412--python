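"""Independent reference implementations used to cross-check the package.

The brute-force scanner enumerates every (position, spacer, strand)
placement with plain Python arithmetic and applies the same published
scoring rule (block log-odds + log spacer probability, min-max relative
threshold, per-position floor) so scanner bugs cannot hide in shared code.
"""

import math

from ecf41.promoter_model import reverse_complement


def random_seq(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def oracle_scan(model, seq, threshold):
    """Naive enumeration of every placement, with overlap resolution."""

    def col_score(pwm, base, j, bg):
        idx = "ACGT".find(base)
        if idx < 0:
            return 0.0
        return max(
            math.log2(max(pwm[j, idx], 1e-300) / bg[idx]), model.LOG_ODDS_FLOOR
        )

    def raw_score(text, spacer):
        s = math.log2(model.spacer_probs[spacer])
        for j in range(7):
            s += col_score(model.pwm35, text[j], j, model.background)
        for j in range(4):
            s += col_score(model.pwm10, text[7 + spacer + j], j, model.background)
        return s

    smin, smax = model.score_range()
    hits = []
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for spacer in model.spacers:
            span = 11 + spacer
            for i in range(len(s) - span + 1):
                raw = raw_score(s[i : i + span], spacer)
                if (raw - smin) / (smax - smin) >= threshold:
                    if strand == "+":
                        start, end = i + 1, i + span
                    else:
                        start, end = len(s) - (i + span) + 1, len(s) - i
                    hits.append((strand, start, end, spacer, raw))
    # same overlap rule: best score wins, ties to smaller coordinate/spacer
    hits.sort(key=lambda h: (-h[4], h[1], h[3]))
    kept = []
    for h in hits:
        if not any(k[0] == h[0] and h[1] <= k[2] and h[2] >= k[1] for k in kept):
            kept.append(h)
    return {(h[0], h[1], h[2], h[3]) for h in kept}
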