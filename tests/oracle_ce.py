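"""Independent brute-force conversion-efficiency oracle.

Recomputes per-product CE from raw δ¹³C and %FAME with plain scalar
arithmetic — no package imports — so it can cross-check the pipeline.
Inputs: per fatty acid the labelled bird's (delta, pct_fame) and the
control's delta; ``members`` orders the pathway with the precursor first.
"""


def brute_force_ce(members, labelled, control_delta, r_standard=0.0112372,
                   delta_meoh=None, n_carbons=None):
    def ap(delta, n=None):
        if delta_meoh is not None and n is not None:
            delta = ((n + 1) * delta - delta_meoh) / n
        r = r_standard * (delta / 1000.0 + 1.0)
        return 100.0 * r / (1.0 + r)

    labels = {}
    for fa in members:
        delta, pct = labelled[fa]
        n = n_carbons[fa] if n_carbons else None
        labels[fa] = pct * (ap(delta, n) - ap(control_delta[fa], n))
    denom = sum(labels.values())
    return {fa: labels[fa] / denom * 100.0 for fa in members}
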