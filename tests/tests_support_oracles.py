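"""Independent brute-force oracles shared by the test suite."""


def pairwise_auc(scores, labels):
    """O(n^2) Mann-Whitney AUC: (concordant + 0.5 * tied) / (n_pos * n_neg)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))
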