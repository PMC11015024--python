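"""Independent brute-force oracle for the pre-ranked enrichment score.

Walks the full ranked list with an explicit running sum — no shortcuts — so it
shares nothing with the implementation's hit-position formulation except the
definition of the statistic and the documented tie convention (the positive
extreme wins when the two extreme magnitudes agree within 1e-12).
"""

from __future__ import annotations


def brute_force_es(genes, scores, gene_set, weight: float = 1.0) -> float:
    n = len(genes)
    hits = [g in gene_set for g in genes]
    k = sum(hits)
    assert 0 < k < n, "set must intersect the list without covering it"
    abs_w = [abs(s) ** weight for s in scores]
    hit_mass = sum(a for a, h in zip(abs_w, hits) if h)
    miss_step = 1.0 / (n - k)
    running = 0.0
    pos_extreme = 0.0
    neg_extreme = 0.0
    for a, h in zip(abs_w, hits):
        if h:
            running += a / hit_mass if hit_mass > 0 else 1.0 / k
        else:
            running -= miss_step
        pos_extreme = max(pos_extreme, running)
        neg_extreme = min(neg_extreme, running)
    return pos_extreme if pos_extreme + neg_extreme >= -1e-12 else neg_extreme
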