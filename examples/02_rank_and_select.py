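"""Rank genotypes across all selection criteria and pick the best overall.

A synthetic 15-genotype screen is ranked under every index with rank 1 =
most favourable; the average sum of ranks (ASR) aggregates the 11 rank
columns, and the lowest ASR flags the genotype that is consistently
superior no matter which index you trust.
"""

import stressidx as sx

trial = sx.generate_trial(n=15, reduction=0.3, seed=11)
table = sx.compute_indices(trial)
ranks = sx.rank_all(table, trial)

summary = ranks.ranks.copy()
summary["ASR"] = ranks.asr
summary["SD"] = ranks.rank_sd
print(summary.round(2).to_string())

order = sx.sort_by_asr(ranks)
best = order[0]
print(f"\nSelection order (best first): {', '.join(order[:5])}, ...")
print(
    f"{best} has the lowest ASR ({ranks.asr[best]:.2f} ± {ranks.rank_sd[best]:.2f}): "
    "it ranks near the top under yield and under every tolerance index."
)
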