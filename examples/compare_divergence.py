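"""Profile distance tracks evolutionary divergence.

Mutate one ancestor at increasing substitution rates and watch the mean
Manhattan distance between chaos-game profiles grow with the rate — the
property that makes the encoding usable for alignment-free comparison.
"""

import numpy as np
from scipy.stats import spearmanr

from pcmer import (
    DivergenceSeries,
    SequenceRecord,
    encode_pcmer,
    manhattan_distance,
    make_divergence_series,
)

rng = np.random.default_rng(0)
ancestor = SequenceRecord("ancestor", "".join(rng.choice(list("ACGT"), 500)))
rates = [0.01, 0.05, 0.1, 0.2, 0.3]
series = make_divergence_series(
    DivergenceSeries(ancestor=ancestor, rates=rates, replicates=20), seed=1
)

k = 8
anc_profile = encode_pcmer(ancestor.residues, k)
print(f"substitution rate -> mean Manhattan distance (k={k}, 20 replicates)")
means = []
for rate in rates:
    dists = [
        manhattan_distance(anc_profile, encode_pcmer(rec.residues, k))
        for rec, label in zip(series.records, series.labels)
        if label == f"rate={rate:g}"
    ]
    means.append(np.mean(dists))
    print(f"  {rate:5.2f} -> {means[-1]:8.1f}")

rho = spearmanr(rates, means).statistic
print(f"\nSpearman(rate, mean distance) = {rho:.3f}")
print("A value near 1 means profile distance ranks sequences by divergence,")
print("so nearest-profile retrieval recovers relatedness without alignment.")
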