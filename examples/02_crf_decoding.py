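"""Score, normalise and decode label paths with the linear-chain CRF.

A tiny 3-position, 3-label instance small enough to enumerate by hand:
the Viterbi path is checked against exhaustive enumeration and the path
posteriors are shown to sum to one.
"""

import itertools

import numpy as np

from convner import (brute_force_best_path, crf_log_partition, crf_path_score,
                     viterbi_decode)

rng = np.random.default_rng(0)
n, K = 3, 3
emissions = rng.standard_normal((n, K))
transitions = rng.standard_normal((K + 2, K + 2))  # labels + start/stop

best = viterbi_decode(emissions, transitions)
brute = brute_force_best_path(emissions, transitions)
logZ = crf_log_partition(emissions, transitions)

print(f"Viterbi path     : {best.indices}  score {best.score:.4f}")
print(f"Enumeration path : {brute.indices}  score {brute.score:.4f}")
print(f"log partition    : {logZ:.4f}")

total = sum(np.exp(crf_path_score(emissions, list(y), transitions) - logZ)
            for y in itertools.product(range(K), repeat=n))
print(f"sum of all {K}^{n} path posteriors: {total:.6f}")
# The two paths coincide and the posteriors sum to 1: the dynamic
# programs agree exactly with brute force on enumerable instances.
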