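"""Derive the first-choice prior from pooled first-trial frequencies.

Across 504 participants the very first card pick is biased (A is chosen 38%
of the time). Inverting those frequencies through the softmax at beta = 3
gives mean-centred initial exploitation weights; pushing the weights back
through the softmax must reproduce the frequencies exactly.
"""

import numpy as np

from igtrl import (
    FIRST_CHOICE_COUNTS,
    choice_probabilities,
    consistency,
    derive_first_choice_prior,
    init_state,
)

counts = np.array(FIRST_CHOICE_COUNTS)
print("first-choice counts:", dict(zip("ABCD", counts)))
print("observed frequencies:", np.round(counts / counts.sum(), 4))

prior = derive_first_choice_prior(counts, beta=3.0)
print("initial weights w_ini:", np.round(prior.w_ini, 4))

round_trip = choice_probabilities(init_state(prior), consistency(3.0))
print("softmax(w_ini * C):   ", np.round(round_trip, 4))
# The weights (~[0.0184, 0.0020, -0.0050, -0.0155]) are a decaying initial
# memory trace: positive for the popular decks, negative for the avoided
# ones, and exactly invertible back to the observed first-choice frequencies.
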