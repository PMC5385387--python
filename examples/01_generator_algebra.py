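"""Elementary generator algebra: translation, mirror, split, backward.

Builds the block operators, applies them to small code vectors, and
shows the canonical worked examples: a cyclic shift, a midline
reflection, and the split/standing transformations that describe the
atypical fan-shaped-body innervation patterns.
"""

import numpy as np

from cxcircuit import apply_generator, backward, mirror, split, translation

a = np.array([0, 1, 2, 3])
print("T^(1,4) x (0,1,2,3) =", (translation(1, 4) @ a).tolist())
print("M^(4)   x (0,1,2,3) =", (mirror(4) @ a).tolist())

# A fan-shaped-body layer has 8 subunits.  A typical neuron type moves
# its single axonal subunit one slot per type; the split generator
# S = I + T duplicates it into the adjacent slot, and the backward
# generator B = T^-1 cancels the translation ("standing").
T, S, B = translation(1, 8), split(8), backward(8)
type4 = np.array([0, 0, 0, 0, 0, 2, 0, 0])
print("split:    S T x", type4.tolist(), "->", apply_generator(S, apply_generator(T, type4)).tolist())
type1 = np.array([0, 0, 0, 0, 0, 0, 2, 0])
print("standing: B T x", type1.tolist(), "->", apply_generator(B, apply_generator(T, type1)).tolist())

# The split output innervates two adjacent subunits; the standing
# output is unchanged — the two atypical patterns seen in the data.
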