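"""The discrete swarm operators, one by one.

Builds a toy swarm of personal-best bitstrings and walks through the update
chain: mean-best majority vote, crossover local attractor, jump length, and
the mutation that realises the jump.
"""

import numpy as np

import geneswarm as gs

rng = np.random.default_rng(0)

pbests = ["1011001010", "0011001110", "1011011010", "1111001000", "0011101010"]
gbest = "1011001010"

mbest = gs.get_mbest(pbests, rng)
print("pbests:        ", pbests)
print("mbest:         ", gs.bits_to_string(mbest))
# mbest carries the per-bit majority of the five personal bests.

attractor = gs.get_local_attractor(pbests[1], gbest, rng)
print("attractor:     ", gs.bits_to_string(attractor))
d = gs.hamming(attractor, pbests[1]) + gs.hamming(attractor, gbest)
print("betweenness:   ", d, "== d(pbest, gbest) ==", gs.hamming(pbests[1], gbest))
# Every attractor bit comes from one parent, so the distances add up exactly.

x = "0000000000"
draw = gs.jump_length(x, mbest, ce_coefficient=1.0, rng=rng)
print(f"jump draw:      mu={draw.mu:.3f}  b={draw.b}  Pr={draw.pr:.2f}")
moved = gs.mutate_toward(attractor, draw, rng)
print("new position:  ", gs.bits_to_string(moved))
# b scales with the particle's Hamming distance to mbest: far particles make
# long exploratory jumps, converged ones stay put (b = 0 at distance 0).
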