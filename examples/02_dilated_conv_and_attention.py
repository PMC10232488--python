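"""The two building blocks of the feature extractor, in isolation.

A dilated convolution spaces its kernel taps `rate` pixels apart, growing
the receptive field without extra parameters.  The attention block runs
three dilated branches (rates 1, 2, 3) in parallel and fuses them as a
convex combination whose weights come from pooled branch descriptors.
"""

import numpy as np

import histotile as ht
from histotile.backbone import DiConvAttentionBlock

# all-ones 5x5 input, all-ones 3x3 kernel at rate 2: the single valid
# output position taps 9 pixels, so the response is 9
out = ht.dilated_conv2d(np.ones((1, 5, 5)), np.ones((1, 1, 3, 3)),
                        rate=2, padding="valid")
print("dilated conv, all-ones 5x5 / 3x3 kernel, rate 2 ->", out[0, 0, 0])

rng = np.random.default_rng(0)
block = DiConvAttentionBlock(channels=4, rng=np.random.default_rng(1))
x = rng.standard_normal((1, 4, 12, 12))
branches = [conv.forward(x) for conv in block.convs]
bw = block.branch_attention_weights(branches)
print("branch weights mu:", np.round(bw.mu[0], 4), "sum:", bw.mu[0].sum())

fused = block.forward(x)
print("fused map shape:", fused.shape)
# mu sums to 1, so the fused map lies pointwise between the branch maps:
# the block reweights scales instead of amplifying them.
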