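"""Inspect the convolutional encoder: shapes, splicing and parameters.

Shows that the stride-1 stack preserves sequence length, that the four
stage outputs splice to the sum of the channel widths, and that the
closed-form parameter count matches the instantiated model.
"""

import numpy as np

from convner import ConvStageConfig, count_parameters
from convner.autograd import Tensor
from convner.convnet import ConvEncoder, depthwise_param_count

cfg = ConvStageConfig(channels=(16, 32, 64, 128))  # reduced widths
enc = ConvEncoder(in_channels=64, cfg=cfg, rng=np.random.default_rng(0))

for L in (1, 7, 20):
    x = Tensor(np.random.default_rng(L).standard_normal((1, L, 64)))
    out = enc(x, np.ones((1, L), dtype=bool))
    print(f"L={L:2d}: encoder output {out.shape}")

print(f"blocks: {cfg.n_blocks} (stack ratio {cfg.depths})")
print(f"instantiated parameters: {enc.n_parameters()}")
print(f"closed-form count      : {count_parameters(cfg, 64)}")
print(f"depthwise layer at width 128, kernel 7: "
      f"{depthwise_param_count(7, 128)} weights (Dk*Dk*1*M)")
# Output width 240 = 16+32+64+128: the splice concatenates the last map
# of every stage. Length never changes because every conv is stride 1.
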