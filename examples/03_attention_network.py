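"""Build the channel-spatial attention CNN and look at its structure.

Constructs the full-size network (128-channel spectrogram input) and the
compact test-profile variant, prints layer shapes and parameter counts, and
demonstrates the attention algebra: sigmoid gating always shrinks features,
and with zero weights the gate is exactly 0.5.
"""

import numpy as np

from emgmeta import CSACNet, NetworkConfig, channel_attention
from emgmeta.model import ChannelAttentionParams
from emgmeta import autodiff as ad

full = CSACNet(NetworkConfig(), seed=0)
print(full.describe())
print()
for variant in ("csac", "sac", "cac", "cnn"):
    n = CSACNet(NetworkConfig(variant=variant)).parameter_count()
    print(f"variant {variant:4s}: {n} parameters")
print("(ablations swap attention for a depthwise conv, keeping capacity flat)")

x = np.random.default_rng(0).normal(size=(4, 3, 3))
zero = ChannelAttentionParams(
    *(ad.Tensor(np.zeros(s), requires_grad=True)
      for s in ((2, 4), (2,), (4, 2), (4,))))
y = channel_attention(ad.Tensor(x), zero)
print(f"\nzero-weight channel attention: max |y - 0.5 x| = "
      f"{np.max(np.abs(y.data - 0.5 * x)):.1e} (gate = sigmoid(0) = 0.5)")

probs = full.forward(np.random.default_rng(1).normal(size=(2, 128, 33, 33)))
print(f"forward on a 2-sample batch: probabilities shape {probs.shape}, "
      f"row sums {probs.data.sum(axis=1)}")
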