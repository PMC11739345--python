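"""Shared helper for building random attention parameters in tests."""

import numpy as np

from eegmind.autodiff import Tensor
from eegmind.dtgam import AttentionParams


def attention_params(rng: np.random.Generator, d_model: int = 8,
                     n_heads: int = 2) -> AttentionParams:
    d_t = d_model // n_heads
    mk = lambda *s: Tensor(rng.standard_normal(s) * 0.3, requires_grad=True)
    return AttentionParams(
        d_model=d_model, n_heads=n_heads,
        w_q=mk(n_heads, d_model, d_t), w_k=mk(n_heads, d_model, d_t),
        w_v=mk(n_heads, d_model, d_t), w_o=mk(n_heads * d_t, d_model),
    )
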