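"""Token-level abnormality classifier: sequence encoder + sigmoid head.

The encoder contract: map a length-n token-id sequence to n hidden vectors
of size d_h, deterministically given parameters. The default implementation
is a lightweight single-head self-attention encoder trainable on CPU in
seconds; heavier pretrained transformers can be dropped in behind the same
contract.
"""

from __future__ import annotations

import numpy as np

from ..nn import Embedding, Linear, Module, Tensor, no_grad

__all__ = ["SequenceEncoder", "TinySelfAttentionEncoder", "TokenClassifierHead"]


class SequenceEncoder(Module):
    """Contract: __call__(token_ids) -> Tensor of shape (n, hidden_size)."""

    hidden_size: int

    def __call__(self, token_ids: list[int]) -> Tensor:  # pragma: no cover - interface
        raise NotImplementedError


class _Block(Module):
    def __init__(self, hidden: int, ffn: int, rng: np.random.Generator):
        self.wq = Linear(hidden, hidden, rng)
        self.wk = Linear(hidden, hidden, rng)
        self.wv = Linear(hidden, hidden, rng)
        self.ff1 = Linear(hidden, ffn, rng)
        self.ff2 = Linear(ffn, hidden, rng)
        self._scale = 1.0 / np.sqrt(hidden)

    def __call__(self, x: Tensor) -> Tensor:
        q, k, v = self.wq(x), self.wk(x), self.wv(x)
        scores = (q @ k.transpose(1, 0)) * self._scale
        attn = scores.softmax(axis=-1)
        x = x + attn @ v
        return x + self.ff2(self.ff1(x).relu())


class TinySelfAttentionEncoder(SequenceEncoder):
    def __init__(
        self,
        vocab_size: int,
        hidden: int = 32,
        ffn: int = 64,
        n_blocks: int = 1,
        max_len: int = 128,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.hidden_size = hidden
        self.max_len = max_len
        self.embedding = Embedding(vocab_size, hidden, rng)
        self.position = Tensor(rng.normal(0.0, 0.1, (max_len, hidden)), requires_grad=True)
        self.blocks = [_Block(hidden, ffn, rng) for _ in range(n_blocks)]

    def __call__(self, token_ids: list[int]) -> Tensor:
        n = len(token_ids)
        if n > self.max_len:
            token_ids = token_ids[: self.max_len]
            n = self.max_len
        x = self.embedding(token_ids) + self.position.slice_rows(0, n)
        for block in self.blocks:
            x = block(x)
        return x


class TokenClassifierHead(Module):
    """Fully-connected layer with sigmoid activation over each hidden vector."""

    def __init__(self, hidden_size: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.linear = Linear(hidden_size, 1, rng)

    def __call__(self, hidden: Tensor) -> Tensor:
        """hidden (n, d_h) -> per-token abnormality probabilities (n,)."""
        return self.linear(hidden).sigmoid().reshape(-1)

    def predict(self, encoder: SequenceEncoder, token_ids: list[int]) -> np.ndarray:
        with no_grad():
            return self(encoder(token_ids)).data.copy()
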