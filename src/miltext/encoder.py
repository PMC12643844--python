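"""Encoder adapters: pluggable producers of stacked block-level features.

The classifier consumes an ``L x d`` matrix per post: one summary
(classification-token) vector per encoder block, shallow blocks carrying
lower-level semantics and deeper blocks higher-level ones. Any object with
``tokenize(text) -> token ids``, ``encode(token_ids, max_len) -> (L, d)``
and ``n_blocks`` / ``dim`` attributes is a valid adapter.

Two adapters ship:

* :class:`ToyEncoder` — a randomly initialized, seeded 4-block encoder for
  desk-scale tests and synthetic experiments; no downloads, deterministic.
* :class:`TransformersEncoderAdapter` — wraps a pretrained 12-block
  transformer via the ``transformers`` package when the user has it
  installed; imported lazily.
"""

from __future__ import annotations

from typing import Protocol, Sequence

import numpy as np


class EncoderAdapter(Protocol):
    n_blocks: int
    dim: int

    def tokenize(self, text: str) -> list[int]: ...

    def encode(self, token_ids: Sequence[int], max_len: int) -> np.ndarray: ...


def _stable_hash(token: str, mod: int) -> int:
    h = 0
    for ch in token:
        h = (h * 131 + ord(ch)) % (2**31)
    return h % mod


class ToyEncoder:
    """Seeded random-weight block encoder over whitespace tokens.

    Token vectors come from a hashed embedding table; block ``l``'s summary
    vector is ``tanh(W_l h_{l-1} + b_l)`` starting from the mean token
    embedding. Identical text always yields an identical matrix for a
    given seed, and class-conditional token distributions stay linearly
    separable with high probability, which is all the test suite needs.
    """

    def __init__(self, n_blocks: int = 4, dim: int = 32, seed: int = 0,
                 vocab_size: int = 4096):
        self.n_blocks = n_blocks
        self.dim = dim
        self.seed = seed
        self.vocab_size = vocab_size
        rng = np.random.default_rng(seed)
        self.embeddings = rng.normal(0.0, 1.0, (vocab_size, dim))
        self.W = rng.normal(0.0, 1.0 / np.sqrt(dim), (n_blocks, dim, dim))
        self.b = rng.normal(0.0, 0.01, (n_blocks, dim))

    def fingerprint(self) -> tuple:
        return ("toy", self.n_blocks, self.dim, self.seed, self.vocab_size)

    def tokenize(self, text: str) -> list[int]:
        return [_stable_hash(tok, self.vocab_size) for tok in text.split()]

    def encode(self, token_ids: Sequence[int], max_len: int) -> np.ndarray:
        ids = list(token_ids)[:max_len]
        if ids:
            h = self.embeddings[ids].mean(axis=0)
        else:
            h = np.zeros(self.dim)
        rows = []
        for layer in range(self.n_blocks):
            h = np.tanh(self.W[layer] @ h + self.b[layer])
            rows.append(h)
        return np.stack(rows)


class TransformersEncoderAdapter:
    """Adapter over a pretrained transformer encoder (optional dependency).

    Extracts the classification-token vector from every hidden layer of a
    ``transformers`` model (e.g. a 12-block Chinese BERT) and stacks them.
    Requires the user to have ``transformers`` and ``torch`` installed and
    to supply a model name or path; nothing is downloaded by this package.
    """

    def __init__(self, model_name_or_path: str):
        try:
            from transformers import AutoModel, AutoTokenizer  # noqa: PLC0415
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "TransformersEncoderAdapter requires the 'transformers' and "
                "'torch' packages"
            ) from exc
        self._tokenizer = AutoTokenizer.from_pretrained(model_name_or_path)
        self._model = AutoModel.from_pretrained(
            model_name_or_path, output_hidden_states=True
        )
        self._model.eval()
        self.n_blocks = self._model.config.num_hidden_layers
        self.dim = self._model.config.hidden_size
        self._name = model_name_or_path

    def fingerprint(self) -> tuple:  # pragma: no cover - optional dependency
        return ("transformers", self._name, self.n_blocks, self.dim)

    def tokenize(self, text: str) -> list[int]:  # pragma: no cover
        return self._tokenizer.encode(text, add_special_tokens=True)

    def encode(self, token_ids, max_len: int) -> np.ndarray:  # pragma: no cover
        import torch  # noqa: PLC0415

        ids = list(token_ids)[:max_len]
        ids = ids + [self._tokenizer.pad_token_id] * (max_len - len(ids))
        with torch.no_grad():
            out = self._model(input_ids=torch.tensor([ids]))
        # hidden_states[0] is the embedding layer; blocks are 1..L
        cls_rows = [h[0, 0, :].numpy() for h in out.hidden_states[1:]]
        return np.stack(cls_rows)
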