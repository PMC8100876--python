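"""Token representation layer.

Each token is represented by the concatenation of two streams:

* a character-level CNN (one convolution per kernel size, max-pooled)
  feeding a bidirectional LSTM that contextualizes tokens within the
  sentence, and
* a pluggable *contextual encoder* satisfying a simple contract — token
  strings in, one aligned vector per token out.  In a production setting
  this slot is filled by a pretrained sub-word transformer (uncased, with
  first-sub-word alignment); the packaged default is
  :class:`HashedContextualEncoder`, a deterministic per-token embedding
  derived from a cryptographic hash of the lowercased token, which keeps
  the full system trainable and testable with no external weights.

A learned ROOT vector is prepended as row 0 of every sentence
representation so the dummy root can be scored as an arc head.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, dropout
from .nn import BiLSTM, CharCNN, Module

PAD_CHAR = 0
UNK_CHAR = 1


@dataclass
class EncoderConfig:
    """Representation-layer hyperparameters (production defaults)."""

    char_embedding_dim: int = 25
    char_cnn_filters: int = 50
    cnn_kernel_sizes: tuple[int, ...] = (3, 4, 5)
    bilstm_hidden: int = 256  # per direction
    contextual_dim: int = 768
    dropout: float = 0.5
    max_sentence_length: int = 128
    # Whether the plugged-in contextual encoder is updated during training.
    # The hashed stand-in is frozen by construction; the flag matters only
    # for trainable contextual encoders.
    finetune_contextual: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        for name in (
            "char_embedding_dim",
            "char_cnn_filters",
            "bilstm_hidden",
            "contextual_dim",
            "max_sentence_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def token_dim(self) -> int:
        return self.contextual_dim + 2 * self.bilstm_hidden

    @staticmethod
    def toy(**overrides) -> "EncoderConfig":
        """A desk-scale configuration for tests and synthetic experiments."""
        cfg = dict(
            char_embedding_dim=12,
            char_cnn_filters=12,
            cnn_kernel_sizes=(2, 3),
            bilstm_hidden=24,
            contextual_dim=24,
            dropout=0.1,
            max_sentence_length=64,
        )
        cfg.update(overrides)
        return EncoderConfig(**cfg)


class HashedContextualEncoder:
    """Deterministic frozen token embeddings from a hash of the lowercased
    token — the packaged implementation of the contextual-encoder contract.

    Vectors are reproducible across processes and platforms (no RNG state),
    approximately unit-scale, and distinct tokens receive near-orthogonal
    vectors with high probability.
    """

    def __init__(self, dim: int):
        self.dim = dim
        self._cache: dict[str, np.ndarray] = {}

    def _vector(self, word: str) -> np.ndarray:
        v = self._cache.get(word)
        if v is None:
            digest = hashlib.blake2b(word.encode("utf-8"), digest_size=8).digest()
            seed = int.from_bytes(digest, "little") % (2**31)
            v = np.random.default_rng(seed).normal(0.0, 1.0, self.dim) / np.sqrt(self.dim)
            self._cache[word] = v
        return v

    def encode(self, words: list[str]) -> np.ndarray:
        """Aligned token vectors, shape (len(words), dim)."""
        if not words:
            return np.zeros((0, self.dim))
        return np.stack([self._vector(w.lower()) for w in words])

    def fingerprint(self) -> str:
        return f"hashed-blake2b-d{self.dim}"


class CharVocab:
    """Character inventory with PAD=0 and UNK=1, fitted on a corpus."""

    def __init__(self, chars: list[str]):
        self.chars = list(chars)
        self.index = {c: i + 2 for i, c in enumerate(self.chars)}

    def __len__(self) -> int:
        return len(self.chars) + 2

    @staticmethod
    def fit(sentences: list[list[str]]) -> "CharVocab":
        seen = sorted({c for sent in sentences for w in sent for c in w})
        return CharVocab(seen)

    def encode(self, word: str) -> list[int]:
        return [self.index.get(c, UNK_CHAR) for c in word]


class SentenceEncoder(Module):
    """Char-CNN → BiLSTM stream concatenated with the contextual stream."""

    def __init__(
        self,
        config: EncoderConfig,
        char_vocab: CharVocab,
        contextual,
        rng: np.random.Generator,
    ):
        if contextual.dim != config.contextual_dim:
            raise ValueError(
                f"contextual encoder dim {contextual.dim} != config "
                f"contextual_dim {config.contextual_dim}"
            )
        self.config = config
        self.char_vocab = char_vocab
        self.contextual = contextual
        self.char_cnn = CharCNN(
            rng,
            n_chars=len(char_vocab),
            char_dim=config.char_embedding_dim,
            kernel_sizes=config.cnn_kernel_sizes,
            n_filters=config.char_cnn_filters,
        )
        self.bilstm = BiLSTM(rng, self.char_cnn.out_dim, config.bilstm_hidden)
        self.root = Tensor(
            rng.normal(0.0, 0.1, size=(config.token_dim,)), requires_grad=True
        )

    # -- batched forward -----------------------------------------------------

    def __call__(
        self,
        sentences: list[list[str]],
        rng: np.random.Generator,
        train: bool,
        contextual_override: np.ndarray | None = None,
    ) -> tuple[Tensor, np.ndarray]:
        """Encode a batch of sentences (lists of token strings).

        Returns ``(rep, mask)`` where ``rep`` has shape (B, Tmax+1, d) with
        the ROOT vector at row 0 of each sentence, and ``mask`` (B, Tmax)
        marks real tokens.  ``contextual_override`` substitutes the
        contextual stream (used in ablation tests).
        """
        if not sentences:
            raise ValueError("empty batch")
        cfg = self.config
        lengths = np.array([len(s) for s in sentences])
        if lengths.min() < 1:
            raise ValueError("sentences must contain at least one token")
        if lengths.max() > cfg.max_sentence_length:
            raise ValueError(
                f"sentence of length {lengths.max()} exceeds "
                f"max_sentence_length={cfg.max_sentence_length}; split it first"
            )
        B, T = len(sentences), int(lengths.max())
        mask = np.arange(T)[None, :] < lengths[:, None]

        # character stream
        kmax = max(cfg.cnn_kernel_sizes)
        char_lens = np.array(
            [[len(w) for w in s] + [0] * (T - len(s)) for s in sentences]
        ).reshape(B * T)
        Lmax = max(int(char_lens.max()), kmax)
        char_idx = np.zeros((B * T, Lmax), dtype=int)
        for bi, s in enumerate(sentences):
            for ti, w in enumerate(s):
                ids = self.char_vocab.encode(w)
                char_idx[bi * T + ti, : len(ids)] = ids
        char_feat = self.char_cnn(char_idx, char_lens)  # (B*T, F)
        char_feat = char_feat.reshape(B, T, self.char_cnn.out_dim)
        lstm_out = self.bilstm(char_feat, mask)  # (B, T, 2H)

        # contextual stream (constant w.r.t. the graph when frozen)
        if contextual_override is not None:
            ctx = np.asarray(contextual_override, dtype=float)
            if ctx.shape != (B, T, cfg.contextual_dim):
                raise ValueError("contextual_override shape mismatch")
        else:
            ctx = np.zeros((B, T, cfg.contextual_dim))
            for bi, s in enumerate(sentences):
                ctx[bi, : len(s)] = self.contextual.encode(s)

        rep = concat([Tensor(ctx), lstm_out], axis=-1)  # (B, T, d)
        rep = dropout(rep, cfg.dropout, rng, train)
        rep = rep * Tensor(mask[:, :, None].astype(float))
        root = self.root.reshape(1, 1, cfg.token_dim) + Tensor(
            np.zeros((B, 1, cfg.token_dim))
        )
        return concat([root, rep], axis=1), mask


def encode_sentence(
    tokens: list[str], encoder: SentenceEncoder, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Single-sentence convenience wrapper: (n+1, d) representation, eval mode."""
    rng = rng or np.random.default_rng(0)
    rep, _ = encoder([tokens], rng, train=False)
    return rep.data[0]
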