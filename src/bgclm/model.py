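"""Dilated 1-D convolutional masked language model over BGC domain chains.

Architecture: embedding lookup (``embed_dim``) -> linear down-projection to
``hidden_dim`` -> ``n_layers`` residual blocks -> linear decoder to the joint
class+Pfam+special vocabulary. Block ``b`` uses dilation ``2^(b mod
(log2(max_dilation)+1))`` so dilations cycle 1, 2, 4, ..., max_dilation; each
block is

    LayerNorm -> GELU -> 1x1 projection hidden -> hidden/2
              -> dilated conv (kernel_width, same-length padding)
              -> GELU -> 1x1 projection hidden/2 -> hidden -> residual add

Convolutions are unmasked (bidirectional context): the objective is
autoencoding, not autoregressive. Padded positions are zeroed after the
embedding and after every block, so a sequence's logits are independent of
how much padding its batch carries.

At the published hyperparameters (kernel 3, max dilation 128, 32 layers,
hidden 256, embeddings 1280) and a full-scale vocabulary this totals about
34 million parameters.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .embeddings import EmbeddingTable, random_table
from .vocab import PfamVocab


@dataclass
class ModelConfig:
    vocab_size: int
    kernel_width: int = 3
    max_dilation: int = 128
    n_layers: int = 32
    hidden_dim: int = 256
    embed_dim: int = 1280
    seed: int = 0

    def __post_init__(self) -> None:
        md = self.max_dilation
        if md < 1 or (md & (md - 1)) != 0:
            raise ValueError("max_dilation must be a power of 2 >= 1")
        if self.kernel_width % 2 != 1:
            raise ValueError("kernel_width must be odd")
        for name in ("n_layers", "hidden_dim", "embed_dim", "vocab_size"):
            if getattr(self, name) <= 0 and name != "n_layers":
                raise ValueError(f"{name} must be positive")
        if self.n_layers < 0:
            raise ValueError("n_layers must be non-negative")

    def dilation_of_layer(self, b: int) -> int:
        cycle = int(np.log2(self.max_dilation)) + 1
        return 2 ** (b % cycle)

    def receptive_field(self) -> int:
        """Number of positions either side of p that can influence logits at p."""
        half = self.kernel_width // 2
        return half * sum(self.dilation_of_layer(b) for b in range(self.n_layers))


class _Block(nn.Module):
    def __init__(self, hidden: int, kernel: int, dilation: int,
                 rng: np.random.Generator, name: str) -> None:
        half = hidden // 2
        self.norm = nn.LayerNorm(hidden, name + ".norm")
        self.act1 = nn.GELU()
        self.down = nn.Linear(hidden, half, rng, name + ".down")
        self.conv = nn.DilatedConv1d(half, half, kernel, dilation, rng, name + ".conv")
        self.act2 = nn.GELU()
        self.up = nn.Linear(half, hidden, rng, name + ".up")

    def forward(self, x: np.ndarray, keep: np.ndarray) -> np.ndarray:
        h = self.norm.forward(x)
        h = self.act1.forward(h)
        h = self.down.forward(h)
        h = h * keep  # pad positions contribute zeros to the convolution
        h = self.conv.forward(h)
        h = self.act2.forward(h)
        h = self.up.forward(h)
        return (x + h) * keep

    def backward(self, dy: np.ndarray, keep: np.ndarray) -> np.ndarray:
        dy = dy * keep
        dh = self.up.backward(dy)
        dh = self.act2.backward(dh)
        dh = self.conv.backward(dh)
        dh = dh * keep
        dh = self.down.backward(dh)
        dh = self.act1.backward(dh)
        dx = self.norm.backward(dh)
        return dy + dx

    def params(self) -> list[nn.Param]:
        return (self.norm.params() + self.down.params()
                + self.conv.params() + self.up.params())


class ByteNetMLM:
    """The masked LM: embedding table + residual dilated-CNN stack + decoder."""

    def __init__(self, config: ModelConfig, table: EmbeddingTable) -> None:
        if table.matrix.shape[0] != config.vocab_size:
            raise ValueError(
                f"embedding rows {table.matrix.shape[0]} != vocab_size {config.vocab_size}")
        if table.dim != config.embed_dim:
            raise ValueError(f"embedding dim {table.dim} != embed_dim {config.embed_dim}")
        self.config = config
        self.vocab = table.vocab
        rng = np.random.default_rng(config.seed)
        emb = table.matrix.astype(np.float32).copy()
        emb[self.vocab.pad_id] = 0.0  # PAD embeds to zero
        self.embedding = nn.Param(emb, "embedding")
        self.embedding_row_trainable = table.row_trainable_mask()
        self.embedding_provenance = table.provenance
        self.in_proj = nn.Linear(config.embed_dim, config.hidden_dim, rng, "in_proj")
        self.blocks = [
            _Block(config.hidden_dim, config.kernel_width,
                   config.dilation_of_layer(b), rng, f"block{b}")
            for b in range(config.n_layers)
        ]
        self.decoder = nn.Linear(config.hidden_dim, config.vocab_size, rng, "decoder")
        self._cache: dict | None = None

    # -- parameters -------------------------------------------------------
    def params(self) -> list[nn.Param]:
        out = [self.embedding] + self.in_proj.params()
        for blk in self.blocks:
            out.extend(blk.params())
        out.extend(self.decoder.params())
        return out

    def count_parameters(self) -> int:
        return sum(p.size for p in self.params())

    # -- forward / backward ----------------------------------------------
    def _keep_mask(self, tokens: np.ndarray, pad_mask: np.ndarray | None) -> np.ndarray:
        if pad_mask is None:
            pad_mask = tokens != self.vocab.pad_id
        return pad_mask.astype(np.float32)[..., None]

    def forward(self, tokens: np.ndarray, pad_mask: np.ndarray | None = None,
                return_hidden: bool = False) -> np.ndarray:
        """Logits (B, L, V) for a batch of token-id rows.

        ``pad_mask`` flags real positions (True = not padding); by default it
        is inferred from the PAD id. With ``return_hidden`` the final hidden
        states (B, L, H) before the decoder are returned instead.
        """
        tokens = np.asarray(tokens)
        if tokens.ndim == 1:
            tokens = tokens[None, :]
        if tokens.min(initial=0) < 0 or tokens.max(initial=0) >= self.config.vocab_size:
            raise ValueError("token id out of range")
        keep = self._keep_mask(tokens, pad_mask)
        x = self.embedding.value[tokens] * keep
        h = self.in_proj.forward(x) * keep
        for blk in self.blocks:
            h = blk.forward(h, keep)
        self._cache = {"tokens": tokens, "keep": keep, "hidden": h}
        if return_hidden:
            return h
        return self.decoder.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.decoder.backward(dlogits)
        self.backward_from_hidden(dh)

    def backward_from_hidden(self, dh: np.ndarray) -> None:
        cache = self._cache
        keep = cache["keep"]
        for blk in reversed(self.blocks):
            dh = blk.backward(dh, keep)
        dh = dh * keep
        dx = self.in_proj.backward(dh) * keep
        tokens = cache["tokens"]
        grad = np.zeros_like(self.embedding.value)
        np.add.at(grad, tokens.ravel(), dx.reshape(-1, dx.shape[-1]))
        grad[~self.embedding_row_trainable] = 0.0
        grad[self.vocab.pad_id] = 0.0
        self.embedding.grad += grad

    __call__ = forward

    # -- state ------------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {p.name: p.value for p in self.params()}

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: config + vocab + provenance + weights."""
        meta = {
            "config": asdict(self.config),
            "vocab": {
                "pfam_tokens": self.vocab.pfam_tokens,
                "class_tokens": self.vocab.class_tokens,
                "special_tokens": self.vocab.special_tokens,
            },
            "embedding_provenance": self.embedding_provenance,
            "embedding_row_trainable_all": bool(self.embedding_row_trainable.all()),
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            import io
            buf = io.BytesIO()
            np.savez(buf, **self.state_arrays())
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "ByteNetMLM":
        import io
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            with np.load(io.BytesIO(zf.read("weights.npz"))) as npz:
                state = {k: npz[k] for k in npz.files}
        vocab = PfamVocab(**meta["vocab"])
        config = ModelConfig(**meta["config"])
        table = EmbeddingTable(
            state["embedding"], vocab,
            trainable=meta["embedding_row_trainable_all"],
            provenance=meta["embedding_provenance"])
        model = cls(config, table)
        model.load_state(state)
        return model


def build_model(config: ModelConfig, table: EmbeddingTable) -> ByteNetMLM:
    """Instantiate the model from a config and an embedding table."""
    return ByteNetMLM(config, table)


def build_random_model(config: ModelConfig, vocab: PfamVocab) -> ByteNetMLM:
    """Convenience: model with a seeded random embedding table over ``vocab``."""
    if len(vocab) != config.vocab_size:
        raise ValueError(f"vocab size {len(vocab)} != config.vocab_size {config.vocab_size}")
    return ByteNetMLM(config, random_table(vocab, config.embed_dim, config.seed))


def count_parameters(config: ModelConfig) -> int:
    """Closed-form parameter count (embedding included) without allocation."""
    V, E, H = config.vocab_size, config.embed_dim, config.hidden_dim
    half = H // 2
    per_block = (2 * H                      # LayerNorm gamma/beta
                 + H * half + half          # down projection
                 + config.kernel_width * half * half + half  # dilated conv
                 + half * H + H)            # up projection
    return V * E + (E * H + H) + config.n_layers * per_block + (H * V + V)
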