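"""Token-embedding tables: pretrained (mean-pooled protein-LM vectors) or random.

Each Pfam token is represented by a d-dimensional vector (1280 at full
scale, matching mean-pooled per-residue protein-language-model embeddings
supplied as an external matrix). Three regimes are supported: pretrained
rows finetuned, pretrained rows frozen, and random rows finetuned. Class
and special tokens never have a pretrained counterpart, so their rows are
always randomly initialized and always trainable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .vocab import PfamVocab

DEFAULT_INIT_STD = 0.02  # zero-mean Gaussian init, common transformer practice


@dataclass
class EmbeddingTable:
    """|vocab| x d matrix keyed by token id.

    ``trainable`` marks whether Pfam rows may be updated during training
    (class/special rows always are); ``provenance`` is ``pretrained`` or
    ``random``.
    """

    matrix: np.ndarray
    vocab: PfamVocab
    trainable: bool = True
    provenance: str = "random"

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise ValueError("embedding matrix must be 2-D")
        if self.matrix.shape[0] != len(self.vocab):
            raise ValueError(
                f"row count {self.matrix.shape[0]} != vocab size {len(self.vocab)}")
        if self.matrix.shape[1] <= 0:
            raise ValueError("embedding dimension must be positive")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding matrix contains non-finite entries")

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1])

    def row_trainable_mask(self) -> np.ndarray:
        """Per-row trainability: Pfam rows follow ``trainable``; others always train."""
        mask = np.ones(len(self.vocab), dtype=bool)
        if not self.trainable:
            mask[: self.vocab.n_pfam] = False
        return mask

    def save_tsv(self, path: str | Path) -> None:
        d = self.dim
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("token\t" + "\t".join(f"v{i+1}" for i in range(d)) + "\n")
            for idx in range(len(self.vocab)):
                vals = "\t".join(repr(float(x)) for x in self.matrix[idx])
                fh.write(f"{self.vocab.token_of(idx)}\t{vals}\n")


def mean_pool(per_residue: np.ndarray) -> np.ndarray:
    """Average an L x d per-residue embedding matrix over its rows."""
    per_residue = np.asarray(per_residue, dtype=float)
    if per_residue.ndim != 2 or per_residue.shape[0] == 0:
        raise ValueError("mean_pool expects a non-empty L x d matrix")
    if not np.all(np.isfinite(per_residue)):
        raise ValueError("per-residue embeddings contain non-finite entries")
    return per_residue.mean(axis=0)


def random_table(vocab: PfamVocab, d: int, seed: int,
                 std: float = DEFAULT_INIT_STD) -> EmbeddingTable:
    """Seeded zero-mean Gaussian table (the random-initialization regime)."""
    if d <= 0:
        raise ValueError("embedding dimension must be positive")
    rng = np.random.default_rng(seed)
    matrix = rng.normal(0.0, std, size=(len(vocab), d)).astype(np.float32)
    return EmbeddingTable(matrix, vocab, trainable=True, provenance="random")


def load_table(path: str | Path, vocab: PfamVocab, missing_policy: str = "error",
               seed: int = 0, trainable: bool = True,
               std: float = DEFAULT_INIT_STD) -> EmbeddingTable:
    """Load a ``token<TAB>v1..v_d`` matrix file aligned to ``vocab`` ids.

    Pfam tokens absent from the file follow ``missing_policy`` (``error`` or
    ``random_fill``); class/special tokens are always random-filled from the
    recorded ``seed`` since no pretrained vector exists for them.
    """
    if missing_policy not in ("error", "random_fill"):
        raise ValueError("missing_policy must be 'error' or 'random_fill'")
    rows: dict[str, np.ndarray] = {}
    d: int | None = None
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("token"):
            raise ValueError(f"{path}: missing 'token' header line")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            vec = np.asarray([float(x) for x in parts[1:]], dtype=np.float32)
            if d is None:
                d = vec.size
            elif vec.size != d:
                raise ValueError(f"{path}: inconsistent dimension for {parts[0]!r}")
            rows[parts[0]] = vec
    if d is None:
        raise ValueError(f"{path}: no embedding rows found")

    rng = np.random.default_rng(seed)
    fill = rng.normal(0.0, std, size=(len(vocab), d)).astype(np.float32)
    matrix = fill.copy()
    for idx in range(len(vocab)):
        tok = vocab.token_of(idx)
        if tok in rows:
            matrix[idx] = rows[tok]
        elif idx < vocab.n_pfam and missing_policy == "error":
            raise ValueError(f"Pfam token {tok!r} missing from embedding file {path}")
    return EmbeddingTable(matrix, vocab, trainable=trainable, provenance="pretrained")
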