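"""Masked-LM training: BERT-style corruption, losses, ECE, and fine-tuning.

Corruption follows the standard masked-LM recipe: each non-pad position is
independently selected for supervision with probability 0.15; a selected
position is replaced by MASK with probability 0.8, by a uniformly drawn
Pfam token with probability 0.1, and left unchanged with probability 0.1.
The prepended class token is eligible for selection like any other token,
but random replacement only ever draws Pfam tokens.

Model quality is summarised by the exponentiated cross entropy (ECE):
``exp`` of the mean masked-reconstruction cross entropy over supervised
positions of a token group. A perfect predictor scores 1; a uniform guesser
scores the size of the relevant vocabulary (e.g. 55 for product classes).

Supervised fine-tuning shuffles positive (BGC) and negative domain chains
into one synthetic "genome" each epoch, chunks it, and trains a per-domain
binary logistic head on the encoder's final hidden states, selecting the
epoch with the best validation AUROC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .annotation import GenomeDomainTrack
from .corpus import Corpus, encode_record
from .model import ByteNetMLM
from .vocab import PfamVocab

ACTION_NONE, ACTION_MASK, ACTION_RANDOM, ACTION_UNCHANGED = 0, 1, 2, 3


@dataclass
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 1e-4
    n_epochs: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size <= 0 or self.learning_rate <= 0 or self.n_epochs <= 0:
            raise ValueError("batch_size, learning_rate and n_epochs must be positive")


@dataclass
class CorruptionPlan:
    corrupted: np.ndarray   # (B, L) ids after corruption
    supervised: np.ndarray  # (B, L) bool
    targets: np.ndarray     # (B, L) original ids
    actions: np.ndarray     # (B, L) int8 action codes


def corrupt(tokens: np.ndarray, vocab: PfamVocab, seed: int,
            p_select: float = 0.15, p_mask: float = 0.8,
            p_random: float = 0.1) -> CorruptionPlan:
    """Seeded BERT-style corruption of a (B, L) id batch (PAD excluded)."""
    tokens = np.asarray(tokens)
    rng = np.random.default_rng(seed)
    nonpad = tokens != vocab.pad_id
    supervised = (rng.random(tokens.shape) < p_select) & nonpad

    u = rng.random(tokens.shape)
    actions = np.full(tokens.shape, ACTION_NONE, dtype=np.int8)
    actions[supervised & (u < p_mask)] = ACTION_MASK
    actions[supervised & (u >= p_mask) & (u < p_mask + p_random)] = ACTION_RANDOM
    actions[supervised & (u >= p_mask + p_random)] = ACTION_UNCHANGED

    corrupted = tokens.copy()
    corrupted[actions == ACTION_MASK] = vocab.mask_id
    n_random = int((actions == ACTION_RANDOM).sum())
    if n_random:
        if vocab.n_pfam == 0:
            raise ValueError("random replacement requires a non-empty Pfam vocabulary")
        corrupted[actions == ACTION_RANDOM] = rng.integers(0, vocab.n_pfam, size=n_random)
    return CorruptionPlan(corrupted, supervised, tokens.copy(), actions)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _log_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    z = logits - m
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def mlm_loss(logits: np.ndarray, plan: CorruptionPlan) -> float:
    """Mean −log softmax probability of the target over supervised positions."""
    sup = plan.supervised
    if not sup.any():
        warnings.warn("no supervised positions; loss defined as 0", stacklevel=2)
        return 0.0
    logp = _log_softmax(np.asarray(logits, dtype=np.float64))
    nll = -np.take_along_axis(logp, plan.targets[..., None], axis=-1)[..., 0]
    return float(nll[sup].mean())


def mlm_loss_and_grad(logits: np.ndarray, plan: CorruptionPlan
                      ) -> tuple[float, np.ndarray]:
    """Loss plus d(loss)/d(logits), for the training loop."""
    sup = plan.supervised
    n_sup = int(sup.sum())
    if n_sup == 0:
        return 0.0, np.zeros_like(logits)
    logits64 = np.asarray(logits, dtype=np.float64)
    logp = _log_softmax(logits64)
    nll = -np.take_along_axis(logp, plan.targets[..., None], axis=-1)[..., 0]
    loss = float(nll[sup].mean())
    probs = np.exp(logp)
    grad = probs
    np.subtract.at(grad.reshape(-1, grad.shape[-1]),
                   (np.arange(grad[..., 0].size), plan.targets.ravel()), 1.0)
    grad *= sup[..., None] / n_sup
    return loss, grad.astype(np.float32)


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------

def pad_batch(seqs: Sequence[Sequence[int]], pad_id: int) -> np.ndarray:
    L = max((len(s) for s in seqs), default=0)
    out = np.full((len(seqs), max(L, 1)), pad_id, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out


def _call_model(model, plan: CorruptionPlan, pad_id: int) -> np.ndarray:
    pad_mask = plan.targets != pad_id
    if getattr(model, "wants_targets", False):
        return model(plan.corrupted, pad_mask, targets=plan.targets)
    return model(plan.corrupted, pad_mask)


# ---------------------------------------------------------------------------
# ECE
# ---------------------------------------------------------------------------

def ece(model, corpus: Corpus, token_group: str = "pfam", seed: int = 0,
        batch_size: int = 64, prepend_class: bool = True) -> float:
    """Exponentiated cross entropy of masked reconstruction on one token group.

    ``token_group`` is ``"pfam"``, ``"class"`` or ``"all"``; positions are
    grouped by their *target* token. The corruption draw is seeded so the
    measurement is reproducible. ``model`` is anything mapping
    ``(tokens, pad_mask) -> logits``; diagnostic stubs that need the true
    targets advertise ``wants_targets`` (see :class:`OracleStub`).
    """
    if len(corpus) == 0:
        raise ValueError("ece requires a non-empty corpus")
    vocab = corpus.vocab
    seqs = [encode_record(r, vocab, prepend_class=prepend_class) for r in corpus]
    rng = np.random.default_rng(seed)
    total_nll, total_n = 0.0, 0
    for lo in range(0, len(seqs), batch_size):
        tokens = pad_batch(seqs[lo: lo + batch_size], vocab.pad_id)
        plan = corrupt(tokens, vocab, seed=int(rng.integers(2**31)))
        logits = _call_model(model, plan, vocab.pad_id)
        sel = plan.supervised.copy()
        if token_group == "class":
            sel &= np.isin(plan.targets, np.asarray(vocab.class_range))
        elif token_group == "pfam":
            sel &= plan.targets < vocab.n_pfam
        elif token_group != "all":
            raise ValueError("token_group must be 'pfam', 'class' or 'all'")
        if sel.any():
            logp = _log_softmax(np.asarray(logits, dtype=np.float64))
            nll = -np.take_along_axis(logp, plan.targets[..., None], axis=-1)[..., 0]
            total_nll += float(nll[sel].sum())
            total_n += int(sel.sum())
    if total_n == 0:
        raise ValueError(f"no supervised positions in token group {token_group!r}")
    return float(np.exp(total_nll / total_n))


# ---------------------------------------------------------------------------
# Diagnostic stub predictors
# ---------------------------------------------------------------------------

class UniformStub:
    """Uniform distribution over one token group at every position.

    With the class group this is the random-guessing baseline whose class
    ECE equals the number of classes; with the Pfam group, the Pfam
    vocabulary size.
    """

    def __init__(self, vocab: PfamVocab, group: str = "all") -> None:
        self.vocab = vocab
        logits = np.full(len(vocab), -1e9)
        rng = {"pfam": vocab.pfam_range, "class": vocab.class_range,
               "all": range(len(vocab))}[group]
        logits[np.asarray(rng)] = 0.0
        self._logits = logits

    def __call__(self, tokens, pad_mask=None):
        tokens = np.asarray(tokens)
        return np.broadcast_to(self._logits, tokens.shape + (len(self.vocab),))


class OracleStub:
    """Places probability ``confidence`` on the true token at every position.

    A test double: it receives the uncorrupted targets through the
    ``wants_targets`` protocol, which real models never use. ``confidence=1``
    is the ideal predictor (ECE 1); ``confidence=0.5`` gives ECE 2.
    """

    wants_targets = True

    def __init__(self, vocab: PfamVocab, confidence: float = 1.0) -> None:
        if not 0.0 < confidence <= 1.0:
            raise ValueError("confidence must be in (0, 1]")
        self.vocab = vocab
        self.confidence = confidence

    def __call__(self, tokens, pad_mask=None, targets=None):
        if targets is None:
            raise ValueError("OracleStub requires targets")
        V = len(self.vocab)
        p = self.confidence
        off = -1e9 if p >= 1.0 else float(np.log((1.0 - p) / (V - 1)))
        logits = np.full(targets.shape + (V,), off)
        np.put_along_axis(logits, np.asarray(targets)[..., None],
                          0.0 if p >= 1.0 else float(np.log(p)), axis=-1)
        return logits


# ---------------------------------------------------------------------------
# Pretraining
# ---------------------------------------------------------------------------

@dataclass
class PretrainResult:
    model: ByteNetMLM
    history: list[dict]            # epoch, train_loss, val_loss
    best_epoch: int
    best_val_loss: float

    def save_log(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("epoch\ttrain_loss\tval_loss\n")
            for row in self.history:
                fh.write(f"{row['epoch']}\t{row['train_loss']:.6f}\t{row['val_loss']:.6f}\n")


def _epoch_loss(model: ByteNetMLM, seqs, vocab, batch_size, seed) -> float:
    """Corruption-seeded forward-only loss over a split (validation)."""
    rng = np.random.default_rng(seed)
    total, n = 0.0, 0
    for lo in range(0, len(seqs), batch_size):
        tokens = pad_batch(seqs[lo: lo + batch_size], vocab.pad_id)
        plan = corrupt(tokens, vocab, seed=int(rng.integers(2**31)))
        if not plan.supervised.any():
            continue
        logits = model(plan.corrupted, plan.targets != vocab.pad_id)
        total += mlm_loss(logits, plan) * int(plan.supervised.sum())
        n += int(plan.supervised.sum())
    return total / max(n, 1)


def pretrain(train: Corpus, val: Corpus, model: ByteNetMLM, cfg: TrainConfig,
             verbose: bool = False) -> PretrainResult:
    """Masked-LM pretraining; returns the epoch with the lowest validation loss."""
    if len(train) == 0 or len(val) == 0:
        raise ValueError("pretrain requires non-empty train and validation splits")
    vocab = model.vocab
    train_seqs = [encode_record(r, vocab) for r in train]
    val_seqs = [encode_record(r, vocab) for r in val]
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)

    history: list[dict] = []
    best_state, best_val, best_epoch = model.copy_state(), np.inf, -1
    val_seed = cfg.seed + 10_007  # fixed across epochs for comparable val losses
    for epoch in range(cfg.n_epochs):
        rng = np.random.default_rng(cfg.seed + epoch)
        perm = rng.permutation(len(train_seqs))
        losses, weights = [], []
        for lo in range(0, len(perm), cfg.batch_size):
            batch = [train_seqs[i] for i in perm[lo: lo + cfg.batch_size]]
            tokens = pad_batch(batch, vocab.pad_id)
            plan = corrupt(tokens, vocab, seed=int(rng.integers(2**31)))
            if not plan.supervised.any():
                continue
            logits = model(plan.corrupted, plan.targets != vocab.pad_id)
            loss, dlogits = mlm_loss_and_grad(logits, plan)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; aborting")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            weights.append(int(plan.supervised.sum()))
        train_loss = float(np.average(losses, weights=weights)) if losses else 0.0
        val_loss = _epoch_loss(model, val_seqs, vocab, cfg.batch_size, val_seed)
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if verbose:
            print(f"epoch {epoch:3d}  train {train_loss:.4f}  val {val_loss:.4f}")
        if val_loss < best_val:
            best_val, best_epoch, best_state = val_loss, epoch, model.copy_state()
    model.load_state(best_state)
    return PretrainResult(model, history, best_epoch, float(best_val))


# ---------------------------------------------------------------------------
# Supervised fine-tuning (per-domain in-BGC prediction)
# ---------------------------------------------------------------------------

@dataclass
class FinetunedModel:
    model: ByteNetMLM
    head: nn.Linear
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    def score_ids(self, ids: Sequence[int], chunk_len: int = 256) -> np.ndarray:
        """Per-domain in-BGC probability for one id chain."""
        vocab = self.model.vocab
        scores = np.empty(len(ids))
        for lo in range(0, len(ids), chunk_len):
            chunk = np.asarray(ids[lo: lo + chunk_len])[None, :]
            hidden = self.model(chunk, return_hidden=True)
            z = self.head.forward(hidden)[0, :, 0]
            scores[lo: lo + chunk.shape[1]] = 1.0 / (1.0 + np.exp(-z))
        return scores

    def score_track(self, track: GenomeDomainTrack, chunk_len: int = 256) -> np.ndarray:
        ids = self.model.vocab.encode(track.pfam_accessions, allow_unk=True)
        return self.score_ids(ids, chunk_len)


def _bce_and_grad(z: np.ndarray, y: np.ndarray, mask: np.ndarray
                  ) -> tuple[float, np.ndarray]:
    n = max(int(mask.sum()), 1)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    s = 1.0 / (1.0 + np.exp(-z))
    grad = (s - y) * mask / n
    return float((loss * mask).sum() / n), grad.astype(np.float32)


def finetune_supervised(model: ByteNetMLM,
                        positives: Sequence[Sequence[int]],
                        negatives: Sequence[Sequence[int]],
                        val_tracks: Sequence[GenomeDomainTrack],
                        cfg: TrainConfig,
                        chunk_len: int = 256,
                        freeze_encoder: bool = False) -> FinetunedModel:
    """Shuffle-into-genome fine-tuning of a per-domain binary head.

    Each epoch the positive and negative domain-id chains are permuted and
    concatenated into one long labelled track (1 for positive-origin
    domains), chunked into ``chunk_len`` segments, and the head (plus,
    unless frozen, the encoder) is trained with binary cross-entropy. The
    epoch with the highest domain AUROC on ``val_tracks`` is returned.
    """
    from .detection import auroc

    if not positives or not negatives:
        raise ValueError("finetune_supervised requires positives and negatives")
    vocab = model.vocab
    head = nn.Linear(model.config.hidden_dim, 1,
                     np.random.default_rng(cfg.seed + 77), "head")
    params = head.params() if freeze_encoder else model.params() + head.params()
    opt = nn.Adam(params, lr=cfg.learning_rate)

    seqs = [(list(s), 1) for s in positives] + [(list(s), 0) for s in negatives]
    val_ids = [vocab.encode(t.pfam_accessions, allow_unk=True) for t in val_tracks]
    val_labels = np.concatenate([np.asarray(t.labels) for t in val_tracks])

    ft = FinetunedModel(model, head)
    best_state: dict | None = None
    best_auroc = -np.inf
    for epoch in range(cfg.n_epochs):
        rng = np.random.default_rng(cfg.seed + epoch)
        perm = rng.permutation(len(seqs))
        genome = [tok for i in perm for tok in seqs[i][0]]
        labels = [seqs[i][1] for i in perm for _ in seqs[i][0]]
        chunks = [genome[lo: lo + chunk_len] for lo in range(0, len(genome), chunk_len)]
        lchunks = [labels[lo: lo + chunk_len] for lo in range(0, len(labels), chunk_len)]
        for lo in range(0, len(chunks), cfg.batch_size):
            tokens = pad_batch(chunks[lo: lo + cfg.batch_size], vocab.pad_id)
            y = np.zeros(tokens.shape, dtype=np.float64)
            mask = np.zeros(tokens.shape, dtype=np.float64)
            for i, lab in enumerate(lchunks[lo: lo + cfg.batch_size]):
                y[i, : len(lab)] = lab
                mask[i, : len(lab)] = 1.0
            hidden = model(tokens, mask.astype(bool), return_hidden=True)
            z = head.forward(hidden)[..., 0]
            loss, dz = _bce_and_grad(z, y, mask)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite fine-tuning loss at epoch {epoch}")
            opt.zero_grad()
            dh = head.backward(dz[..., None].astype(np.float32))
            if not freeze_encoder:
                model.backward_from_hidden(dh)
            opt.step()
        scores = np.concatenate([ft.score_ids(ids, chunk_len) for ids in val_ids])
        val_auroc = auroc(scores, val_labels)
        ft.history.append({"epoch": epoch, "val_auroc": val_auroc})
        if val_auroc > best_auroc:
            best_auroc, ft.best_epoch = val_auroc, epoch
            best_state = {**model.copy_state(),
                          "head.W": head.W.value.copy(), "head.b": head.b.value.copy()}
    assert best_state is not None
    model.load_state({k: v for k, v in best_state.items() if not k.startswith("head.")})
    head.W.value[...] = best_state["head.W"]
    head.b.value[...] = best_state["head.b"]
    return ft
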