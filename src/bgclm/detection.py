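"""Unsupervised BGC detection and zero-shot product-class prediction.

The model should be more confident on BGC-like context than on background.
For each stride-1 window of ``w`` (default 64) domains along a genome's
domain track, a MASK token is prepended (standing in the class-token slot)
and the model is queried once. Three quantities are read off per window:

* **start entropy** — entropy of the class prediction at the MASK position;
  low values mark likely BGC start locations,
* **domain entropy** — entropy of the full-vocabulary distribution at each
  domain position,
* **NLL** — negative log probability of the true domain at each position.

A domain interior to the track appears in ``w`` windows and thus collects
``w x 3`` values; its in-BGC score is the negated mean of all of them
(higher = more BGC-like). A position's start score is the negated start
entropy of the window beginning there.

Zero-shot class prediction prepends MASK to a whole BGC sequence and reads
the class-token slice of the softmax at the MASK position; predictions from
several models ensemble by arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .annotation import GenomeDomainTrack
from .training import _log_softmax, pad_batch
from .vocab import PfamVocab

DEFAULT_WINDOW = 64


class UndefinedMetricError(ValueError):
    """Metric undefined for the given labels (e.g. one class only)."""


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def windows(track: GenomeDomainTrack, vocab: PfamVocab, w: int = DEFAULT_WINDOW
            ) -> list[tuple[int, np.ndarray]]:
    """Stride-1 windows of ``w`` domains, each with a prepended MASK token.

    Returns ``(window_start, ids)`` pairs; ``ids[0]`` is MASK. A track
    shorter than ``w`` yields a single whole-track window. Out-of-vocabulary
    accessions map to UNK.
    """
    ids = vocab.encode(track.pfam_accessions, allow_unk=True)
    L = len(ids)
    if L == 0:
        raise ValueError("windows requires a non-empty track")
    span = min(L, w)
    return [(s, np.asarray([vocab.mask_id] + ids[s: s + span], dtype=np.int64))
            for s in range(L - span + 1)]


# ---------------------------------------------------------------------------
# Entropies and per-window scores
# ---------------------------------------------------------------------------

def entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats, with 0·ln 0 = 0."""
    p = np.asarray(p, dtype=np.float64)
    if p.ndim != 1 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("entropy expects a probability vector summing to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


@dataclass
class WindowScores:
    window_start: int
    start_entropy: float
    domain_entropy: np.ndarray  # length = window span
    nll: np.ndarray             # length = window span


def _scores_from_logits(logp: np.ndarray, tokens: np.ndarray, vocab: PfamVocab,
                        start: int, start_entropy_slice: str = "class") -> WindowScores:
    """logp: (L+1, V) log-softmax; tokens: (L+1,) ids with MASK first."""
    if start_entropy_slice == "class":
        cls = logp[0, np.asarray(vocab.class_range)]
        cls = cls - np.log(np.exp(cls - cls.max()).sum()) - cls.max()  # renormalize
        p0 = np.exp(cls)
    elif start_entropy_slice == "full":
        p0 = np.exp(logp[0])
    else:
        raise ValueError("start_entropy_slice must be 'class' or 'full'")
    start_ent = float(-(p0 * np.where(p0 > 0, np.log(np.maximum(p0, 1e-300)), 0.0)).sum())

    probs = np.exp(logp[1:])
    dom_ent = -(probs * np.where(probs > 0, logp[1:], 0.0)).sum(axis=-1)
    nll = -np.take_along_axis(logp[1:], tokens[1:, None], axis=-1)[:, 0]
    return WindowScores(start, start_ent, dom_ent, np.maximum(nll, 0.0))


def score_window(model, window: tuple[int, np.ndarray],
                 start_entropy_slice: str = "class") -> WindowScores:
    """Model confidence scores for one MASK-prepended window."""
    start, tokens = window
    vocab = model.vocab
    logits = model(tokens[None, :])
    logp = _log_softmax(np.asarray(logits, dtype=np.float64))[0]
    return _scores_from_logits(logp, tokens, vocab, start, start_entropy_slice)


def score_windows(model, wins: Sequence[tuple[int, np.ndarray]],
                  batch_size: int = 64,
                  start_entropy_slice: str = "class") -> list[WindowScores]:
    """Batched :func:`score_window` over many equal-or-varying-length windows."""
    vocab = model.vocab
    out: list[WindowScores] = []
    for lo in range(0, len(wins), batch_size):
        chunk = wins[lo: lo + batch_size]
        tokens = pad_batch([w[1] for w in chunk], vocab.pad_id)
        logits = model(tokens)
        logp = _log_softmax(np.asarray(logits, dtype=np.float64))
        for i, (start, ids) in enumerate(chunk):
            out.append(_scores_from_logits(logp[i, : len(ids)], ids, vocab,
                                           start, start_entropy_slice))
    return out


# ---------------------------------------------------------------------------
# Aggregation over windows
# ---------------------------------------------------------------------------

@dataclass
class DomainScoreTrack:
    """Aggregated per-domain scores for one genome track.

    ``domain_score[i]`` is the negated mean of every value the ``i``-th
    domain collects (start entropy, its domain entropy and its NLL, from
    each containing window); higher = more BGC-like. ``start_score[i]`` is
    the negated start entropy of the window beginning at ``i`` (NaN where no
    window starts). ``window_count[i]`` is the number of containing windows.
    """

    domain_score: np.ndarray
    start_score: np.ndarray
    window_count: np.ndarray

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#domain_index\tstart_score\tdomain_score\twindow_count\n")
            for i in range(len(self.domain_score)):
                ss = "nan" if np.isnan(self.start_score[i]) else f"{self.start_score[i]:.6f}"
                fh.write(f"{i}\t{ss}\t{self.domain_score[i]:.6f}\t{int(self.window_count[i])}\n")


def aggregate(track: GenomeDomainTrack, window_scores: Sequence[WindowScores],
              w: int = DEFAULT_WINDOW) -> DomainScoreTrack:
    L = len(track)
    value_sum = np.zeros(L)
    value_n = np.zeros(L, dtype=int)
    win_count = np.zeros(L, dtype=int)
    start_score = np.full(L, np.nan)
    for ws in window_scores:
        span = len(ws.nll)
        idx = np.arange(ws.window_start, ws.window_start + span)
        value_sum[idx] += ws.start_entropy + ws.domain_entropy + ws.nll
        value_n[idx] += 3
        win_count[idx] += 1
        start_score[ws.window_start] = -ws.start_entropy
    if (value_n == 0).any():
        raise ValueError("window scores do not cover the track")
    return DomainScoreTrack(-value_sum / value_n, start_score, win_count)


def score_track(model, track: GenomeDomainTrack, w: int = DEFAULT_WINDOW,
                batch_size: int = 64,
                start_entropy_slice: str = "class") -> DomainScoreTrack:
    """Windows -> per-window scores -> per-domain aggregation, in one call."""
    wins = windows(track, model.vocab, w)
    return aggregate(track, score_windows(model, wins, batch_size,
                                          start_entropy_slice), w)


# ---------------------------------------------------------------------------
# Zero-shot class prediction
# ---------------------------------------------------------------------------

def predict_class(model, domains: Sequence[int] | Sequence[str]) -> np.ndarray:
    """Class-probability vector for one BGC domain chain (MASK prepended)."""
    if len(domains) == 0:
        raise ValueError("predict_class requires a non-empty sequence")
    vocab = model.vocab
    if isinstance(domains[0], str):
        ids = vocab.encode(list(domains), allow_unk=True)
    else:
        ids = list(domains)
    tokens = np.asarray([vocab.mask_id] + ids, dtype=np.int64)
    logits = np.asarray(model(tokens[None, :]), dtype=np.float64)[0, 0]
    cls = logits[np.asarray(vocab.class_range)]
    cls = cls - cls.max()
    p = np.exp(cls)
    return p / p.sum()


def ensemble(predictions: Sequence[np.ndarray]) -> np.ndarray:
    """Arithmetic mean of class-probability vectors from several models."""
    if len(predictions) == 0:
        raise ValueError("ensemble requires at least one prediction")
    mat = np.asarray(predictions, dtype=np.float64)
    if mat.ndim != 2:
        raise ValueError("predictions must be equal-length vectors")
    return mat.mean(axis=0)


def map_classes(pred: np.ndarray, pretrain_classes: Sequence[str],
                mapping: Mapping[str, str], eval_classes: Sequence[str],
                other_label: str = "other") -> np.ndarray:
    """Project a pretraining-class simplex onto evaluation classes.

    Each pretraining class contributes its probability to its mapped
    evaluation class; unmapped classes fall into ``other_label``. The
    result is a simplex over ``eval_classes``.
    """
    pred = np.asarray(pred, dtype=np.float64)
    if pred.shape != (len(pretrain_classes),):
        raise ValueError("pred length must match pretrain_classes")
    idx = {c: i for i, c in enumerate(eval_classes)}
    out = np.zeros(len(eval_classes))
    for p, cls in zip(pred, pretrain_classes):
        target = mapping.get(cls, other_label)
        if target not in idx:
            raise ValueError(f"mapped class {target!r} not among evaluation classes")
        out[idx[target]] += p
    return out


def read_class_mapping(path) -> dict[str, str]:
    """TSV ``pretrain_class<TAB>eval_class``."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            src, dst = line.split("\t")
            mapping[src] = dst
    return mapping


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("metric undefined: labels contain a single class")
    return labels


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUROC (ties counted 1/2)."""
    labels = _check_binary(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def average_precision(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Step-wise average precision over ranked positives."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise UndefinedMetricError("average precision undefined without positives")
    return float(average_precision_score(labels, np.asarray(scores, dtype=np.float64)))


def evaluate_detection(track: GenomeDomainTrack, scores: DomainScoreTrack
                       ) -> dict[str, float]:
    """Domain AUROC and start AUROC of aggregated scores against track labels.

    Positions where no window starts (the trailing ``w-1`` domains) are
    excluded from the start AUROC.
    """
    if track.labels is None or track.starts is None:
        raise ValueError("track must carry labels and starts")
    out = {"domain_auroc": auroc(scores.domain_score, track.labels)}
    valid = ~np.isnan(scores.start_score)
    out["start_auroc"] = auroc(scores.start_score[valid],
                               np.asarray(track.starts)[valid])
    return out
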