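"""BGC records, corpora, the on-disk TSV format, and substring-aware splitting.

A corpus record is a product-class label plus an ordered Pfam-domain chain.
Because near-identical clusters recur across genomes, train/validation/test
splits must guarantee that no record in one split is a strict substring (as a
contiguous domain run) of a record in another split, and that nothing in
train/val overlaps designated holdout sets. Splitting therefore groups
records into substring-connected components and assigns whole components to
splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .vocab import DEFAULT_SPECIALS, PfamVocab, VocabularyError


class CorpusFormatError(ValueError):
    """Malformed corpus file (parse errors carry the offending line number)."""


@dataclass
class BGCRecord:
    """One biosynthetic gene cluster: class label + ordered Pfam accessions."""

    record_id: str
    class_label: str
    domains: list[str]
    source: str | None = None


@dataclass
class Corpus:
    records: list[BGCRecord]
    vocab: PfamVocab

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.class_label] = counts.get(rec.class_label, 0) + 1
        return counts


@dataclass
class SplitSpec:
    """Fractions for a train/val/test split plus the shuffling seed."""

    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be three non-negative reals")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


# ---------------------------------------------------------------------------
# TSV corpus I/O: record_id <TAB> class_label <TAB> dom1;dom2;...
# ---------------------------------------------------------------------------

def read_corpus(path: str | Path, vocab_policy: str = "build",
                vocab: PfamVocab | None = None) -> Corpus:
    """Read a corpus TSV.

    ``vocab_policy="build"`` constructs the vocabulary from observed tokens;
    ``"strict"`` requires ``vocab`` and errors on unknown tokens.
    """
    if vocab_policy not in ("build", "strict"):
        raise ValueError("vocab_policy must be 'build' or 'strict'")
    if vocab_policy == "strict" and vocab is None:
        raise ValueError("strict vocab_policy requires a vocab")

    records: list[BGCRecord] = []
    seen_ids: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
            record_id, class_label, domain_field = parts
            if record_id in seen_ids:
                raise CorpusFormatError(f"{path}:{lineno}: duplicate record id {record_id!r}")
            seen_ids.add(record_id)
            domains = [d for d in domain_field.split(";") if d]
            if vocab_policy == "strict":
                assert vocab is not None
                for d in domains:
                    if d not in vocab:
                        raise VocabularyError(
                            f"{path}:{lineno}: domain {d!r} not in vocabulary")
                if class_label not in vocab:
                    raise VocabularyError(
                        f"{path}:{lineno}: class {class_label!r} not in vocabulary")
            records.append(BGCRecord(record_id, class_label, domains))

    if vocab_policy == "build":
        vocab = PfamVocab.from_observed(
            (d for r in records for d in r.domains),
            (r.class_label for r in records),
            DEFAULT_SPECIALS,
        )
    assert vocab is not None
    return Corpus(records, vocab)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in corpus.records:
            fh.write(f"{rec.record_id}\t{rec.class_label}\t{';'.join(rec.domains)}\n")


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def encode_record(record: BGCRecord, vocab: PfamVocab, prepend_class: bool = True,
                  allow_unk: bool = False) -> list[int]:
    """Token ids for one record, optionally with the class token first."""
    ids = vocab.encode(record.domains, allow_unk=allow_unk)
    if prepend_class:
        ids = [vocab.id_of(record.class_label)] + ids
    return ids


# ---------------------------------------------------------------------------
# Substring relations and splitting
# ---------------------------------------------------------------------------

def _key(domains: Sequence[str]) -> str:
    # sentinel-delimited join so matches respect token boundaries
    return "\x1f" + "\x1f".join(domains) + "\x1f"


def is_strict_substring(a: Sequence[str], b: Sequence[str]) -> bool:
    """True iff ``a`` occurs as a contiguous run inside ``b`` and ``a != b``.

    Comparison is over domain tokens only; callers must not pass class tokens.
    """
    if len(a) >= len(b):
        return False
    return _key(a) in _key(b)


def _related(a: Sequence[str], b: Sequence[str]) -> bool:
    """Either direction of strict-substring containment, or exact equality."""
    ka, kb = _key(a), _key(b)
    return ka in kb or kb in ka


def remove_holdout_overlaps(records: list[BGCRecord],
                            holdout_corpora: Iterable[Corpus]) -> list[BGCRecord]:
    """Drop records that contain, equal, or are contained in any holdout record."""
    holdout_keys = [_key(r.domains) for c in holdout_corpora for r in c.records]
    kept = []
    for rec in records:
        k = _key(rec.domains)
        if any(k in hk or hk in k for hk in holdout_keys):
            continue
        kept.append(rec)
    return kept


def split_corpus(corpus: Corpus, spec: SplitSpec,
                 holdout_corpora: Sequence[Corpus] = ()) -> tuple[Corpus, Corpus, Corpus]:
    """Deterministic train/val/test split with cross-split substring exclusion.

    Records are grouped into connected components of the (undirected)
    strict-substring relation; components are shuffled by ``spec.seed`` and
    greedily assigned to the split with the largest remaining deficit, so
    sizes approximate the fractions subject to grouping. Records overlapping
    a holdout corpus are removed from train and validation only.
    """
    records = corpus.records
    n = len(records)
    if n == 0:
        empty = lambda: Corpus([], corpus.vocab)  # noqa: E731
        return empty(), empty(), empty()

    # union-find over substring-connected components
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    keys = [_key(r.domains) for r in records]
    order = sorted(range(n), key=lambda i: len(keys[i]))
    for ai in range(n):
        i = order[ai]
        for bi in range(ai + 1, n):
            j = order[bi]
            if keys[i] in keys[j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    comp_list = sorted(comps.values(), key=lambda c: min(c))

    rng = np.random.default_rng(spec.seed)
    rng.shuffle(comp_list)

    targets = [f * n for f in spec.fractions]
    sizes = [0.0, 0.0, 0.0]
    assignment: list[list[int]] = [[], [], []]
    for comp in comp_list:
        deficits = [targets[k] - sizes[k] for k in range(3)]
        k = int(np.argmax(deficits))
        assignment[k].extend(comp)
        sizes[k] += len(comp)

    splits = []
    for k in range(3):
        recs = [records[i] for i in sorted(assignment[k])]
        if k < 2 and holdout_corpora:  # train and val only
            recs = remove_holdout_overlaps(recs, holdout_corpora)
        splits.append(Corpus(recs, corpus.vocab))
    return splits[0], splits[1], splits[2]
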