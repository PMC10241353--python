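"""Seeded synthetic BGC corpora and genomes with implanted, labelled clusters.

The generator emulates the one statistical property of real BGC data the
model exploits: product classes differ in Pfam-domain composition. Each
class owns a disjoint *signature* set of Pfam tokens; all classes share a
*background* set. A synthetic BGC of class ``c`` draws each domain i.i.d.
from ``c``'s signature set with probability ``signature_purity`` and from
the background set otherwise. A synthetic genome is a uniform-background
domain chain with ``n_implants`` BGCs placed at non-overlapping positions,
labelled per domain (and per BGC-start).

Everything is deterministic given the spec seed; per-object seeds are fanned
out from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import DomainHit, GenomeDomainTrack
from .corpus import BGCRecord, Corpus
from .vocab import DEFAULT_SPECIALS, PfamVocab


@dataclass
class SynthSpec:
    """Study conditions for synthetic corpora and genomes.

    Defaults: 200 Pfams across 5 classes with 20 signature domains each and
    60 shared background domains, BGC lengths 16-48 domains, genomes of 500
    domains carrying 3 implanted BGCs, signature purity 0.8.
    """

    n_pfams: int = 200
    n_classes: int = 5
    signature_size: int = 20
    background_size: int = 60
    bgc_length_range: tuple[int, int] = (16, 48)
    genome_length: int = 500
    n_implants: int = 3
    signature_purity: float = 0.8
    markov: bool = False          # tandem-repeat structure within records
    markov_persistence: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signature_size * self.n_classes + self.background_size > self.n_pfams:
            raise ValueError("signature and background sets exceed n_pfams")
        lo, hi = self.bgc_length_range
        if not (0 < lo <= hi):
            raise ValueError("bgc_length_range must satisfy 0 < min <= max")
        if not 0.0 <= self.signature_purity <= 1.0:
            raise ValueError("signature_purity must lie in [0, 1]")

    # token-index sets (into the Pfam id range)
    def signature_ids(self, class_index: int) -> np.ndarray:
        lo = class_index * self.signature_size
        return np.arange(lo, lo + self.signature_size)

    def background_ids(self) -> np.ndarray:
        lo = self.n_classes * self.signature_size
        return np.arange(lo, lo + self.background_size)


def make_vocab(spec: SynthSpec) -> PfamVocab:
    """Deterministic vocabulary: SYN00001.. Pfams, classNN labels, specials."""
    pfams = [f"SYN{i + 1:05d}" for i in range(spec.n_pfams)]
    classes = [f"class{i + 1:02d}" for i in range(spec.n_classes)]
    return PfamVocab(pfams, classes, list(DEFAULT_SPECIALS))


def sample_bgc(spec: SynthSpec, class_index: int, seed: int,
               record_id: str | None = None, length: int | None = None) -> BGCRecord:
    """One class-conditional BGC record (domains i.i.d., see module docstring)."""
    if not 0 <= class_index < spec.n_classes:
        raise ValueError(f"class_index {class_index} out of range")
    rng = np.random.default_rng(seed)
    vocab = make_vocab(spec)
    lo, hi = spec.bgc_length_range
    if length is None:
        length = int(rng.integers(lo, hi + 1))
    from_sig = rng.random(length) < spec.signature_purity
    sig, bg = spec.signature_ids(class_index), spec.background_ids()
    ids = np.where(from_sig, rng.choice(sig, size=length), rng.choice(bg, size=length))
    if spec.markov:
        # first-order structure: repeat the previous domain (tandem repeats)
        repeat = rng.random(length) < spec.markov_persistence
        for i in range(1, length):
            if repeat[i]:
                ids[i] = ids[i - 1]
    return BGCRecord(
        record_id=record_id or f"SYNBGC-{seed}",
        class_label=vocab.class_tokens[class_index],
        domains=[vocab.pfam_tokens[i] for i in ids],
        source="synthetic")


def make_corpus(spec: SynthSpec, n_records: int, seed: int,
                class_weights: list[float] | None = None) -> Corpus:
    """Corpus of ``n_records`` synthetic BGCs.

    Class assignment is uniform by default; ``class_weights`` (length
    ``n_classes``, normalized internally) skews it to emulate imbalanced
    corpora.
    """
    if n_records < 0:
        raise ValueError("n_records must be non-negative")
    rng = np.random.default_rng(seed)
    vocab = make_vocab(spec)
    p = None
    if class_weights is not None:
        if len(class_weights) != spec.n_classes:
            raise ValueError("class_weights length must equal n_classes")
        p = np.asarray(class_weights, dtype=float)
        p = p / p.sum()
    records = []
    for i in range(n_records):
        cls = int(rng.integers(spec.n_classes)) if p is None \
            else int(rng.choice(spec.n_classes, p=p))
        rec = sample_bgc(spec, cls, seed=int(rng.integers(2**31)),
                         record_id=f"SYNBGC-{seed}-{i + 1:05d}")
        records.append(rec)
    return Corpus(records, vocab)


def sample_genome(spec: SynthSpec, seed: int,
                  genome_id: str | None = None) -> GenomeDomainTrack:
    """Background domain chain with labelled implanted BGCs.

    Implant positions come from a uniform stars-and-bars split of the
    background budget into ``n_implants + 1`` gaps, so implants are
    non-overlapping by construction. Labels flag in-BGC domains; starts flag
    each implant's first domain.
    """
    rng = np.random.default_rng(seed)
    vocab = make_vocab(spec)
    lengths = [int(rng.integers(spec.bgc_length_range[0], spec.bgc_length_range[1] + 1))
               for _ in range(spec.n_implants)]
    total_bg = spec.genome_length - sum(lengths)
    if total_bg < 0:
        raise ValueError("implants cannot fit in genome_length")
    cuts = np.sort(rng.integers(0, total_bg + 1, size=spec.n_implants))
    gaps = np.diff(np.concatenate([[0], cuts, [total_bg]]))

    bg = spec.background_ids()
    ids: list[int] = []
    labels: list[int] = []
    starts: list[int] = []

    def extend_background(n: int) -> None:
        ids.extend(rng.choice(bg, size=n).tolist())
        labels.extend([0] * n)
        starts.extend([0] * n)

    extend_background(int(gaps[0]))
    for k in range(spec.n_implants):
        cls = int(rng.integers(spec.n_classes))
        rec = sample_bgc(spec, cls, seed=int(rng.integers(2**31)), length=lengths[k])
        dom_ids = [vocab.id_of(d) for d in rec.domains]
        ids.extend(dom_ids)
        labels.extend([1] * len(dom_ids))
        starts.extend([1] + [0] * (len(dom_ids) - 1))
        extend_background(int(gaps[k + 1]))

    hits = [DomainHit(gene_id=f"g{i + 1:05d}", gene_order=i,
                      pfam_acc=vocab.pfam_tokens[t],
                      env_start=1, env_end=100, bitscore=100.0, evalue=1e-30)
            for i, t in enumerate(ids)]
    return GenomeDomainTrack(genome_id or f"syngenome-{seed}", hits, labels, starts)
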