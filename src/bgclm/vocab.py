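"""Joint token inventory over Pfam accessions, product-class labels and specials.

A BGC is modelled as an ordered chain of Pfam domains with a product-class
token prepended, so the vocabulary holds three disjoint token groups sharing
one contiguous integer id space:

* Pfam tokens  — ids ``[0, n_pfam)``
* class tokens — ids ``[n_pfam, n_pfam + n_class)``
* specials     — ids ``[n_pfam + n_class, size)``; always include MASK, PAD
  and UNK (out-of-vocabulary Pfams seen at inference map to UNK).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

MASK = "MASK"
PAD = "PAD"
UNK = "UNK"

DEFAULT_SPECIALS = (MASK, PAD, UNK)


class VocabularyError(KeyError):
    """A token cannot be resolved in (or added consistently to) a vocabulary."""


@dataclass
class PfamVocab:
    """Immutable-by-convention token inventory with stable integer ids.

    Parameters
    ----------
    pfam_tokens : ordered Pfam accession strings.
    class_tokens : ordered product-class label strings.
    special_tokens : ordered specials; must contain MASK and PAD.
    """

    pfam_tokens: list[str]
    class_tokens: list[str]
    special_tokens: list[str] = field(default_factory=lambda: list(DEFAULT_SPECIALS))

    def __post_init__(self) -> None:
        if MASK not in self.special_tokens or PAD not in self.special_tokens:
            raise ValueError("special_tokens must include MASK and PAD")
        self._id_of: dict[str, int] = {}
        for tok in (*self.pfam_tokens, *self.class_tokens, *self.special_tokens):
            if tok in self._id_of:
                raise ValueError(f"token {tok!r} appears in more than one group")
            self._id_of[tok] = len(self._id_of)
        self._tokens = list(self.pfam_tokens) + list(self.class_tokens) + list(self.special_tokens)

    # -- sizes and ranges -------------------------------------------------
    def __len__(self) -> int:
        return len(self._tokens)

    @property
    def n_pfam(self) -> int:
        return len(self.pfam_tokens)

    @property
    def n_class(self) -> int:
        return len(self.class_tokens)

    @property
    def pfam_range(self) -> range:
        return range(0, self.n_pfam)

    @property
    def class_range(self) -> range:
        return range(self.n_pfam, self.n_pfam + self.n_class)

    @property
    def special_range(self) -> range:
        return range(self.n_pfam + self.n_class, len(self))

    @property
    def mask_id(self) -> int:
        return self._id_of[MASK]

    @property
    def pad_id(self) -> int:
        return self._id_of[PAD]

    @property
    def unk_id(self) -> int:
        if UNK not in self._id_of:
            raise VocabularyError("vocabulary has no UNK special token")
        return self._id_of[UNK]

    # -- lookups ----------------------------------------------------------
    def id_of(self, token: str) -> int:
        try:
            return self._id_of[token]
        except KeyError:
            raise VocabularyError(f"unknown token {token!r}") from None

    def token_of(self, idx: int) -> str:
        return self._tokens[idx]

    def __contains__(self, token: str) -> bool:
        return token in self._id_of

    def encode(self, tokens: Iterable[str], allow_unk: bool = False) -> list[int]:
        out = []
        for tok in tokens:
            if allow_unk and tok not in self._id_of:
                out.append(self.unk_id)
            else:
                out.append(self.id_of(tok))
        return out

    def decode(self, ids: Sequence[int]) -> list[str]:
        return [self._tokens[i] for i in ids]

    def is_class_id(self, idx: int) -> bool:
        return idx in self.class_range

    def is_pfam_id(self, idx: int) -> bool:
        return idx < self.n_pfam

    # -- serialization ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write the three-section plain-text vocab file."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#PFAM\n")
            fh.writelines(t + "\n" for t in self.pfam_tokens)
            fh.write("#CLASS\n")
            fh.writelines(t + "\n" for t in self.class_tokens)
            fh.write("#SPECIAL\n")
            fh.writelines(t + "\n" for t in self.special_tokens)

    @classmethod
    def load(cls, path: str | Path) -> "PfamVocab":
        sections: dict[str, list[str]] = {"#PFAM": [], "#CLASS": [], "#SPECIAL": []}
        current: list[str] | None = None
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line in sections:
                    current = sections[line]
                elif current is None:
                    raise ValueError(f"vocab file {path}: token before a section header")
                else:
                    current.append(line)
        return cls(sections["#PFAM"], sections["#CLASS"], sections["#SPECIAL"])

    @classmethod
    def from_observed(
        cls,
        pfam_tokens: Iterable[str],
        class_tokens: Iterable[str],
        special_tokens: Sequence[str] = DEFAULT_SPECIALS,
    ) -> "PfamVocab":
        """Build a vocabulary from observed tokens, sorted for stable ids."""
        return cls(sorted(set(pfam_tokens)), sorted(set(class_tokens)), list(special_tokens))
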