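"""Note assembly, cleaning, tokenization, vocabulary and fixed-length encoding.

A stay's notes up to an HPA cutoff are concatenated in chart-time order,
de-identification placeholders (``[** ... **]``) are stripped, text is
lowercased and split into alphanumeric tokens, and the token sequence is
mapped to a fixed-length id vector (default 2000, head-truncated,
right-padded).
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .synthgen import StayRecord

PAD_ID = 0
UNK_ID = 1
DEFAULT_MAX_LEN = 2000
DEFAULT_MIN_COUNT = 3

_PLACEHOLDER_RE = re.compile(r"\[\*\*.*?\*\*\]", flags=re.DOTALL)
_TOKEN_RE = re.compile(r"[a-z0-9]+")


class EmptyCorpusError(ValueError):
    """Raised when a vocabulary is requested over a corpus with no tokens."""


def assemble_document(stay: StayRecord, cutoff_hpa: float) -> str:
    """Concatenate (single-space join) texts of notes with chart_hpa <= cutoff.

    Notes are ordered ascending by chart time (stable for ties), so the
    document at cutoff t is a prefix of the document at any later cutoff.
    """
    notes = sorted((n for n in stay.notes if n.chart_hpa <= cutoff_hpa),
                   key=lambda n: n.chart_hpa)
    return " ".join(n.text for n in notes)


def clean_and_tokenize(text: str) -> list[str]:
    """Strip de-identification placeholders, lowercase, split alphanumerics."""
    return _TOKEN_RE.findall(_PLACEHOLDER_RE.sub(" ", text).lower())


@dataclass
class Vocab:
    """Token-to-id map with reserved pad (0) and unknown (1) ids.

    Only tokens seen at least ``min_count`` times in the corpus the vocabulary
    was built from receive their own id; everything else maps to ``unk_id``.
    The pad id is tied to an all-zero embedding row downstream.
    """

    token_to_id: dict[str, int]
    counts: dict[str, int]
    min_count: int
    pad_id: int = PAD_ID
    unk_id: int = UNK_ID

    def __len__(self) -> int:
        return len(self.token_to_id) + 2  # + pad, unk

    def __post_init__(self) -> None:
        self._id_to_token = {i: t for t, i in self.token_to_id.items()}

    def id_of(self, token: str) -> int:
        return self.token_to_id.get(token, self.unk_id)

    def token_of(self, idx: int) -> str:
        if idx == self.pad_id:
            return "<pad>"
        if idx == self.unk_id:
            return "<unk>"
        return self._id_to_token[idx]

    def decode(self, ids: Sequence[int]) -> list[str]:
        return [self.token_of(int(i)) for i in ids if int(i) != self.pad_id]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            for tok, idx in sorted(self.token_to_id.items(), key=lambda kv: kv[1]):
                w.writerow([tok, idx, self.counts[tok]])

    @classmethod
    def from_tsv(cls, path: str | Path, min_count: int = DEFAULT_MIN_COUNT) -> "Vocab":
        token_to_id: dict[str, int] = {}
        counts: dict[str, int] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for tok, idx, cnt in csv.reader(fh, delimiter="\t"):
                token_to_id[tok] = int(idx)
                counts[tok] = int(cnt)
        return cls(token_to_id, counts, min_count)


def build_vocab(corpus: Iterable[Sequence[str]],
                min_count: int = DEFAULT_MIN_COUNT) -> Vocab:
    """Map every token occurring >= min_count times to a dense, stable id.

    Ids are assigned by descending frequency (ties broken alphabetically)
    starting at 2; pad and unk occupy 0 and 1.
    """
    counts: Counter[str] = Counter()
    for tokens in corpus:
        counts.update(tokens)
    if not counts:
        raise EmptyCorpusError("vocabulary requested over an empty corpus")
    kept = sorted((t for t, c in counts.items() if c >= min_count),
                  key=lambda t: (-counts[t], t))
    return Vocab({t: i + 2 for i, t in enumerate(kept)}, dict(counts), min_count)


@dataclass(frozen=True)
class EncodedDoc:
    """Fixed-length token-id sequence for one stay at one HPA cutoff."""

    stay_id: str
    cutoff_hpa: float
    token_ids: np.ndarray  # shape (max_len,), dtype int32
    true_length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "token_ids", np.asarray(self.token_ids, dtype=np.int32))


def encode(tokens: Sequence[str], vocab: Vocab, max_len: int = DEFAULT_MAX_LEN, *,
           stay_id: str = "", cutoff_hpa: float = float("nan"),
           tail_truncate: bool = False) -> EncodedDoc:
    """Map tokens to ids, truncated to ``max_len`` and right-padded with pad_id.

    Head truncation (keep the earliest text) is the default: in the early
    prediction setting the earliest notes are the ones actually available.
    """
    if tail_truncate:
        kept = tokens[-max_len:]
    else:
        kept = tokens[:max_len]
    ids = np.full(max_len, vocab.pad_id, dtype=np.int32)
    for i, t in enumerate(kept):
        ids[i] = vocab.id_of(t)
    return EncodedDoc(stay_id=stay_id, cutoff_hpa=cutoff_hpa,
                      token_ids=ids, true_length=len(kept))


def encode_stay(stay: StayRecord, cutoff_hpa: float, vocab: Vocab,
                max_len: int = DEFAULT_MAX_LEN, **kw) -> EncodedDoc:
    """assemble -> clean/tokenize -> encode, for one stay at one cutoff."""
    tokens = clean_and_tokenize(assemble_document(stay, cutoff_hpa))
    return encode(tokens, vocab, max_len, stay_id=stay.stay_id,
                  cutoff_hpa=cutoff_hpa, **kw)
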