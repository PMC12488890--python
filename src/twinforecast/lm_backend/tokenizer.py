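"""Lossless word-piece tokenizer for clinical prompt text.

Splits text into decimal numbers (kept whole, e.g. "11.2"), integers, words,
single punctuation characters and whitespace runs; detokenization is plain
concatenation, so encode->decode is exact for in-vocabulary text.  Keeping
each one-decimal value a single token means a small causal LM predicts a
value with one softmax over the value vocabulary observed in training.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Iterable

TOKEN_RE = re.compile(r"\d+\.\d+|\d+|[A-Za-z]+|[^\sA-Za-z0-9]|\s+")

PAD, BOS, SEP, EOS, UNK = "<pad>", "<bos>", "<sep>", "<eos>", "<unk>"
SPECIALS = (PAD, BOS, SEP, EOS, UNK)


def split_text(text: str) -> list[str]:
    return TOKEN_RE.findall(text)


class Tokenizer:
    def __init__(self, vocab: list[str]):
        for i, s in enumerate(SPECIALS):
            if vocab[i] != s:
                raise ValueError("vocab must start with the special tokens")
        self.vocab = list(vocab)
        self.index = {tok: i for i, tok in enumerate(self.vocab)}

    @classmethod
    def fit(cls, texts: Iterable[str]) -> "Tokenizer":
        counts: Counter[str] = Counter()
        for text in texts:
            counts.update(split_text(text))
        ordered = sorted(counts, key=lambda t: (-counts[t], t))
        return cls(list(SPECIALS) + ordered)

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def bos_id(self) -> int:
        return 1

    @property
    def sep_id(self) -> int:
        return 2

    @property
    def eos_id(self) -> int:
        return 3

    @property
    def unk_id(self) -> int:
        return 4

    def __len__(self) -> int:
        return len(self.vocab)

    def encode(self, text: str) -> list[int]:
        unk = self.unk_id
        return [self.index.get(tok, unk) for tok in split_text(text)]

    def decode(self, ids: Iterable[int]) -> str:
        special = set(range(len(SPECIALS)))
        return "".join(self.vocab[i] for i in ids if i not in special)

    def to_dict(self) -> dict:
        return {"vocab": self.vocab}

    @classmethod
    def from_dict(cls, d: dict) -> "Tokenizer":
        return cls(d["vocab"])
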