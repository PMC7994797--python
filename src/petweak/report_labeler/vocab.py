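"""Wordpiece vocabulary: greedy merge-based construction and tokenization.

Construction starts from all single characters observed in the corpus and
repeatedly merges the adjacent piece pair that removes the most tokens from
the corpus (ties broken by the lexicographically smallest merged string),
until the target size is reached. Rare words therefore decompose into
frequent fragments ("subcarinal" -> "sub" + "carinal") while common words
stay whole.

Tokenization is greedy longest-match-first within whitespace-delimited
words of the lowercased sentence; characters outside the vocabulary map to
the unknown marker. Evaluation/test texts must be excluded from the corpus
used for construction (caller's contract).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

__all__ = ["UNK", "WordpieceVocab", "TokenSequence", "build_wordpiece_vocab", "tokenize"]

UNK = "<unk>"

_WORD_RE = re.compile(r"\S+")


@dataclass
class WordpieceVocab:
    pieces: list[str]
    base_pieces: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if len(set(self.pieces)) != len(self.pieces):
            raise ValueError("duplicate wordpieces")
        if UNK not in self.pieces:
            self.pieces = [UNK] + self.pieces
        if not self.base_pieces:
            self.base_pieces = frozenset(p for p in self.pieces if len(p) == 1) | {UNK}
        self._index = {p: i for i, p in enumerate(self.pieces)}
        self._piece_set = set(self.pieces)
        self._max_len = max(len(p) for p in self.pieces)

    def __len__(self) -> int:
        return len(self.pieces)

    def __contains__(self, piece: str) -> bool:
        return piece in self._piece_set

    def index(self, piece: str) -> int:
        return self._index[piece]

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.pieces) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "WordpieceVocab":
        pieces = [line for line in Path(path).read_text().splitlines() if line]
        return cls(pieces=pieces)


@dataclass
class TokenSequence:
    """Wordpiece tokens of one sentence with per-token character offsets."""

    tokens: list[str]
    char_spans: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.tokens)

    def ids(self, vocab: WordpieceVocab) -> list[int]:
        return [vocab.index(t) if t in vocab else vocab.index(UNK) for t in self.tokens]

    def detokenize(self) -> str:
        """Reconstruct the lowercased sentence with whitespace collapsed."""
        out = []
        prev_end = None
        for token, (start, end) in zip(self.tokens, self.char_spans):
            if prev_end is not None and start > prev_end:
                out.append(" ")
            out.append(token)
            prev_end = end
        return "".join(out)


def _merge_word(pieces: tuple[str, ...], pair: tuple[str, str]) -> tuple[str, ...]:
    merged = pair[0] + pair[1]
    out: list[str] = []
    i = 0
    while i < len(pieces):
        if i + 1 < len(pieces) and pieces[i] == pair[0] and pieces[i + 1] == pair[1]:
            out.append(merged)
            i += 2
        else:
            out.append(pieces[i])
            i += 1
    return tuple(out)


def _pair_counts(words: dict[tuple[str, ...], int]) -> Counter:
    """Non-overlapping adjacent-pair occurrence counts, weighted by word frequency."""
    counts: Counter = Counter()
    for pieces, freq in words.items():
        i = 0
        while i + 1 < len(pieces):
            counts[(pieces[i], pieces[i + 1])] += freq
            if pieces[i] == pieces[i + 1]:
                i += 2  # "aaa" holds only one non-overlapping ("a","a")
            else:
                i += 1
    return counts


def build_wordpiece_vocab(
    corpus: Iterable[str],
    target_size: int = 3000,
    base: Optional[WordpieceVocab] = None,
) -> WordpieceVocab:
    """Greedy merge-based wordpiece selection minimizing corpus token count.

    Each merge step removes exactly (number of merged occurrences) tokens
    from the corpus, so picking the most frequent adjacent pair is the
    locally optimal greedy move.
    """
    word_freq: Counter = Counter()
    for text in corpus:
        for word in text.lower().split():
            word_freq[word] += 1
    if not word_freq:
        raise ValueError("empty corpus")

    chars = sorted({c for w in word_freq for c in w})
    pieces: list[str] = [UNK] + chars
    if base is not None:
        for p in base.pieces:
            if p not in pieces:
                pieces.append(p)
    if target_size < len(pieces):
        raise ValueError(
            f"target_size={target_size} below base coverage ({len(pieces)} pieces needed)"
        )

    piece_set = set(pieces)
    words: dict[tuple[str, ...], int] = {}
    for word, freq in word_freq.items():
        words[tuple(word)] = words.get(tuple(word), 0) + freq

    while len(pieces) < target_size:
        counts = _pair_counts(words)
        best = None
        for pair, count in counts.items():
            if pair[0] + pair[1] in piece_set:
                continue
            key = (-count, pair[0] + pair[1])
            if best is None or key < best[0]:
                best = (key, pair, count)
        if best is None or best[2] == 0:
            break
        _, pair, _ = best
        merged = pair[0] + pair[1]
        pieces.append(merged)
        piece_set.add(merged)
        words = {_merge_word(p, pair): f for p, f in words.items()}
    return WordpieceVocab(pieces=pieces)


def tokenize(sentence: str, vocab: WordpieceVocab) -> TokenSequence:
    """Greedy longest-match-first decomposition; every character consumed."""
    lowered = sentence.lower()
    tokens: list[str] = []
    spans: list[tuple[int, int]] = []
    for match in _WORD_RE.finditer(lowered):
        word, offset = match.group(0), match.start()
        i = 0
        while i < len(word):
            piece = None
            for j in range(min(len(word), i + vocab._max_len), i, -1):
                if word[i:j] in vocab:
                    piece = word[i:j]
                    break
            if piece is None:
                tokens.append(UNK)
                spans.append((offset + i, offset + i + 1))
                i += 1
            else:
                tokens.append(piece)
                spans.append((offset + i, offset + i + len(piece)))
                i += len(piece)
    return TokenSequence(tokens=tokens, char_spans=spans)
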