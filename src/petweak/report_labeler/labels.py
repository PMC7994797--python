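"""Token label sequences and the rule-based baseline labeler.

Token labels take values 0 (neutral/negative mention), 1 (abnormal
mention), or MASKED for tokens outside every mention span; masked tokens
are ignored by the training loss.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from ..ontology import RegionOntology
from ..tagging import Mention
from .vocab import TokenSequence

__all__ = [
    "MASKED",
    "TokenLabelSequence",
    "char_span_to_token_span",
    "label_tokens",
    "DEFAULT_NEGATIVE_KEYWORDS",
    "rule_based_label",
]

MASKED = None  # "-" in the labeling scheme {0, 1, -}

DEFAULT_NEGATIVE_KEYWORDS = (
    "physiologic",
    "without",
    "unremarkable",
    "no",
    "not",
    "negative",
    "resolved",
    "stable",
)


@dataclass
class TokenLabelSequence:
    """Per-token labels in {0, 1, MASKED}, aligned with a TokenSequence."""

    labels: list[Optional[int]]

    def __post_init__(self):
        for label in self.labels:
            if label is not MASKED and label not in (0, 1):
                raise ValueError(f"token label must be 0, 1 or MASKED, got {label!r}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def mask(self) -> list[bool]:
        return [label is not MASKED for label in self.labels]


def char_span_to_token_span(
    tokens: TokenSequence, char_span: tuple[int, int]
) -> tuple[int, int]:
    """Half-open token-index span of the tokens intersecting a character span."""
    start_char, end_char = char_span
    indices = [
        i
        for i, (s, e) in enumerate(tokens.char_spans)
        if s < end_char and e > start_char
    ]
    if not indices:
        raise ValueError(f"char span {char_span} maps to zero tokens")
    return indices[0], indices[-1] + 1


def label_tokens(
    tokens: TokenSequence,
    mentions: Sequence[Mention],
    mention_states: Mapping[int, int],
) -> TokenLabelSequence:
    """Assign each token its covering mention's state; others are MASKED.

    `mention_states` maps positions in `mentions` to {0, 1}. Overlapping
    mentions with conflicting states raise.
    """
    labels: list[Optional[int]] = [MASKED] * len(tokens)
    for m_idx, mention in enumerate(mentions):
        state = mention_states[m_idx]
        if state not in (0, 1):
            raise ValueError(f"mention state must be 0 or 1, got {state!r}")
        t_start, t_end = char_span_to_token_span(tokens, mention.char_span)
        for i in range(t_start, t_end):
            if labels[i] is not MASKED and labels[i] != state:
                raise ValueError(
                    f"token {i} covered by mentions with conflicting states"
                )
            labels[i] = state
    return TokenLabelSequence(labels=labels)


def _keyword_pattern(keywords: Sequence[str]) -> re.Pattern:
    joined = "|".join(re.escape(k) for k in keywords)
    return re.compile(rf"\b(?:{joined})\b", re.IGNORECASE)


def rule_based_label(
    sentence: str,
    mentions: Sequence[Mention],
    ontology: RegionOntology,
    negative_keywords: Sequence[str] = DEFAULT_NEGATIVE_KEYWORDS,
) -> list[tuple[str, int]]:
    """Keyword baseline: a sentence with no negative-finding keyword marks
    every mentioned region — and all its ancestors — abnormal; otherwise all
    mentioned regions are marked normal.
    """
    if not mentions:
        return []
    has_negative = bool(_keyword_pattern(negative_keywords).search(sentence))
    states: dict[str, int] = {}
    for mention in mentions:
        if has_negative:
            states.setdefault(mention.region_id, 0)
        else:
            states[mention.region_id] = 1
            for ancestor in ontology.ancestors(mention.region_id):
                states[ancestor] = 1
    return sorted(states.items())
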