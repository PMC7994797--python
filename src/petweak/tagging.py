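"""Report parsing and region-mention tagging.

Reports are split into the four conventional sections (clinical history,
procedure, findings, impression) and then into sentences; pattern-based
tagging functions locate region mentions in the findings and impression
sections only. All spans are 0-based and half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .ontology import RegionOntology

__all__ = ["SECTIONS", "ReportDocument", "Mention", "parse_report", "split_sentences", "tag_report"]

SECTIONS = ("clinical_history", "procedure", "findings", "impression")

_HEADER_RE = re.compile(
    r"^[ \t]*(clinical history|history|procedure|findings?|impression)[ \t]*:",
    re.IGNORECASE | re.MULTILINE,
)

_HEADER_TO_SECTION = {
    "clinical history": "clinical_history",
    "history": "clinical_history",
    "procedure": "procedure",
    "finding": "findings",
    "findings": "findings",
    "impression": "impression",
}

# Sentence boundaries: period or semicolon followed by whitespace. Decimal
# numbers ("SUV 6.5") and measurements ("13 x 12 mm") survive because their
# periods are not followed by whitespace.
_SENTENCE_SPLIT_RE = re.compile(r"(?<=[.;])\s+")


@dataclass
class ReportDocument:
    """A sectioned radiology report with its derived sentence list."""

    exam_id: str
    sections: dict[str, str]
    sentences: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        for name in SECTIONS:
            self.sections.setdefault(name, "")
        if not self.sentences:
            self.sentences = [
                (name, sent)
                for name in SECTIONS
                for sent in split_sentences(self.sections[name])
            ]

    def sentences_in(self, *section_names: str) -> list[tuple[int, str]]:
        """(sentence_index, text) pairs restricted to the given sections."""
        return [
            (i, text)
            for i, (section, text) in enumerate(self.sentences)
            if section in section_names
        ]


@dataclass
class Mention:
    """A located reference to a region inside one report sentence."""

    region_id: str
    section: str
    sentence_index: int
    char_span: tuple[int, int]
    token_span: Optional[tuple[int, int]] = None
    probability: Optional[float] = None

    def __post_init__(self):
        start, end = self.char_span
        if end <= start or start < 0:
            raise ValueError(f"bad char span {self.char_span}")
        if self.probability is not None and not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability out of range: {self.probability}")


def split_sentences(text: str) -> list[str]:
    if not text.strip():
        return []
    parts = _SENTENCE_SPLIT_RE.split(text.strip())
    return [p.strip() for p in parts if p.strip()]


def parse_report(raw_text: str, exam_id: str = "") -> ReportDocument:
    """Split free text into the four report sections by header keywords.

    Text preceding the first recognized header is assigned to
    clinical_history; missing sections come back as empty strings.
    """
    sections = {name: "" for name in SECTIONS}
    matches = list(_HEADER_RE.finditer(raw_text))
    if not matches:
        sections["clinical_history"] = raw_text.strip()
        return ReportDocument(exam_id=exam_id, sections=sections)
    preamble = raw_text[: matches[0].start()].strip()
    if preamble:
        sections["clinical_history"] = preamble
    for i, match in enumerate(matches):
        name = _HEADER_TO_SECTION[match.group(1).lower()]
        end = matches[i + 1].start() if i + 1 < len(matches) else len(raw_text)
        body = raw_text[match.end() : end].strip()
        if sections[name]:
            sections[name] = sections[name] + " " + body
        else:
            sections[name] = body
    return ReportDocument(exam_id=exam_id, sections=sections)


def _region_pattern(patterns: tuple[str, ...]) -> re.Pattern:
    # longest alternative first so the regex engine prefers the longest match
    ordered = sorted(patterns, key=len, reverse=True)
    joined = "|".join(f"(?:{p})" for p in ordered)
    return re.compile(rf"\b(?:{joined})\b", re.IGNORECASE)


def tag_report(report: ReportDocument, ontology: RegionOntology) -> list[Mention]:
    """Locate region mentions in the findings and impression sections.

    One Mention per (region, non-overlapping pattern match). Patterns for
    different regions may overlap and both fire. Output is ordered by
    (sentence index, character offset, region id).
    """
    compiled = {
        rid: _region_pattern(region.patterns) for rid, region in ontology.regions.items()
    }
    mentions: list[Mention] = []
    for sent_idx, text in report.sentences_in("findings", "impression"):
        section = report.sentences[sent_idx][0]
        for rid in sorted(compiled):
            for match in compiled[rid].finditer(text):
                mentions.append(
                    Mention(
                        region_id=rid,
                        section=section,
                        sentence_index=sent_idx,
                        char_span=(match.start(), match.end()),
                    )
                )
    mentions.sort(key=lambda m: (m.sentence_index, m.char_span[0], m.region_id))
    return mentions
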