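"""Weak-label engine: report -> mentions -> probabilities -> region map.

Ties together tagging, mention scoring (trained model or keyword rule),
and upward propagation through the ontology; also selects the task regions
by label prevalence and derives binary mortality labels.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .ontology import RegionOntology, RegionProbabilityMap
from .report_labeler import (
    SequenceEncoder,
    TokenClassifierHead,
    WordpieceVocab,
    predict_mention_probability,
    rule_based_label,
)
from .report_labeler.labels import DEFAULT_NEGATIVE_KEYWORDS
from .tagging import ReportDocument, tag_report

__all__ = [
    "RuleLabeler",
    "ModelLabeler",
    "generate_weak_labels",
    "label_table",
    "select_task_regions",
    "derive_mortality_label",
]


@dataclass
class RuleLabeler:
    """Keyword baseline: mention probabilities are hard 0/1."""

    negative_keywords: Sequence[str] = DEFAULT_NEGATIVE_KEYWORDS

    def __call__(self, sentence, mentions, ontology) -> list[tuple[str, float]]:
        states = rule_based_label(sentence, mentions, ontology, self.negative_keywords)
        return [(rid, float(state)) for rid, state in states]


@dataclass
class ModelLabeler:
    """Trained token classifier; mention probability = mean token probability."""

    encoder: SequenceEncoder
    head: TokenClassifierHead
    vocab: WordpieceVocab

    def __call__(self, sentence, mentions, ontology) -> list[tuple[str, float]]:
        scored = predict_mention_probability(
            sentence, mentions, self.encoder, self.head, self.vocab
        )
        return [(m.region_id, m.probability) for m in scored]


def generate_weak_labels(
    report: ReportDocument,
    ontology: RegionOntology,
    labeler,
) -> RegionProbabilityMap:
    """Tag findings/impression, score mentions, propagate up the ontology."""
    mentions = tag_report(report, ontology)
    by_sentence: dict[int, list] = {}
    for m in mentions:
        by_sentence.setdefault(m.sentence_index, []).append(m)
    mention_probs: list[tuple[str, float]] = []
    for sent_idx, sent_mentions in sorted(by_sentence.items()):
        sentence = report.sentences[sent_idx][1]
        mention_probs.extend(labeler(sentence, sent_mentions, ontology))
    return ontology.propagate(mention_probs)


def label_table(
    reports: Sequence[ReportDocument],
    ontology: RegionOntology,
    labeler,
) -> pd.DataFrame:
    """Exams x regions table of propagated weak-label probabilities."""
    rows = {}
    for report in reports:
        probs = generate_weak_labels(report, ontology, labeler)
        rows[report.exam_id] = {rid: probs.get(rid) for rid in ontology}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "exam_id"
    return table[sorted(ontology)]


def select_task_regions(
    labels: Sequence[RegionProbabilityMap],
    threshold_main: float = 0.10,
    threshold_rare: float = 0.03,
    binarize_at: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Split regions into main (prevalence >= threshold_main) and rare
    (0 < prevalence < threshold_rare) sets by binarized label prevalence.

    Both lists are ordered by prevalence descending (region id breaks ties).
    """
    if not labels:
        raise ValueError("empty label set")
    regions = sorted({rid for m in labels for rid in m.probs})
    n = len(labels)
    prevalence = {
        rid: sum(1 for m in labels if m.get(rid) >= binarize_at) / n for rid in regions
    }
    order = sorted(regions, key=lambda r: (-prevalence[r], r))
    main = [r for r in order if prevalence[r] >= threshold_main]
    rare = [r for r in order if 0.0 < prevalence[r] < threshold_rare]
    return main, rare


def derive_mortality_label(
    date_of_death: Optional[datetime.date],
    scan_date: datetime.date,
    x: int,
) -> int:
    """1 iff death occurred within x days of the scan (inclusive).

    Patients without a recorded date of death are assumed to survive
    (label 0). A death date before the scan date is flagged as an error.
    """
    if date_of_death is None:
        return 0
    delta = (date_of_death - scan_date).days
    if delta < 0:
        raise ValueError(
            f"date of death {date_of_death} precedes scan date {scan_date}"
        )
    return int(delta <= x)
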