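"""Synthetic cohorts: paired templated reports and blob phantoms.

Each synthetic exam carries a full ground truth: per-region abnormality
states, a sectioned report whose findings/impression sentences mention
regions in abnormal, explicitly negative, or neutral contexts (with the
mention span and state recorded per sentence), a 2-channel volume in which
state-1 leaf regions carry an elevated-uptake Gaussian blob strictly inside
a deterministic axis-aligned box mask on the PET channel, and an optional
death date whose hazard grows with the number of abnormal regions.

Neutral templates come in two flavors: "soft" ones containing a default
negative keyword ("physiologic ...", correctly handled by the keyword
baseline) and "hard" ones with no such keyword (baseline false positives,
which a trained context classifier can avoid).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .ontology import AnatomicalRegion, RegionOntology, RegionProbabilityMap
from .report_labeler import LabeledSentence, WordpieceVocab, make_labeled_sentence
from .scan_model import ScanVolume
from .tagging import Mention, ReportDocument

__all__ = [
    "PlantedMention",
    "SyntheticExam",
    "MortalityLink",
    "demo_ontology",
    "leaf_mask_layout",
    "generate_cohort",
    "oracle_labels",
    "cohort_labeled_sentences",
]

ABNORMAL_TEMPLATES = (
    "Abnormal FDG uptake in the {name}.",
    "There is intense radiotracer uptake in the {name}.",
    "Focal hypermetabolic activity seen in the {name}.",
)

NEGATIVE_TEMPLATES = (
    "No abnormal FDG uptake in the {name}.",
    "The {name} is unremarkable.",
)

# "soft" neutrals contain a default negative keyword; "hard" ones do not
NEUTRAL_SOFT_TEMPLATES = ("Intense physiologic uptake in the {name}.",)
NEUTRAL_HARD_TEMPLATES = (
    "Mild uptake in the {name} likely inflammatory.",
    "Uptake in the {name} consistent with usual metabolic activity.",
)


@dataclass
class PlantedMention:
    """Ground truth for one generated sentence mentioning one region."""

    section: str
    sentence: str
    region_id: str
    char_span: tuple[int, int]
    state: int  # 1 abnormal, 0 neutral/negative
    hard_neutral: bool = False


@dataclass
class SyntheticExam:
    exam_id: str
    region_states: dict[str, int]  # leaf regions only
    report: ReportDocument
    planted: list[PlantedMention]
    volume: ScanVolume
    region_masks: dict[str, np.ndarray]
    scan_date: datetime.date
    date_of_death: Optional[datetime.date] = None


@dataclass
class MortalityLink:
    """Logistic death hazard on the number of abnormal leaf regions."""

    intercept: float = -2.0
    slope: float = 1.0
    max_days: int = 365


def demo_ontology() -> RegionOntology:
    """Small multi-level ontology with 8 leaf regions carrying masks."""

    def region(rid: str, name: str, *extra_patterns: str) -> AnatomicalRegion:
        return AnatomicalRegion(id=rid, display_name=name, patterns=(name, *extra_patterns))

    regions = [
        region("body", "body", "whole body"),
        region("chest", "chest", "thorax"),
        region("lungs", "lungs"),
        region("left_lung", "left lung"),
        region("right_lung", "right lung"),
        region("abdomen", "abdomen"),
        region("liver", "liver", "hepatic"),
        region("spleen", "spleen", "splenic"),
        region("kidneys", "kidneys", "renal"),
        region("left_kidney", "left kidney"),
        region("right_kidney", "right kidney"),
        region("lymph_nodes", "lymph nodes", "lymph node"),
        region("axillary_lymph_nodes", "axillary lymph nodes", "axillary lymph node"),
        region("inguinal_lymph_nodes", "inguinal lymph nodes", "inguinal lymph node"),
    ]
    edges = [
        ("body", "chest"),
        ("body", "abdomen"),
        ("body", "lymph_nodes"),
        ("chest", "lungs"),
        ("lungs", "left_lung"),
        ("lungs", "right_lung"),
        ("abdomen", "liver"),
        ("abdomen", "spleen"),
        ("abdomen", "kidneys"),
        ("kidneys", "left_kidney"),
        ("kidneys", "right_kidney"),
        ("lymph_nodes", "axillary_lymph_nodes"),
        ("lymph_nodes", "inguinal_lymph_nodes"),
    ]
    return RegionOntology(regions, edges)


# fractional boxes (y0, y1, x0, x1, z0, z1) in a body-like arrangement:
# lungs upper, liver mid-right, kidneys lower, nodes as small boxes
_BODY_LAYOUT: dict[str, tuple[float, float, float, float, float, float]] = {
    "left_lung": (0.05, 0.40, 0.52, 0.95, 0.10, 0.90),
    "right_lung": (0.05, 0.40, 0.05, 0.48, 0.10, 0.90),
    "liver": (0.42, 0.68, 0.06, 0.48, 0.10, 0.90),
    "spleen": (0.42, 0.68, 0.52, 0.94, 0.10, 0.90),
    "right_kidney": (0.70, 0.97, 0.06, 0.46, 0.06, 0.48),
    "left_kidney": (0.70, 0.97, 0.54, 0.94, 0.06, 0.48),
    "axillary_lymph_nodes": (0.02, 0.25, 0.02, 0.22, 0.25, 0.75),
    "inguinal_lymph_nodes": (0.70, 0.97, 0.30, 0.70, 0.54, 0.95),
}


def _auto_layout(leaves: Sequence[str]) -> dict[str, tuple[float, ...]]:
    """Deterministic tiling for leaf sets without a named layout."""
    n = len(leaves)
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    layout = {}
    for i, rid in enumerate(sorted(leaves)):
        r, c = divmod(i, cols)
        y0, y1 = r / rows, (r + 0.6) / rows
        x0, x1 = c / cols, (c + 0.6) / cols
        layout[rid] = (y0 + 0.02, min(y1, 0.98), x0 + 0.02, min(x1, 0.98), 0.2, 0.8)
    return layout


def leaf_mask_layout(
    ontology: RegionOntology, volume_shape: tuple[int, int, int]
) -> dict[str, np.ndarray]:
    """Boolean box masks for every region, scaled to the volume shape.

    Leaves get their own box; inner regions get the union of their
    descendants' leaf boxes.
    """
    h, w, l = volume_shape
    leaves = ontology.leaves()
    if all(rid in _BODY_LAYOUT for rid in leaves):
        fractional = {rid: _BODY_LAYOUT[rid] for rid in leaves}
    else:
        fractional = _auto_layout(leaves)
    masks: dict[str, np.ndarray] = {}
    for rid, (y0, y1, x0, x1, z0, z1) in fractional.items():
        mask = np.zeros(volume_shape, dtype=bool)
        ys, ye = int(y0 * h), max(int(y1 * h), int(y0 * h) + 1)
        xs, xe = int(x0 * w), max(int(x1 * w), int(x0 * w) + 1)
        zs, ze = int(z0 * l), max(int(z1 * l), int(z0 * l) + 1)
        mask[ys:ye, xs:xe, zs:ze] = True
        masks[rid] = mask
    for rid in ontology:
        if rid in masks:
            continue
        union = np.zeros(volume_shape, dtype=bool)
        for leaf in ontology.descendants(rid) & set(masks):
            union |= masks[leaf]
        masks[rid] = union
    return masks


def _ct_texture(shape: tuple[int, int, int]) -> np.ndarray:
    """Fixed anatomical texture: a soft body ellipse on every slice."""
    h, w, l = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.sqrt(((yy - cy) / (0.45 * h)) ** 2 + ((xx - cx) / (0.4 * w)) ** 2)
    body = np.clip(1.0 - r, 0.0, 1.0)
    return np.repeat(body[:, :, None], l, axis=2)


def _gaussian_blob(shape: tuple[int, int, int], box: np.ndarray, peak: float) -> np.ndarray:
    ys, xs, zs = np.nonzero(box)
    cy, cx, cz = ys.mean(), xs.mean(), zs.mean()
    sy = max((ys.max() - ys.min()) / 4.0, 0.75)
    sx = max((xs.max() - xs.min()) / 4.0, 0.75)
    sz = max((zs.max() - zs.min()) / 4.0, 0.75)
    yy, xx, zz = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    blob = peak * np.exp(
        -(
            (yy - cy) ** 2 / (2 * sy**2)
            + (xx - cx) ** 2 / (2 * sx**2)
            + (zz - cz) ** 2 / (2 * sz**2)
        )
    )
    return blob * box  # strictly confined to the mask


def _build_report(
    exam_id: str,
    states: Mapping[str, int],
    ontology: RegionOntology,
    rng: np.random.Generator,
    neutral_sentence_rate: float,
    negative_sentence_rate: float,
) -> tuple[ReportDocument, list[PlantedMention]]:
    planted: list[PlantedMention] = []
    findings: list[str] = []

    def add(section_sentences, section, template, rid, state, hard=False):
        name = ontology.regions[rid].display_name
        sentence = template.format(name=name)
        start = sentence.index(name)
        section_sentences.append(sentence)
        planted.append(
            PlantedMention(
                section=section,
                sentence=sentence,
                region_id=rid,
                char_span=(start, start + len(name)),
                state=state,
                hard_neutral=hard,
            )
        )

    abnormal = [rid for rid in sorted(states) if states[rid] == 1]
    for rid in sorted(states):
        if states[rid] == 1:
            template = ABNORMAL_TEMPLATES[rng.integers(len(ABNORMAL_TEMPLATES))]
            add(findings, "findings", template, rid, 1)
        elif rng.random() < neutral_sentence_rate:
            pool = NEUTRAL_SOFT_TEMPLATES + NEUTRAL_HARD_TEMPLATES
            k = int(rng.integers(len(pool)))
            add(findings, "findings", pool[k], rid, 0, hard=k >= len(NEUTRAL_SOFT_TEMPLATES))
        elif rng.random() < negative_sentence_rate:
            template = NEGATIVE_TEMPLATES[rng.integers(len(NEGATIVE_TEMPLATES))]
            add(findings, "findings", template, rid, 0)

    impression: list[str] = []
    if abnormal:
        rid = abnormal[int(rng.integers(len(abnormal)))]
        add(impression, "impression", ABNORMAL_TEMPLATES[0], rid, 1)
    else:
        impression.append("Unremarkable whole-body study.")

    sections = {
        "clinical_history": "Restaging examination.",
        "procedure": "Whole-body FDG PET CT acquired per protocol.",
        "findings": " ".join(findings),
        "impression": " ".join(impression),
    }
    return ReportDocument(exam_id=exam_id, sections=sections), planted


def generate_cohort(
    ontology: RegionOntology,
    n_exams: int,
    prevalences: Mapping[str, float],
    volume_shape: tuple[int, int, int] = (64, 64, 16),
    blob_intensity: float = 3.0,
    noise_sd: float = 0.3,
    neutral_sentence_rate: float = 0.0,
    negative_sentence_rate: float = 0.5,
    mortality_link: Optional[MortalityLink] = None,
    seed: int = 0,
) -> list[SyntheticExam]:
    """Generate a fully ground-truthed cohort of paired reports and volumes.

    `prevalences` maps leaf region ids to abnormality prevalence in [0, 1];
    leaves not listed get prevalence 0. All randomness derives from `seed`.
    """
    for rid, p in prevalences.items():
        if rid not in ontology:
            raise KeyError(f"unknown region {rid!r}")
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"prevalence for {rid!r} out of range: {p}")
    rng = np.random.default_rng(seed)
    leaves = ontology.leaves()
    masks = leaf_mask_layout(ontology, volume_shape)
    ct = _ct_texture(volume_shape)
    base_date = datetime.date(2005, 1, 1)

    exams: list[SyntheticExam] = []
    for i in range(n_exams):
        states = {
            rid: int(rng.random() < prevalences.get(rid, 0.0)) for rid in leaves
        }
        pet = rng.normal(0.0, noise_sd, volume_shape)
        for rid in leaves:
            if states[rid]:
                pet += _gaussian_blob(volume_shape, masks[rid], blob_intensity)
        report, planted = _build_report(
            f"exam{i:04d}", states, ontology, rng, neutral_sentence_rate, negative_sentence_rate
        )
        scan_date = base_date + datetime.timedelta(days=int(rng.integers(0, 365)))
        date_of_death = None
        if mortality_link is not None:
            n_abn = sum(states.values())
            p_death = 1.0 / (
                1.0 + np.exp(-(mortality_link.intercept + mortality_link.slope * n_abn))
            )
            if rng.random() < p_death:
                date_of_death = scan_date + datetime.timedelta(
                    days=int(rng.integers(0, mortality_link.max_days + 1))
                )
        exams.append(
            SyntheticExam(
                exam_id=f"exam{i:04d}",
                region_states=states,
                report=report,
                planted=planted,
                volume=ScanVolume(data=np.stack([pet, ct], axis=0)),
                region_masks=masks,
                scan_date=scan_date,
                date_of_death=date_of_death,
            )
        )
    return exams


def oracle_labels(
    exams: Sequence[SyntheticExam], ontology: RegionOntology
) -> list[RegionProbabilityMap]:
    """Ground-truth states OR-propagated up the ontology (the p -> 1 limit
    of probabilistic propagation)."""
    out = []
    for exam in exams:
        mention_probs = [(rid, float(state)) for rid, state in exam.region_states.items()]
        out.append(ontology.propagate(mention_probs))
    return out


def cohort_labeled_sentences(
    exams: Sequence[SyntheticExam], vocab: WordpieceVocab
) -> list[LabeledSentence]:
    """Token-labeled sentences for report-model training, one per planted
    mention sentence."""
    items = []
    for exam in exams:
        for planted in exam.planted:
            mention = Mention(
                region_id=planted.region_id,
                section=planted.section,
                sentence_index=0,
                char_span=planted.char_span,
            )
            items.append(
                make_labeled_sentence(planted.sentence, [mention], [planted.state], vocab)
            )
    return items
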