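"""Anatomical-region ontology: a DAG of regions with tagging patterns.

The ontology is the substrate for weak-label propagation: each region's
probability of abnormality is the probability that at least one mention of
the region or any of its descendants occurred in an abnormal context,
assuming mention independence:

    P(t is abnormal) = 1 - prod_i (1 - p_i)

over the mention probabilities p_1..p_{n_t} collected from t and the full
descendant closure of t.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

__all__ = [
    "AnatomicalRegion",
    "RegionOntology",
    "RegionProbabilityMap",
    "OntologyError",
    "CycleError",
    "load_ontology",
    "build_ontology_candidates",
]


class OntologyError(ValueError):
    """Malformed ontology definition."""


class CycleError(OntologyError):
    """The region graph contains a directed cycle."""


@dataclass(frozen=True)
class AnatomicalRegion:
    """A node of the ontology with its case-insensitive tagging patterns."""

    id: str
    display_name: str
    patterns: tuple[str, ...]

    def __post_init__(self):
        if not self.patterns:
            raise OntologyError(f"region {self.id!r} has no patterns")
        for pat in self.patterns:
            try:
                re.compile(pat, re.IGNORECASE)
            except re.error as exc:
                raise OntologyError(f"region {self.id!r}: bad pattern {pat!r}: {exc}") from exc


@dataclass
class RegionProbabilityMap:
    """Mapping region id -> probability of abnormality in [0, 1]."""

    probs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for rid, p in self.probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability for {rid!r} out of range: {p}")

    def __getitem__(self, region_id: str) -> float:
        return self.probs[region_id]

    def get(self, region_id: str, default: float = 0.0) -> float:
        return self.probs.get(region_id, default)

    def binarize(self, threshold: float = 0.5) -> dict[str, int]:
        return {rid: int(p >= threshold) for rid, p in self.probs.items()}


class RegionOntology:
    """Directed-acyclic graph of anatomical regions.

    Edges point from parent (coarse) to child (fine): chest -> lungs.
    """

    def __init__(self, regions: Iterable[AnatomicalRegion], edges: Iterable[tuple[str, str]]):
        self.regions: dict[str, AnatomicalRegion] = {}
        for region in regions:
            if region.id in self.regions:
                raise OntologyError(f"duplicate region id {region.id!r}")
            self.regions[region.id] = region
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(self.regions)
        for parent, child in edges:
            for endpoint in (parent, child):
                if endpoint not in self.regions:
                    raise OntologyError(f"edge ({parent!r}, {child!r}) references unknown region {endpoint!r}")
            self.graph.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise CycleError(f"ontology contains a cycle through edge {cycle[0][:2]}")

    def __len__(self) -> int:
        return len(self.regions)

    def __contains__(self, region_id: str) -> bool:
        return region_id in self.regions

    def __iter__(self):
        return iter(self.regions)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    def _check(self, region_id: str) -> None:
        if region_id not in self.regions:
            raise KeyError(f"unknown region {region_id!r}")

    def children(self, region_id: str) -> set[str]:
        self._check(region_id)
        return set(self.graph.successors(region_id))

    def descendants(self, region_id: str) -> set[str]:
        """Transitive closure of children, excluding the region itself."""
        self._check(region_id)
        return set(nx.descendants(self.graph, region_id))

    def ancestors(self, region_id: str) -> set[str]:
        """Transitive closure of parents, excluding the region itself."""
        self._check(region_id)
        return set(nx.ancestors(self.graph, region_id))

    def leaves(self) -> list[str]:
        return sorted(n for n in self.graph if self.graph.out_degree(n) == 0)

    def propagate(self, mention_probs: Sequence[tuple[str, float]]) -> RegionProbabilityMap:
        """Combine mention probabilities into one probability per region.

        Every mention of region r contributes to r and to every ancestor of
        r; a region's probability is 1 - prod(1 - p_i) over its contributing
        mentions, and 0 when nothing contributes.
        """
        for rid, p in mention_probs:
            self._check(rid)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"mention probability for {rid!r} out of range: {p}")
        log_complement = {rid: 0.0 for rid in self.regions}
        exact_one = {rid: False for rid in self.regions}
        for rid, p in mention_probs:
            targets = {rid} | self.ancestors(rid)
            for t in targets:
                if p >= 1.0:
                    exact_one[t] = True
                else:
                    log_complement[t] += np.log1p(-p) if p > 0 else 0.0
        probs = {}
        for rid in self.regions:
            if exact_one[rid]:
                probs[rid] = 1.0
            else:
                probs[rid] = float(-np.expm1(log_complement[rid])) + 0.0  # -0.0 -> 0.0
        return RegionProbabilityMap(probs)


def _parse_region(entry: Mapping) -> AnatomicalRegion:
    if "id" not in entry:
        raise OntologyError(f"region entry missing 'id': {entry!r}")
    rid = str(entry["id"])
    name = str(entry.get("name", rid))
    patterns = entry.get("patterns")
    if patterns is None:
        patterns = [re.escape(name)]
    return AnatomicalRegion(id=rid, display_name=name, patterns=tuple(str(p) for p in patterns))


def load_ontology(path: str | Path) -> RegionOntology:
    """Load and validate an ontology config (YAML or JSON).

    Expected structure::

        regions:
          - {id: lungs, name: lungs, patterns: ["lungs?"]}
        edges:
          - [chest, lungs]
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "regions" not in doc:
        raise OntologyError(f"{path}: expected a mapping with a 'regions' key")
    regions = [_parse_region(entry) for entry in doc["regions"]]
    edges = [(str(a), str(b)) for a, b in doc.get("edges", [])]
    return RegionOntology(regions, edges)


_TOKEN_RE = re.compile(r"[a-z0-9]+")


def build_ontology_candidates(
    corpus: Iterable[str], k_max: int = 3, min_count: int = 35
) -> list[tuple[str, int]]:
    """Mine frequent k-grams (k = 1..k_max) as candidate region names.

    Tokens are lowercased alphanumeric runs; k-grams never cross document
    boundaries. Returns (k-gram, count) with count >= min_count, sorted by
    count descending then lexicographically. Curation of which candidates
    are anatomical is up to the caller.
    """
    counts: dict[str, int] = {}
    for text in corpus:
        tokens = _TOKEN_RE.findall(text.lower())
        for k in range(1, k_max + 1):
            for i in range(len(tokens) - k + 1):
                gram = " ".join(tokens[i : i + k])
                counts[gram] = counts.get(gram, 0) + 1
    survivors = [(g, c) for g, c in counts.items() if c >= min_count]
    survivors.sort(key=lambda gc: (-gc[1], gc[0]))
    return survivors
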