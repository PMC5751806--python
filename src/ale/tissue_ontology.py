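"""Tissue label extraction against an OBO ontology, plus DAG metrics.

The tissue vocabulary is an ontology in OBO flat-file format (the BRENDA
Tissue Ontology in production; a toy DAG in tests).  Term names and synonyms
form a match dictionary scanned over the metadata text with the Aho-Corasick
algorithm.  When several terms match in the same field, the SHALLOWEST term
(closest to a root, i.e. most general) is chosen: ontologies carry many
short, ambiguous synonyms ("bud", "cap") deeper down, so preferring general
terms trades informativeness for precision.

Depth is the shortest is_a path from a term up to any root (root depth 0).
For evaluating predictions, :func:`ontology_distance` measures shortest path
length over the is_a graph with edges treated as undirected, and
:func:`random_distance_baseline` gives the null distribution of distances
between uniformly drawn term pairs.
"""

from __future__ import annotations

import io
import logging
import re
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import obonet

from ._aho import AhoCorasick
from .errors import OntologyError
from .metadata_model import (
    DEFAULT_FIELD_ORDER,
    FieldOrder,
    LabelRecord,
    SampleMetadata,
    field_units,
)

logger = logging.getLogger(__name__)

TISSUE_KEY_RE = re.compile(r"(?:tissue|organ|cell\s*type|source)", re.IGNORECASE)

_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"\s*([A-Z]+)?')


@dataclass(frozen=True)
class Synonym:
    text: str
    scope: str = "RELATED"  # EXACT | RELATED | NARROW | BROAD


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    synonyms: tuple[Synonym, ...] = ()
    parents: tuple[str, ...] = ()
    obsolete: bool = False

    def surface_forms(self) -> list[str]:
        return [self.name] + [s.text for s in self.synonyms]


class OntologyGraph:
    """A DAG of ontology terms with depth and distance queries."""

    def __init__(self, terms: Iterable[Term]):
        self.terms: dict[str, Term] = {}
        for term in terms:
            self.terms[term.term_id] = term
        # drop dangling parent links so every recorded parent exists
        cleaned = {}
        for tid, term in self.terms.items():
            parents = tuple(p for p in term.parents if p in self.terms)
            if len(parents) != len(term.parents):
                missing = set(term.parents) - set(parents)
                logger.warning("term %s: dropping unknown parents %s", tid, sorted(missing))
                term = Term(term.term_id, term.name, term.synonyms, parents, term.obsolete)
            cleaned[tid] = term
        self.terms = cleaned
        if not self.terms:
            raise OntologyError("empty ontology")
        self._graph = nx.DiGraph()  # edges child -> parent
        self._graph.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.parents:
                self._graph.add_edge(term.term_id, parent)
        if not nx.is_directed_acyclic_graph(self._graph):
            cycle = nx.find_cycle(self._graph)
            raise OntologyError(f"is_a graph contains a cycle: {cycle}")
        self.roots: frozenset[str] = frozenset(
            tid for tid, term in self.terms.items() if not term.parents
        )
        self._depths = self._compute_depths()

    def _compute_depths(self) -> dict[str, int]:
        """Multi-source BFS from the roots along parent->child edges; gives
        the shortest upward path length to any root for every term."""
        depths: dict[str, int] = {r: 0 for r in self.roots}
        children = self._graph.reverse(copy=False)
        queue = deque(self.roots)
        while queue:
            node = queue.popleft()
            for child in children.successors(node):
                if child not in depths:
                    depths[child] = depths[node] + 1
                    queue.append(child)
        return depths

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def _require(self, term_id: str) -> Term:
        try:
            return self.terms[term_id]
        except KeyError:
            raise OntologyError(f"unknown term id {term_id!r}") from None

    def depth(self, term_id: str) -> int:
        """Shortest directed path from *term_id* up to any root; root = 0."""
        self._require(term_id)
        return self._depths[term_id]

    def distance(self, a: str, b: str) -> float:
        """Shortest path length between two terms, is_a edges undirected.

        ``d(a, a) == 0``; terms in different connected components get
        ``math.inf``.
        """
        self._require(a)
        self._require(b)
        if a == b:
            return 0
        # BFS on the undirected view
        seen = {a: 0}
        queue = deque([a])
        und = self._graph
        while queue:
            node = queue.popleft()
            for nbr in set(und.successors(node)) | set(und.predecessors(node)):
                if nbr not in seen:
                    seen[nbr] = seen[node] + 1
                    if nbr == b:
                        return seen[nbr]
                    queue.append(nbr)
        return float("inf")


def term_depth(graph: OntologyGraph, term_id: str) -> int:
    return graph.depth(term_id)


def ontology_distance(graph: OntologyGraph, a: str, b: str) -> float:
    return graph.distance(a, b)


def random_distance_baseline(
    graph: OntologyGraph, n: int, seed: int = 0
) -> list[float]:
    """Distances between *n* uniformly sampled term pairs (with replacement)."""
    if len(graph) == 0:
        raise OntologyError("empty ontology")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ids = sorted(graph.terms)
    idx = rng.integers(0, len(ids), size=(n, 2))
    return [graph.distance(ids[i], ids[j]) for i, j in idx]


# ---------------------------------------------------------------------------
# OBO loading (obonet does the flat-file parsing)

def load_obo(source: str | Path | io.TextIOBase) -> OntologyGraph:
    """Load an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    All synonym scopes are kept (scope recorded); obsolete terms are loaded
    but flagged, and excluded from matching.  Stanzas without a name are
    skipped with a warning.  A cyclic is_a graph is a fatal error.
    """
    try:
        if isinstance(source, (str, Path)):
            graph = obonet.read_obo(str(source), ignore_obsolete=False)
        else:
            graph = obonet.read_obo(source, ignore_obsolete=False)
    except Exception as exc:  # obonet raises assorted ValueError subclasses
        raise OntologyError(f"cannot parse OBO: {exc}") from exc
    terms: list[Term] = []
    for term_id, data in graph.nodes(data=True):
        name = data.get("name")
        if not name:
            logger.warning("OBO stanza %s has no name; skipped", term_id)
            continue
        synonyms = []
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.match(raw)
            if m:
                synonyms.append(Synonym(m.group(1), m.group(2) or "RELATED"))
        parents = tuple(
            v for _, v, key in graph.out_edges(term_id, keys=True) if key == "is_a"
        )
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        terms.append(Term(term_id, name, tuple(synonyms), parents, obsolete))
    return OntologyGraph(terms)


# ---------------------------------------------------------------------------
# dictionary matching

@dataclass(frozen=True)
class MatcherConfig:
    case_insensitive: bool = True
    #: only count matches delimited by non-alphanumerics ("cap" must not
    #: fire inside "capsule"); raw substring mode is available but off
    require_token_boundaries: bool = True
    min_pattern_length: int = 3
    stoplist: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.min_pattern_length < 1:
            raise ValueError("min_pattern_length must be >= 1")


DEFAULT_MATCHER_CONFIG = MatcherConfig()


@dataclass(frozen=True)
class TissueLabel:
    term_id: str
    term_name: str
    matched_text: str
    matched_field: str = ""
    depth: int = 0
    source: str = "text"
    confidence: float = 1.0

    def to_record(self, sample_id: str) -> LabelRecord:
        return LabelRecord(
            sample_id, "tissue", self.term_id, "", self.source,
            self.confidence, self.matched_field, self.matched_text,
        )


class TissueMatcher:
    """Aho-Corasick automaton over every usable ontology surface form.

    A surface form shared by several terms maps to all of them; ambiguity is
    resolved at selection time (shallowest term wins).
    """

    def __init__(self, graph: OntologyGraph, cfg: MatcherConfig = DEFAULT_MATCHER_CONFIG):
        self.graph = graph
        self.cfg = cfg
        stop = {s.lower() if cfg.case_insensitive else s for s in cfg.stoplist}
        self.pattern_terms: dict[str, set[str]] = {}
        for term in graph.terms.values():
            if term.obsolete:
                continue
            for surface in term.surface_forms():
                pat = surface.lower() if cfg.case_insensitive else surface
                if len(pat) < cfg.min_pattern_length or pat in stop:
                    continue
                self.pattern_terms.setdefault(pat, set()).add(term.term_id)
        self._automaton = AhoCorasick(self.pattern_terms)

    def find_hits(self, text: str) -> list[tuple[int, int, str, set[str]]]:
        """All dictionary occurrences in *text* as (start, end, surface, term ids)."""
        haystack = text.lower() if self.cfg.case_insensitive else text
        hits = []
        for start, end, pat in self._automaton.finditer(haystack):
            if self.cfg.require_token_boundaries:
                if start > 0 and haystack[start - 1].isalnum():
                    continue
                if end < len(haystack) and haystack[end].isalnum():
                    continue
            hits.append((start, end, text[start:end], self.pattern_terms[pat]))
        return hits


def build_matcher(
    graph: OntologyGraph, cfg: MatcherConfig = DEFAULT_MATCHER_CONFIG
) -> TissueMatcher:
    return TissueMatcher(graph, cfg)


def match_tissue(
    meta: SampleMetadata,
    matcher: TissueMatcher,
    order: FieldOrder = DEFAULT_FIELD_ORDER,
) -> TissueLabel | None:
    """Match ontology terms in the metadata and select one tissue label.

    Fields are searched in *order* (tissue/organ/cell-type/source keyed
    characteristics pairs first).  Among all hits in the first field class
    that yields any, the term with minimal depth wins; ties go to the longer
    matched surface string, then the lexicographically smallest term id.
    """
    graph = matcher.graph
    for field_class in order.fields:
        candidates: list[tuple[int, int, str, str, str]] = []
        # (depth, -surface_len, term_id, surface, field_label)
        for flabel, key, text in field_units(meta, field_class, TISSUE_KEY_RE.pattern):
            for _, _, surface, term_ids in matcher.find_hits(text):
                for tid in term_ids:
                    candidates.append(
                        (graph.depth(tid), -len(surface), tid, surface, flabel)
                    )
        if candidates:
            depth, _, tid, surface, flabel = min(candidates)
            return TissueLabel(
                term_id=tid,
                term_name=graph.terms[tid].name,
                matched_text=surface,
                matched_field=flabel,
                depth=depth,
            )
    return None
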