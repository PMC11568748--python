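"""Ontology parsing, DAG queries, information content, and Lin similarity.

A phenotype ontology (such as the Human Phenotype Ontology) is a directed
acyclic graph of terms linked by is-a (subclass) edges.  Semantic similarity
between two terms is computed from the information content (IC) of their
most informative common ancestor (MICA) using Lin's measure::

    sim(t1, t2) = 2 * IC(MICA) / (IC(t1) + IC(t2))

IC here is structure-based: a term annotating a large subtree is generic
(low IC), a leaf is maximally specific.  Only is-a edges define ancestry;
other relationship types are ignored.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "TermRecord",
    "OntologyGraph",
    "ICTable",
    "OboParseError",
    "parse_obo",
    "resolve_term",
    "ancestor_set",
    "compute_descendants_ic",
    "lin_term_similarity",
]


class OboParseError(ValueError):
    """Raised when an OBO document violates the structural contract."""


@dataclass(frozen=True)
class TermRecord:
    """One ontology term.

    ``parent_ids`` holds is-a parents only and is empty for obsolete terms:
    obsolete terms never participate in traversal.  ``replaced_by`` and
    ``consider`` are replacement hints carried by obsolete terms.
    """

    term_id: str
    name: str = ""
    parent_ids: frozenset[str] = frozenset()
    is_obsolete: bool = False
    replaced_by: str | None = None
    consider: tuple[str, ...] = ()


class OntologyGraph:
    """A validated is-a DAG of :class:`TermRecord` objects.

    Acyclicity is checked at construction.  Ancestor closures are cached per
    term, so repeated similarity queries are cheap.
    """

    def __init__(self, terms: Mapping[str, TermRecord]):
        self.terms: dict[str, TermRecord] = dict(terms)
        self._validate()
        self._ancestors: dict[str, frozenset[str]] = {}

    # -- construction -----------------------------------------------------

    def _validate(self) -> None:
        known = set(self.terms)
        missing = sorted(
            {p for t in self.terms.values() for p in t.parent_ids} - known
        )
        if missing:
            raise OboParseError(
                f"is_a targets absent from the ontology: {', '.join(missing)}"
            )
        dg = nx.DiGraph()
        dg.add_nodes_from(known)
        for t in self.terms.values():
            for p in t.parent_ids:
                dg.add_edge(t.term_id, p)
        if not nx.is_directed_acyclic_graph(dg):
            child, parent, *_ = nx.find_cycle(dg)[0]
            raise OboParseError(
                f"cyclic is_a relation involving edge {child} -> {parent}"
            )

    # -- queries ----------------------------------------------------------

    @property
    def root_ids(self) -> frozenset[str]:
        """Non-obsolete terms with no parents."""
        return frozenset(
            t.term_id
            for t in self.terms.values()
            if not t.is_obsolete and not t.parent_ids
        )

    def live_ids(self) -> frozenset[str]:
        return frozenset(
            t.term_id for t in self.terms.values() if not t.is_obsolete
        )

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Reflexive transitive closure over is-a edges (includes the term)."""
        cached = self._ancestors.get(term_id)
        if cached is not None:
            return cached
        rec = self.terms.get(term_id)
        if rec is None:
            raise KeyError(f"unknown term: {term_id}")
        if rec.is_obsolete:
            raise ValueError(f"obsolete term has no ancestry: {term_id}")
        closure: set[str] = {term_id}
        for p in rec.parent_ids:
            closure |= self.ancestors(p)
        result = frozenset(closure)
        self._ancestors[term_id] = result
        return result


@dataclass(frozen=True)
class ICTable:
    """Per-term information content in nats.

    Invariants: ``ic`` is 0 at every root, finite, and non-decreasing along
    any root-to-leaf path.
    """

    ic: dict[str, float]
    total_terms: int

    def __getitem__(self, term_id: str) -> float:
        return self.ic[term_id]


# ---------------------------------------------------------------------------
# OBO parsing


_ID_RE = re.compile(r"^id:\s*(\S+)")


def _scan_stanza_ids(text: str) -> list[str]:
    """Collect the id of every [Term] stanza, in file order.

    obonet silently merges duplicate stanzas and materialises referenced but
    undefined is_a targets as empty nodes; this pre-scan restores the strict
    contract (duplicate id -> error, dangling target -> error).
    """
    ids: list[str] = []
    in_term = False
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("["):
            in_term = line == "[Term]"
        elif in_term:
            m = _ID_RE.match(line)
            if m:
                ids.append(m.group(1))
                in_term = False  # only the first id: tag of a stanza counts
    return ids


def _strip_comment(value: str) -> str:
    return value.split("!", 1)[0].strip()


def parse_obo(source: str | Path | IO[str]) -> OntologyGraph:
    """Parse OBO-format text into an :class:`OntologyGraph`.

    ``source`` may be OBO text, a path, or an open text stream.  Only
    ``[Term]`` stanzas and the tags id / name / is_a / is_obsolete /
    replaced_by / consider are interpreted; everything else is ignored.
    Trailing ``! comment`` annotations are stripped from identifiers.

    Raises :class:`OboParseError` on duplicate term ids, is_a targets that
    have no stanza of their own, or a cyclic is_a relation.
    """
    if isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
    elif isinstance(source, str):
        if "\n" not in source and Path(source).is_file():
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = source
    else:
        text = source.read()

    stanza_ids = _scan_stanza_ids(text)
    seen: set[str] = set()
    dupes = sorted({i for i in stanza_ids if i in seen or seen.add(i)})
    if dupes:
        raise OboParseError(f"duplicate term ids: {', '.join(dupes)}")

    # obonet logs header chatter to the root logger; keep parsing quiet
    root_logger = logging.getLogger()
    previous_level = root_logger.level
    root_logger.setLevel(logging.ERROR)
    try:
        graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    finally:
        root_logger.setLevel(previous_level)

    terms: dict[str, TermRecord] = {}
    for term_id in stanza_ids:
        data = graph.nodes.get(term_id, {})
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        if obsolete:
            parents: frozenset[str] = frozenset()
        else:
            parents = frozenset(
                _strip_comment(p) for p in data.get("is_a", [])
            )
        replaced = data.get("replaced_by") or None
        terms[term_id] = TermRecord(
            term_id=term_id,
            name=data.get("name", ""),
            parent_ids=parents,
            is_obsolete=obsolete,
            replaced_by=_strip_comment(replaced[0]) if replaced else None,
            consider=tuple(
                _strip_comment(c) for c in data.get("consider", [])
            ),
        )
    return OntologyGraph(terms)


# ---------------------------------------------------------------------------
# term resolution


def resolve_term(graph: OntologyGraph, term_id: str) -> str | None:
    """Map a possibly obsolete identifier to its live replacement.

    Non-obsolete known ids resolve to themselves.  Obsolete ids follow
    ``replaced_by`` (preferred) or the first ``consider`` entry, recursively.
    Unknown ids and obsolete ids with no usable replacement resolve to
    ``None`` (the caller drops the code); a replacement cycle is a hard
    error.
    """
    seen: set[str] = set()
    current: str | None = term_id
    while current is not None:
        if current in seen:
            raise OboParseError(
                f"replacement cycle while resolving {term_id}"
            )
        seen.add(current)
        rec = graph.terms.get(current)
        if rec is None:
            logger.warning("dropping unknown term id %s", current)
            return None
        if not rec.is_obsolete:
            return current
        nxt = rec.replaced_by or (rec.consider[0] if rec.consider else None)
        if nxt is None:
            logger.warning(
                "dropping obsolete term %s with no replacement", current
            )
            return None
        current = nxt
    return None


def ancestor_set(graph: OntologyGraph, term_id: str) -> frozenset[str]:
    """Reflexive ancestor closure of a live term (thin wrapper)."""
    return graph.ancestors(term_id)


# ---------------------------------------------------------------------------
# information content and Lin similarity


def compute_descendants_ic(graph: OntologyGraph) -> ICTable:
    """Structure-based IC: ``ic(t) = -ln(|descendants(t) incl. t| / N)``.

    N counts non-obsolete terms.  Roots subsume everything below them; a
    single-root ontology therefore has ``ic(root) = 0`` exactly, and leaves
    attain the maximum ``-ln(1/N)``.  Corpus-free, hence fully reproducible
    from the ontology file alone.
    """
    import math

    live = graph.live_ids()
    n = len(live)
    if n == 0:
        raise ValueError("ontology has no non-obsolete terms")
    counts = dict.fromkeys(live, 0)
    for term_id in live:
        for anc in graph.ancestors(term_id):
            counts[anc] += 1
    ic = {t: (0.0 if counts[t] == n else -math.log(counts[t] / n)) for t in live}
    return ICTable(ic=ic, total_terms=n)


def lin_term_similarity(
    graph: OntologyGraph, ic: ICTable, t1: str, t2: str
) -> float:
    """Lin similarity ``2*ic(MICA) / (ic(t1)+ic(t2))`` in [0, 1].

    The MICA is the common is-a ancestor with maximal IC; ties are harmless
    because only the IC value enters the score.  Terms with no common
    ancestor (disconnected components) score 0, as does the degenerate
    root-vs-root case where both ICs are 0.
    """
    common = graph.ancestors(t1) & graph.ancestors(t2)
    if not common:
        return 0.0
    denom = ic[t1] + ic[t2]
    if denom == 0.0:
        return 0.0
    mica_ic = max(ic[a] for a in common)
    return 2.0 * mica_ic / denom
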