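"""Shared fixtures: toy ontologies and independent brute-force oracles.

The oracles deliberately avoid the package's own traversal code: ancestry
and descendant counts come from networkx on an explicitly built edge list,
so agreement is a real cross-check rather than a tautology.
"""

from __future__ import annotations

import math

import networkx as nx
import pytest

from phenoblend import (
    ICTable,
    OntologyGraph,
    TermSet,
    parse_obo,
)

TOY_OBO = """format-version: 1.2

[Term]
id: HP:0000001
name: root

[Term]
id: HP:0000002
name: A
is_a: HP:0000001 ! root

[Term]
id: HP:0000003
name: B
is_a: HP:0000002 ! A

[Term]
id: HP:0000004
name: C
is_a: HP:0000002 ! A
"""

DIAMOND_OBO = """format-version: 1.2

[Term]
id: T:0
name: root

[Term]
id: T:A
is_a: T:0

[Term]
id: T:B
is_a: T:A

[Term]
id: T:C
is_a: T:A

[Term]
id: T:D
is_a: T:B
is_a: T:C
"""

TWO_COMPONENT_OBO = """format-version: 1.2

[Term]
id: X:1
name: root one

[Term]
id: X:2
is_a: X:1

[Term]
id: Y:1
name: root two

[Term]
id: Y:2
is_a: Y:1
"""


@pytest.fixture(scope="session")
def toy_graph() -> OntologyGraph:
    return parse_obo(TOY_OBO)


@pytest.fixture(scope="session")
def diamond_graph() -> OntologyGraph:
    return parse_obo(DIAMOND_OBO)


@pytest.fixture(scope="session")
def two_component_graph() -> OntologyGraph:
    return parse_obo(TWO_COMPONENT_OBO)


# ---------------------------------------------------------------------------
# independent oracles


def nx_parent_digraph(graph: OntologyGraph) -> nx.DiGraph:
    """child -> parent edge digraph over live terms, built from records."""
    dg = nx.DiGraph()
    for rec in graph.terms.values():
        if rec.is_obsolete:
            continue
        dg.add_node(rec.term_id)
        for p in rec.parent_ids:
            dg.add_edge(rec.term_id, p)
    return dg


def oracle_ancestors(graph: OntologyGraph, term_id: str) -> set[str]:
    dg = nx_parent_digraph(graph)
    return {term_id} | nx.descendants(dg, term_id)


def oracle_descendant_ic(graph: OntologyGraph) -> ICTable:
    """IC table from networkx descendant counts (reversed edge direction)."""
    dg = nx_parent_digraph(graph).reverse()
    n = dg.number_of_nodes()
    ic = {}
    for t in dg.nodes:
        count = 1 + len(nx.descendants(dg, t))
        ic[t] = -math.log(count / n)
    return ICTable(ic=ic, total_terms=n)


def oracle_lin(graph: OntologyGraph, ic: ICTable, t1: str, t2: str) -> float:
    """O(|anc1| * |anc2|) MICA scan without set intersection."""
    anc1 = oracle_ancestors(graph, t1)
    anc2 = oracle_ancestors(graph, t2)
    best = None
    for a in anc1:
        for b in anc2:
            if a == b and (best is None or ic[a] > best):
                best = ic[a]
    if best is None:
        return 0.0
    denom = ic[t1] + ic[t2]
    return 0.0 if denom == 0 else 2 * best / denom


def oracle_bma(graph: OntologyGraph, ic: ICTable, sa: TermSet, sb: TermSet) -> float:
    fwd = sum(
        max(oracle_lin(graph, ic, a, b) for b in sb.term_ids) for a in sa.term_ids
    ) / len(sa.term_ids)
    bwd = sum(
        max(oracle_lin(graph, ic, a, b) for a in sa.term_ids) for b in sb.term_ids
    ) / len(sb.term_ids)
    return (fwd + bwd) / 2
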