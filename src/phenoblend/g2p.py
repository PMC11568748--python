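"""Curation of gene-to-phenotype tables and antagonistic-pair flagging.

A G2P-style table links gene symbols to diseases with a curation confidence
level and a semicolon-separated list of phenotype term ids.  Curation keeps
only confidently asserted entries, resolves obsolete term ids against the
ontology, pools ("amalgamates") terms per gene across its entries, strips
the mode-of-inheritance subtree, and drops genes left with no terms.

Antagonistic flagging marks gene pairs annotated with clinically opposing
phenotypes (e.g. microcephaly vs macrocephaly) that nonetheless sit close
together in the ontology and therefore score as similar.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from .ontology import OntologyGraph, resolve_term
from .similarity import TermSet

logger = logging.getLogger(__name__)

#: Root of the mode-of-inheritance subtree in the HPO; terms below it
#: describe how a condition is inherited, not what the phenotype is.
MOI_ROOT = "HP:0000005"

#: Confidence categories retained by default (matched case-insensitively).
DEFAULT_CONFIDENCE = frozenset({"strong", "definitive"})

__all__ = [
    "G2PEntry",
    "GeneAnnotationSet",
    "OpposingPairRegistry",
    "read_g2p_csv",
    "read_opposing_registry",
    "curate_annotations",
    "flag_antagonistic_pairs",
    "shared_term_pairs",
    "MOI_ROOT",
    "DEFAULT_CONFIDENCE",
]


@dataclass(frozen=True)
class G2PEntry:
    gene_symbol: str
    disease_name: str
    confidence: str
    hpo_ids: tuple[str, ...] = ()
    allelic_requirement: str = ""

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")


@dataclass
class GeneAnnotationSet:
    """Curated gene -> TermSet map plus drop-reason provenance counters."""

    term_sets: dict[str, TermSet]
    provenance: Counter = field(default_factory=Counter)

    def __getitem__(self, gene: str) -> TermSet:
        return self.term_sets[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.term_sets

    def __len__(self) -> int:
        return len(self.term_sets)

    def genes(self) -> list[str]:
        return sorted(self.term_sets)

    def as_list(self) -> list[TermSet]:
        return [self.term_sets[g] for g in self.genes()]


class OpposingPairRegistry:
    """Unordered pairs of term ids declared clinically antagonistic."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        cleaned = set()
        for a, b in pairs:
            if a == b:
                raise ValueError(f"self-opposing term: {a}")
            cleaned.add((a, b) if a < b else (b, a))
        self.pairs: frozenset[tuple[str, str]] = frozenset(cleaned)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(sorted(self.pairs))

    def resolved(self, graph: OntologyGraph) -> "OpposingPairRegistry":
        """Resolve both members of every pair; drop unresolvable pairs."""
        out = []
        for a, b in self.pairs:
            ra, rb = resolve_term(graph, a), resolve_term(graph, b)
            if ra is None or rb is None or ra == rb:
                logger.warning("dropping unresolvable opposing pair %s/%s", a, b)
                continue
            out.append((ra, rb))
        return OpposingPairRegistry(out)


# ---------------------------------------------------------------------------
# input formats


def read_g2p_csv(source: str | Path | IO[str]) -> list[G2PEntry]:
    """Read a G2P CSV: gene symbol, disease name, confidence, allelic
    requirement, phenotypes (semicolon-separated term ids).

    Column matching is by header name prefix so dialect variants ("gene
    symbol" / "gene_symbol") both work; quoting follows RFC 4180 via the
    stdlib csv module.
    """
    if hasattr(source, "read"):
        handle = source
        rows = list(csv.reader(handle))
    else:
        with open(source, newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
    if not rows:
        raise ValueError("empty G2P table")
    header = [h.strip().lower().replace("_", " ") for h in rows[0]]

    def col(prefix: str) -> int | None:
        for i, h in enumerate(header):
            if h.startswith(prefix):
                return i
        return None

    i_gene = col("gene symbol")
    i_dis = col("disease name")
    i_conf = col("confidence")
    i_allelic = col("allelic requirement")
    i_pheno = col("phenotype")
    if i_gene is None or i_conf is None or i_pheno is None:
        raise ValueError("G2P header missing gene/confidence/phenotype columns")

    entries = []
    for row in rows[1:]:
        if not row or not row[i_gene].strip():
            continue
        phenos = tuple(
            p.strip() for p in row[i_pheno].split(";") if p.strip()
        )
        entries.append(
            G2PEntry(
                gene_symbol=row[i_gene].strip(),
                disease_name=row[i_dis].strip() if i_dis is not None else "",
                confidence=row[i_conf].strip(),
                hpo_ids=phenos,
                allelic_requirement=(
                    row[i_allelic].strip() if i_allelic is not None else ""
                ),
            )
        )
    return entries


def read_opposing_registry(source: str | Path | IO[str]) -> OpposingPairRegistry:
    """Read a 2-column TSV of opposing term ids; ``#`` starts a comment."""
    text = source.read() if hasattr(source, "read") else Path(source).read_text()
    pairs = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"expected two tab-separated ids: {raw!r}")
        pairs.append((parts[0].strip(), parts[1].strip()))
    return OpposingPairRegistry(pairs)


# ---------------------------------------------------------------------------
# curation


def curate_annotations(
    entries: Sequence[G2PEntry],
    graph: OntologyGraph,
    confidence: Iterable[str] = DEFAULT_CONFIDENCE,
    moi_root: str = MOI_ROOT,
) -> GeneAnnotationSet:
    """Filter, resolve, amalgamate and MOI-strip a G2P table.

    Pipeline per entry: keep only the requested confidence categories; per
    gene: resolve every term id (dropping unresolvable ones), union terms
    across the gene's entries, remove terms under the mode-of-inheritance
    root, and finally drop genes whose sets come out empty.  Nothing fails:
    each drop is tallied in ``provenance``.
    """
    keep_conf = {c.strip().lower() for c in confidence}
    prov: Counter = Counter()
    pooled: dict[str, set[str]] = {}

    for entry in entries:
        prov["entries_in"] += 1
        if entry.confidence.strip().lower() not in keep_conf:
            prov["entries_dropped_confidence"] += 1
            continue
        prov["entries_retained"] += 1
        pooled.setdefault(entry.gene_symbol, set()).update(entry.hpo_ids)

    term_sets: dict[str, TermSet] = {}
    for gene in sorted(pooled):
        raw_ids = pooled[gene]
        resolved: set[str] = set()
        for tid in raw_ids:
            live = resolve_term(graph, tid)
            if live is None:
                prov["terms_dropped_unresolvable"] += 1
            else:
                if live != tid:
                    prov["terms_remapped_obsolete"] += 1
                resolved.add(live)
        moi = {
            t for t in resolved if moi_root in graph.ancestors(t)
        }
        prov["terms_dropped_moi"] += len(moi)
        final = resolved - moi
        prov["terms_kept"] += len(final)
        if final:
            term_sets[gene] = TermSet(owner_id=gene, term_ids=frozenset(final))
        else:
            prov["genes_dropped_empty"] += 1
    prov["genes_kept"] = len(term_sets)
    return GeneAnnotationSet(term_sets=term_sets, provenance=prov)


# ---------------------------------------------------------------------------
# pair flagging


def flag_antagonistic_pairs(
    annotations: GeneAnnotationSet, registry: OpposingPairRegistry
) -> set[tuple[str, str]]:
    """Gene pairs linked with both members of an opposing term pair.

    Pair (G1, G2) is flagged iff some registry pair (X, Y) has X annotated
    to one gene and Y to the other.  Matching is on exact term membership —
    no ancestor propagation — so only genes literally annotated with the
    opposing phenotypes are flagged.
    """
    flagged: set[tuple[str, str]] = set()
    genes = annotations.genes()
    by_term: dict[str, set[str]] = {}
    for g in genes:
        for t in annotations[g].term_ids:
            by_term.setdefault(t, set()).add(g)
    for x, y in registry:
        for g1 in by_term.get(x, ()):
            for g2 in by_term.get(y, ()):
                if g1 != g2:
                    flagged.add((g1, g2) if g1 < g2 else (g2, g1))
    return flagged


def shared_term_pairs(
    annotations: GeneAnnotationSet, k: int = 1
) -> set[tuple[str, str]]:
    """Gene pairs sharing at least ``k`` identical terms (synergy candidates)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    genes = annotations.genes()
    out: set[tuple[str, str]] = set()
    for i, g1 in enumerate(genes):
        t1 = annotations[g1].term_ids
        for g2 in genes[i + 1 :]:
            if len(t1 & annotations[g2].term_ids) >= k:
                out.add((g1, g2))
    return out
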