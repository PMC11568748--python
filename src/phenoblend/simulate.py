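"""Synthetic ontologies, gene annotation sets, and dual-diagnosis cohorts.

The generator mirrors the statistical shape of the real analysis inputs so
every pipeline stage can be exercised without downloading anything:

* a rooted multi-level is-a DAG with occasional double parents (diamonds),
  standing in for a phenotype ontology;
* genes organised into families that share a core of identical terms
  (producing the characteristic two-population, high-vs-low structure of
  all-pairs similarity grids) with heavy-tailed per-gene term counts
  (default mean 22, range 1-242);
* probands whose term sets are mixtures of their two diagnostic genes'
  annotations (mixing weight ``w``), plus background noise terms, with the
  generating one/both/neither attribution of every term recorded as ground
  truth (default 1-21 terms per proband).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Sequence

import numpy as np

from .cohort import ProbandRecord
from .g2p import GeneAnnotationSet, OpposingPairRegistry
from .ontology import OntologyGraph, TermRecord, compute_descendants_ic
from .similarity import LinScorer, TermSet

__all__ = [
    "SyntheticConfig",
    "generate_ontology",
    "generate_gene_annotations",
    "generate_annotations_with_opposing",
    "generate_cohort",
    "write_obo",
    "write_g2p_csv",
    "write_cohort_tsv",
]

#: probability that a non-root term gets a second parent (creates diamonds)
SECOND_PARENT_PROB = 0.2


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study; defaults match the emulated cohort."""

    seed: int = 0
    # ontology shape
    n_terms: int = 250
    depth: int = 6
    branching: float = 2.0
    # annotation structure
    n_genes: int = 40
    n_families: int = 4
    core_fraction: float = 0.6
    terms_per_gene_mean: float = 22.0
    terms_per_gene_range: tuple[int, int] = (1, 242)
    # cohort structure
    cohort_size: int = 62
    proband_terms_range: tuple[int, int] = (1, 21)
    mixing_weight: float = 0.5
    noise_rate: float = 0.05
    opposing_injection: bool = False

    def __post_init__(self) -> None:
        for name in ("n_terms", "depth", "n_genes", "n_families", "cohort_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("core_fraction", "mixing_weight", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.n_terms < self.depth:
            raise ValueError("n_terms must be >= depth")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _term_id(i: int) -> str:
    return f"SP:{i:07d}"


# ---------------------------------------------------------------------------
# ontology


def generate_ontology(config: SyntheticConfig) -> OntologyGraph:
    """Build a rooted DAG level by level.

    Level sizes grow geometrically with ``branching`` and are rescaled to
    total ``n_terms``.  Each new term takes one uniform parent from the
    previous level and, with fixed probability, a second distinct one,
    which creates the diamond motifs real ontologies are full of.
    """
    rng = config.rng()
    if config.depth == 1:
        return OntologyGraph(
            {_term_id(0): TermRecord(term_id=_term_id(0), name="root")}
        )
    weights = np.array(
        [config.branching**lvl for lvl in range(1, config.depth)]
    )
    remaining = config.n_terms - 1
    sizes = np.maximum(1, np.floor(remaining * weights / weights.sum())).astype(int)
    # distribute the rounding remainder over the deepest levels
    i = len(sizes) - 1
    while sizes.sum() < remaining:
        sizes[i] += 1
        i = (i - 1) % len(sizes)
    while sizes.sum() > remaining:
        j = int(np.argmax(sizes))
        sizes[j] -= 1

    terms: dict[str, TermRecord] = {
        _term_id(0): TermRecord(term_id=_term_id(0), name="root")
    }
    prev_level = [_term_id(0)]
    counter = 1
    for lvl, size in enumerate(sizes, start=1):
        level_ids = []
        for _ in range(size):
            tid = _term_id(counter)
            counter += 1
            parents = {prev_level[rng.integers(len(prev_level))]}
            if len(prev_level) > 1 and rng.random() < SECOND_PARENT_PROB:
                extra = prev_level[rng.integers(len(prev_level))]
                parents.add(extra)
            terms[tid] = TermRecord(
                term_id=tid,
                name=f"synthetic term {tid} (level {lvl})",
                parent_ids=frozenset(parents),
            )
            level_ids.append(tid)
        prev_level = level_ids
    return OntologyGraph(terms)


# ---------------------------------------------------------------------------
# gene annotations


def _draw_gene_size(
    rng: np.random.Generator, mean: float, lo: int, hi: int, cap: int
) -> int:
    """Right-skewed (log-normal) integer size, truncated to [lo, min(hi, cap)].

    sigma = 1 gives the heavy right tail; mu is mean-matched so that the
    untruncated expectation equals ``mean``.
    """
    sigma = 1.0
    mu = np.log(mean) - sigma**2 / 2.0
    hi = min(hi, cap)
    for _ in range(100):
        size = int(np.round(rng.lognormal(mu, sigma)))
        if lo <= size <= hi:
            return size
    return int(np.clip(size, lo, hi))


def generate_gene_annotations(
    config: SyntheticConfig, graph: OntologyGraph
) -> GeneAnnotationSet:
    annotations, _, _ = generate_annotations_with_opposing(config, graph)
    return annotations


def generate_annotations_with_opposing(
    config: SyntheticConfig, graph: OntologyGraph
) -> tuple[GeneAnnotationSet, OpposingPairRegistry, set[tuple[str, str]]]:
    """Family-structured gene annotations, optionally with opposing terms.

    Genes are split evenly into families; each family owns a disjoint pool
    of terms whose prefix is the family *core*: a gene of size ``s`` takes
    its first ``round(core_fraction*s)`` terms from the core sequence (so
    family members share them) and samples the rest privately.  With
    ``opposing_injection`` on, consecutive family pairs get one member each
    of an opposing term pair drawn from otherwise unused terms; the
    registry of injected pairs and the exactly implied antagonistic gene
    pairs are returned alongside.
    """
    rng = np.random.default_rng(config.seed + 1)
    non_root = sorted(graph.live_ids() - graph.root_ids)
    if len(non_root) < config.n_families:
        raise ValueError("ontology too small for the requested family count")

    shuffled = [str(t) for t in rng.permutation(non_root)]
    # hold out terms for opposing injection so they are unique to it
    n_hold = 2 * (config.n_families // 2) if config.opposing_injection else 0
    held_out = shuffled[:n_hold]
    pool_terms = shuffled[n_hold:]
    pools = [list(p) for p in np.array_split(pool_terms, config.n_families)]

    lo, hi = config.terms_per_gene_range
    term_sets: dict[str, TermSet] = {}
    gene_family: dict[str, int] = {}
    for g in range(config.n_genes):
        fam = g % config.n_families
        pool = pools[fam]
        gene = f"GENE{g:04d}"
        size = _draw_gene_size(
            rng, config.terms_per_gene_mean, lo, hi, cap=len(non_root)
        )
        core_size = min(int(round(config.core_fraction * size)), len(pool))
        core = pool[:core_size]
        n_private = size - core_size
        candidates = [t for t in pool[core_size:]]
        if len(candidates) < n_private:
            candidates += [t for t in non_root if t not in pool and t not in held_out]
        private = (
            [str(t) for t in rng.choice(candidates, size=n_private, replace=False)]
            if n_private
            else []
        )
        term_sets[gene] = TermSet(
            owner_id=gene, term_ids=frozenset(core) | frozenset(private)
        )
        gene_family[gene] = fam

    injected_pairs: list[tuple[str, str]] = []
    expected_gene_pairs: set[tuple[str, str]] = set()
    if config.opposing_injection:
        genes_by_family: dict[int, list[str]] = {}
        for gene, fam in gene_family.items():
            genes_by_family.setdefault(fam, []).append(gene)
        for i in range(config.n_families // 2):
            tx, ty = held_out[2 * i], held_out[2 * i + 1]
            fam_a, fam_b = 2 * i, 2 * i + 1
            ga = genes_by_family[fam_a][int(rng.integers(len(genes_by_family[fam_a])))]
            gb = genes_by_family[fam_b][int(rng.integers(len(genes_by_family[fam_b])))]
            term_sets[ga] = TermSet(ga, term_sets[ga].term_ids | {tx})
            term_sets[gb] = TermSet(gb, term_sets[gb].term_ids | {ty})
            injected_pairs.append((tx, ty))
            expected_gene_pairs.add((ga, gb) if ga < gb else (gb, ga))

    annotations = GeneAnnotationSet(term_sets=term_sets)
    annotations.provenance["genes_kept"] = len(term_sets)
    return annotations, OpposingPairRegistry(injected_pairs), expected_gene_pairs


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(
    config: SyntheticConfig,
    graph: OntologyGraph,
    annotations: GeneAnnotationSet,
) -> list[ProbandRecord]:
    """Simulate dual-diagnosis probands with ground-truth attribution.

    Per proband: a random gene pair; a term count uniform in
    ``proband_terms_range``; each term is a background draw with
    probability ``noise_rate`` (truth: neither), otherwise drawn from gene1
    with probability ``w`` and gene2 with ``1-w`` — a drawn term present in
    both gene sets is attributed to both, so shared terms surface in
    proportion to the genes' overlap.  Similarity columns are computed with
    the same scorer the analysis uses.
    """
    genes = annotations.genes()
    if len(genes) < 2:
        raise ValueError("need at least two annotated genes")
    rng = np.random.default_rng(config.seed + 2)
    ic = compute_descendants_ic(graph)
    scorer = LinScorer(graph, ic)
    background_pool = sorted(graph.live_ids() - graph.root_ids)

    records: list[ProbandRecord] = []
    lo, hi = config.proband_terms_range
    w = config.mixing_weight
    for i in range(config.cohort_size):
        g1, g2 = (genes[int(k)] for k in rng.choice(len(genes), 2, replace=False))
        set1, set2 = annotations[g1].term_ids, annotations[g2].term_ids
        if not set1 or not set2:
            raise ValueError("gene with empty term set")
        only1, only2 = sorted(set1), sorted(set2)
        n_target = int(rng.integers(lo, hi + 1))
        chosen: dict[str, str] = {}  # term -> truth label
        attempts = 0
        while len(chosen) < n_target and attempts < 50 * (n_target + 1):
            attempts += 1
            if rng.random() < config.noise_rate:
                t = background_pool[int(rng.integers(len(background_pool)))]
                label = "neither" if t not in set1 and t not in set2 else None
                if label is None:
                    continue
            else:
                src = only1 if rng.random() < w else only2
                t = src[int(rng.integers(len(src)))]
                label = "both" if (t in set1 and t in set2) else (
                    "g1" if t in set1 else "g2"
                )
            if t not in chosen:
                chosen[t] = label
        if not chosen:  # tiny gene sets + unlucky draws: force one term
            t = only1[0]
            chosen[t] = "both" if t in set2 else "g1"
        counts = {"g1": 0, "g2": 0, "both": 0, "neither": 0}
        for label in chosen.values():
            counts[label] += 1
        proband_terms = TermSet(
            owner_id=f"PB{i:05d}", term_ids=frozenset(chosen)
        )
        records.append(
            ProbandRecord(
                decipher_id=f"PB{i:05d}",
                age_years=float(np.round(rng.uniform(0.5, 22.0), 1)),
                sex="female" if rng.random() < 0.5 else "male",
                n_hpo_terms=len(chosen),
                gene1=g1,
                gene2=g2,
                pair_score=scorer.set_sim(annotations[g1], annotations[g2]),
                score_g1=scorer.set_sim(proband_terms, annotations[g1]),
                score_g2=scorer.set_sim(proband_terms, annotations[g2]),
                n_attr_g1=counts["g1"],
                n_attr_g2=counts["g2"],
                n_attr_both=counts["both"],
                n_attr_neither=counts["neither"],
                n_excluded=0,
                proband_terms=proband_terms,
            )
        )
    return records


# ---------------------------------------------------------------------------
# serialisation (every generated artifact round-trips through its reader)


def write_obo(graph: OntologyGraph, dest: str | Path | IO[str]) -> None:
    lines = ["format-version: 1.2", ""]
    for tid in sorted(graph.terms):
        rec = graph.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {rec.term_id}")
        if rec.name:
            lines.append(f"name: {rec.name}")
        for p in sorted(rec.parent_ids):
            lines.append(f"is_a: {p}")
        if rec.is_obsolete:
            lines.append("is_obsolete: true")
            if rec.replaced_by:
                lines.append(f"replaced_by: {rec.replaced_by}")
            for c in rec.consider:
                lines.append(f"consider: {c}")
        lines.append("")
    text = "\n".join(lines)
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text, encoding="utf-8")


def write_g2p_csv(
    annotations: GeneAnnotationSet, dest: str | Path | IO[str]
) -> None:
    import csv as _csv
    import io as _io

    buf = _io.StringIO()
    writer = _csv.writer(buf, lineterminator="\n")
    writer.writerow(
        ["gene symbol", "disease name", "confidence category",
         "allelic requirement", "phenotypes"]
    )
    for gene in annotations.genes():
        writer.writerow(
            [
                gene,
                f"synthetic condition ({gene})",
                "strong",
                "monoallelic",
                ";".join(sorted(annotations[gene].term_ids)),
            ]
        )
    text = buf.getvalue()
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text, encoding="utf-8")


def write_cohort_tsv(
    records: Sequence[ProbandRecord], dest: str | Path | IO[str]
) -> None:
    from .cohort import COHORT_COLUMNS

    lines = ["\t".join(COHORT_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.decipher_id,
                    f"{r.age_years:.1f}",
                    r.sex,
                    str(r.n_hpo_terms),
                    r.gene1,
                    r.gene2,
                    f"{r.pair_score:.3f}",
                    f"{r.score_g1:.3f}",
                    f"{r.score_g2:.3f}",
                    str(r.n_attr_g1),
                    str(r.n_attr_g2),
                    str(r.n_attr_both),
                    str(r.n_attr_neither),
                    str(r.n_excluded),
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text, encoding="utf-8")
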