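"""Set-vs-set semantic similarity and the all-pairs gene similarity grid.

A gene (or a proband) is represented by the set of phenotype terms annotated
to it.  Two term sets are compared with the symmetric best-match-average
(BMA) of Lin term similarities: every term is matched to its best
counterpart in the other set, the matches are averaged per direction, and
the two directional means are averaged.  The resulting score lies in [0, 1]
and equals 1 for identical sets of informative terms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .ontology import ICTable, OntologyGraph, lin_term_similarity

__all__ = [
    "TermSet",
    "PairScore",
    "ScoreSummary",
    "LinScorer",
    "set_similarity",
    "pairwise_grid",
    "pair_count",
    "summarize_scores",
    "per_owner_mean",
    "terms_vs_mean_regression",
    "write_pair_scores",
    "read_pair_scores",
]


@dataclass(frozen=True)
class TermSet:
    """A non-empty set of live phenotype terms owned by a gene or proband."""

    owner_id: str
    term_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.term_ids:
            raise ValueError(f"empty term set for {self.owner_id}")

    def __len__(self) -> int:
        return len(self.term_ids)


@dataclass(frozen=True)
class PairScore:
    """Similarity of one unordered owner pair; ``id_a < id_b``."""

    id_a: str
    id_b: str
    score: float

    def __post_init__(self) -> None:
        if not self.id_a < self.id_b:
            raise ValueError("PairScore requires id_a < id_b")
        if not 0.0 <= self.score <= 1.0 + 1e-12:
            raise ValueError(f"score out of [0,1]: {self.score}")


@dataclass(frozen=True)
class ScoreSummary:
    n_pairs: int
    mean: float
    sd: float
    minimum: float

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "mean": self.mean,
            "sd": self.sd,
            "minimum": self.minimum,
        }


class LinScorer:
    """Caches term-term Lin similarities across many set comparisons.

    Gene families share large term cores, so the same term pairs recur
    throughout a grid; memoisation makes the all-pairs computation linear in
    the number of *distinct* term pairs.
    """

    def __init__(self, graph: OntologyGraph, ic: ICTable):
        self.graph = graph
        self.ic = ic
        self._cache: dict[tuple[str, str], float] = {}

    def term_sim(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        val = self._cache.get(key)
        if val is None:
            val = lin_term_similarity(self.graph, self.ic, key[0], key[1])
            self._cache[key] = val
        return val

    def set_sim(self, set_a: TermSet, set_b: TermSet) -> float:
        a = sorted(set_a.term_ids)
        b = sorted(set_b.term_ids)
        # directional best-match means, then symmetrise
        best_a = [max(self.term_sim(x, y) for y in b) for x in a]
        best_b = [max(self.term_sim(x, y) for x in a) for y in b]
        forward = sum(best_a) / len(best_a)
        backward = sum(best_b) / len(best_b)
        return min(1.0, (forward + backward) / 2.0)


def set_similarity(
    graph: OntologyGraph, ic: ICTable, set_a: TermSet, set_b: TermSet
) -> float:
    """Symmetric best-match-average Lin similarity of two term sets."""
    return LinScorer(graph, ic).set_sim(set_a, set_b)


def pair_count(n: int) -> int:
    """Number of unordered pairs among n owners, ``n*(n-1)/2``."""
    return math.comb(n, 2)


def pairwise_grid(
    graph: OntologyGraph, ic: ICTable, annotations: Sequence[TermSet]
) -> list[PairScore]:
    """All-pairs similarity grid, sorted by ``(id_a, id_b)``.

    Exactly ``pair_count(len(annotations))`` records; self-pairs excluded.
    """
    if len(annotations) < 2:
        raise ValueError("need at least two annotation sets")
    owners = [s.owner_id for s in annotations]
    if len(set(owners)) != len(owners):
        raise ValueError("duplicate owner ids in annotation list")
    scorer = LinScorer(graph, ic)
    ordered = sorted(annotations, key=lambda s: s.owner_id)
    out: list[PairScore] = []
    for i, sa in enumerate(ordered):
        for sb in ordered[i + 1 :]:
            out.append(
                PairScore(sa.owner_id, sb.owner_id, scorer.set_sim(sa, sb))
            )
    return out


def summarize_scores(
    pairs: Sequence[PairScore], subset: Iterable[str] | None = None
) -> ScoreSummary:
    """Mean / sample SD / minimum of the retained pair scores.

    With ``subset`` given, a pair is retained only when *both* owners belong
    to the subset.  The SD of a single pair is reported as 0 rather than
    NaN.
    """
    if subset is not None:
        keep = set(subset)
        pairs = [p for p in pairs if p.id_a in keep and p.id_b in keep]
    if not pairs:
        raise ValueError("no pairs left to summarise")
    scores = np.array([p.score for p in pairs], dtype=float)
    sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
    return ScoreSummary(
        n_pairs=len(scores),
        mean=float(np.mean(scores)),
        sd=sd,
        minimum=float(np.min(scores)),
    )


def per_owner_mean(pairs: Sequence[PairScore]) -> dict[str, float]:
    """Mean score of every pair each owner participates in."""
    if not pairs:
        raise ValueError("no pairs")
    totals: dict[str, float] = {}
    counts: dict[str, int] = {}
    for p in pairs:
        for owner in (p.id_a, p.id_b):
            totals[owner] = totals.get(owner, 0.0) + p.score
            counts[owner] = counts.get(owner, 0) + 1
    return {o: totals[o] / counts[o] for o in totals}


def terms_vs_mean_regression(
    annotations: Sequence[TermSet], owner_means: Mapping[str, float]
):
    """OLS of per-gene mean similarity on ln(term-set size).

    Quantifies the (weak, positive) tendency of heavily annotated genes to
    score higher against the rest of the gene panel.  Returns a
    :class:`~phenoblend.cohort.RegressionResult`.
    """
    from .cohort import fit_ols

    sizes = []
    means = []
    for s in annotations:
        if s.owner_id in owner_means:
            sizes.append(math.log(len(s.term_ids)))
            means.append(owner_means[s.owner_id])
    return fit_ols(np.asarray(sizes), np.asarray(means))


# ---------------------------------------------------------------------------
# I/O


def write_pair_scores(pairs: Sequence[PairScore], dest: str | Path | IO[str]) -> None:
    """3-column TSV ``id_a  id_b  score`` with 6-decimal scores."""
    lines = [f"{p.id_a}\t{p.id_b}\t{p.score:.6f}" for p in pairs]
    text = "id_a\tid_b\tscore\n" + "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text, encoding="utf-8")


def read_pair_scores(source: str | Path | IO[str]) -> list[PairScore]:
    text = source.read() if hasattr(source, "read") else Path(source).read_text()
    out = []
    for line in text.splitlines()[1:]:
        a, b, s = line.split("\t")
        out.append(PairScore(a, b, float(s)))
    return out


def write_summary_json(
    summaries: Mapping[str, ScoreSummary], dest: str | Path | IO[str]
) -> None:
    payload = {name: s.to_dict() for name, s in summaries.items()}
    text = json.dumps(payload, indent=2) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text, encoding="utf-8")
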