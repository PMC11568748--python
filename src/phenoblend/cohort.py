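"""Dual-diagnosis cohort analysis: attribution, spectrum classes, regressions.

Each proband carries pathogenic variants in two genes.  Their recorded
phenotype terms were manually attributed to one gene, both genes, neither
gene, or excluded as common/subjective.  The attribution proportions place
each proband on a spectrum from *distinct* (every attributable phenotype
belongs to exactly one gene) through *blended* to *indistinguishable*
(every attributable phenotype could come from either gene), and the degree
of blending is predicted by the semantic similarity of the two genes'
phenotype annotations.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .g2p import GeneAnnotationSet, OpposingPairRegistry
from .ontology import ICTable, OntologyGraph
from .similarity import TermSet, set_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "ProbandRecord",
    "AttributionProportions",
    "RegressionResult",
    "SpectrumClass",
    "load_cohort",
    "packaged_cohort_path",
    "proband_gene_scores",
    "attribution_proportions",
    "classify_spectrum",
    "cohort_summary",
    "fit_ols",
    "blending_regressions",
    "subgroup_phenotype_counts",
    "antagonistic_proband_flags",
]

COHORT_COLUMNS = [
    "decipher_id",
    "age_years",
    "sex",
    "n_hpo_terms",
    "gene1",
    "gene2",
    "pair_score",
    "score_g1",
    "score_g2",
    "n_attr_g1",
    "n_attr_g2",
    "n_attr_both",
    "n_attr_neither",
    "n_excluded",
]


class SpectrumClass(str, Enum):
    DISTINCT = "distinct"
    BLENDED = "blended"
    INDISTINGUISHABLE = "indistinguishable"
    UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class ProbandRecord:
    """One proband with a dual molecular diagnosis.

    The five attribution counts partition the recorded phenotype terms
    (``n_hpo_terms``); the row-sum invariant is enforced at construction.
    ``proband_terms`` carries the actual term set for synthetic cohorts and
    is absent when only printed summary columns are available.
    """

    decipher_id: str
    age_years: float
    sex: str
    n_hpo_terms: int
    gene1: str
    gene2: str
    pair_score: float
    score_g1: float
    score_g2: float
    n_attr_g1: int
    n_attr_g2: int
    n_attr_both: int
    n_attr_neither: int
    n_excluded: int
    proband_terms: TermSet | None = None

    def __post_init__(self) -> None:
        counts = (
            self.n_attr_g1,
            self.n_attr_g2,
            self.n_attr_both,
            self.n_attr_neither,
            self.n_excluded,
        )
        if any(c < 0 for c in counts):
            raise ValueError(f"{self.decipher_id}: negative attribution count")
        if sum(counts) != self.n_hpo_terms:
            raise ValueError(
                f"{self.decipher_id}: attribution counts sum to {sum(counts)}, "
                f"expected n_hpo_terms={self.n_hpo_terms}"
            )
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.decipher_id}: bad sex {self.sex!r}")
        if self.age_years < 0:
            raise ValueError(f"{self.decipher_id}: negative age")
        if self.n_hpo_terms <= 0:
            raise ValueError(f"{self.decipher_id}: no phenotype terms")

    @property
    def n_attributed(self) -> int:
        """Terms attributed to one or both genes plus neither-gene terms."""
        return (
            self.n_attr_g1 + self.n_attr_g2 + self.n_attr_both + self.n_attr_neither
        )


@dataclass(frozen=True)
class AttributionProportions:
    p_one: float
    p_both: float
    p_neither: float
    denominator: int


@dataclass(frozen=True)
class RegressionResult:
    beta: float
    intercept: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# loading


def packaged_cohort_path() -> Path:
    """Path of the packaged 62-proband dual-diagnosis cohort table."""
    ref = importlib.resources.files("phenoblend") / "data" / "dual_diagnosis_cohort.tsv"
    return Path(str(ref))


def load_cohort(source: str | Path | IO[str] | None = None) -> list[ProbandRecord]:
    """Read a cohort TSV; with no argument, the packaged 62-proband table.

    Row-sum and field validity are enforced per proband; a violation names
    the offending DECIPHER id.
    """
    if source is None:
        source = packaged_cohort_path()
    df = pd.read_csv(source, sep="\t", dtype={"decipher_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if df.empty:
        raise ValueError("cohort table has no rows")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ProbandRecord(
                decipher_id=str(row.decipher_id),
                age_years=float(row.age_years),
                sex=str(row.sex),
                n_hpo_terms=int(row.n_hpo_terms),
                gene1=str(row.gene1),
                gene2=str(row.gene2),
                pair_score=float(row.pair_score),
                score_g1=float(row.score_g1),
                score_g2=float(row.score_g2),
                n_attr_g1=int(row.n_attr_g1),
                n_attr_g2=int(row.n_attr_g2),
                n_attr_both=int(row.n_attr_both),
                n_attr_neither=int(row.n_attr_neither),
                n_excluded=int(row.n_excluded),
            )
        )
    return records


# ---------------------------------------------------------------------------
# per-proband quantities


def proband_gene_scores(
    graph: OntologyGraph,
    ic: ICTable,
    proband_terms: TermSet,
    gene_terms: TermSet,
) -> float:
    """Similarity of a proband's phenotype to one gene's annotation set."""
    return set_similarity(graph, ic, proband_terms, gene_terms)


def attribution_proportions(
    record: ProbandRecord, denominator: str = "attributed"
) -> AttributionProportions:
    """Fractions of a proband's phenotypes attributed to one/both/neither gene.

    ``denominator="attributed"`` (default) divides by the terms that entered
    manual attribution (one + both + neither), leaving out terms excluded as
    common or subjective; ``denominator="recorded"`` divides by all recorded
    terms instead.
    """
    if denominator == "attributed":
        denom = record.n_attributed
    elif denominator == "recorded":
        denom = record.n_hpo_terms
    else:
        raise ValueError(f"unknown denominator mode: {denominator}")
    if denom <= 0:
        raise ValueError(
            f"{record.decipher_id}: unclassifiable, no attributable terms"
        )
    return AttributionProportions(
        p_one=(record.n_attr_g1 + record.n_attr_g2) / denom,
        p_both=record.n_attr_both / denom,
        p_neither=record.n_attr_neither / denom,
        denominator=denom,
    )


def classify_spectrum(record: ProbandRecord) -> SpectrumClass:
    """Place a proband on the distinct / blended / indistinguishable spectrum.

    *distinct*: every attributable phenotype belongs to exactly one gene;
    *indistinguishable*: every attributable phenotype belongs to both;
    *unclassifiable*: nothing could be attributed at all; *blended*
    otherwise.
    """
    one = record.n_attr_g1 + record.n_attr_g2
    both = record.n_attr_both
    if one + both == 0:
        return SpectrumClass.UNCLASSIFIABLE
    if both == 0:
        return SpectrumClass.DISTINCT
    if one == 0:
        return SpectrumClass.INDISTINGUISHABLE
    return SpectrumClass.BLENDED


# ---------------------------------------------------------------------------
# cohort-level summaries


def cohort_summary(records: Sequence[ProbandRecord]) -> dict:
    """Totals and distributions across the cohort."""
    if not records:
        raise ValueError("empty cohort")
    n_terms = np.array([r.n_hpo_terms for r in records])
    classes = [classify_spectrum(r) for r in records]
    one_total = sum(r.n_attr_g1 + r.n_attr_g2 for r in records)
    both_total = sum(r.n_attr_both for r in records)
    return {
        "n_probands": len(records),
        "total_phenotypes": int(n_terms.sum()),
        "median_phenotypes": float(np.median(n_terms)),
        "min_phenotypes": int(n_terms.min()),
        "max_phenotypes": int(n_terms.max()),
        "attributed_one_gene": one_total,
        "attributed_both_genes": both_total,
        "attributed_neither_gene": sum(r.n_attr_neither for r in records),
        "excluded_terms": sum(r.n_excluded for r in records),
        "percent_female": 100.0
        * sum(r.sex == "female" for r in records)
        / len(records),
        "mean_age_years": float(np.mean([r.age_years for r in records])),
        "spectrum_counts": {
            cls.value: sum(c is cls for c in classes) for cls in SpectrumClass
        },
    }


def fit_ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares of y on x with a two-sided slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor: slope is unidentifiable")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        beta=float(model.params[1]),
        intercept=float(model.params[0]),
        p_value=float(model.pvalues[1]),
        n=int(x.size),
    )


def blending_regressions(
    records: Sequence[ProbandRecord], denominator: str = "attributed"
) -> dict[str, RegressionResult]:
    """The three blending regressions on the gene-pair similarity score.

    (i) ``p_one``  — proportion attributed solely to one gene;
    (ii) ``p_both`` — proportion attributed to both genes;
    (iii) ``score_gap`` — |proband-vs-gene1 − proband-vs-gene2| similarity.
    A negative (i) and positive (ii) slope say that similar gene pairs
    produce blended presentations; a negative (iii) slope says the proband
    resembles both genes equally as the genes converge.
    """
    valid = [r for r in records if r.n_attributed > 0]
    if len(valid) < 3:
        raise ValueError("need at least 3 probands with attributable terms")
    x = np.array([r.pair_score for r in valid])
    props = [attribution_proportions(r, denominator) for r in valid]
    return {
        "p_one": fit_ols(x, np.array([p.p_one for p in props])),
        "p_both": fit_ols(x, np.array([p.p_both for p in props])),
        "score_gap": fit_ols(
            x, np.array([abs(r.score_g1 - r.score_g2) for r in valid])
        ),
    }


def subgroup_phenotype_counts(records: Sequence[ProbandRecord]) -> dict:
    """Phenotype-count burden of the distinct and indistinguishable classes.

    For each extreme class: mean recorded term count plus a Welch two-sided
    t-test against all remaining probands.  Also reports, as untested
    diagnostics, the correlation of term count with the attribution
    proportions.
    """
    classes = {r.decipher_id: classify_spectrum(r) for r in records}
    out: dict = {}
    for cls in (SpectrumClass.DISTINCT, SpectrumClass.INDISTINGUISHABLE):
        members = [r for r in records if classes[r.decipher_id] is cls]
        rest = [r for r in records if classes[r.decipher_id] is not cls]
        if not members:
            continue
        a = np.array([r.n_hpo_terms for r in members], dtype=float)
        b = np.array([r.n_hpo_terms for r in rest], dtype=float)
        if len(rest) >= 2 and (np.ptp(a) > 0 or np.ptp(b) > 0):
            t, p = stats.ttest_ind(a, b, equal_var=False)
        else:
            t, p = np.nan, 1.0
        out[cls.value] = {
            "n": len(members),
            "mean_n_hpo_terms": float(a.mean()),
            "welch_t": float(t),
            "welch_p": float(p),
        }
    # no-correlation diagnostic: term count vs attribution proportions
    valid = [r for r in records if r.n_attributed > 0]
    if len(valid) >= 3:
        n = np.array([r.n_hpo_terms for r in valid], dtype=float)
        props = [attribution_proportions(r) for r in valid]
        for name, vals in (
            ("p_one", np.array([p.p_one for p in props])),
            ("p_both", np.array([p.p_both for p in props])),
        ):
            if np.ptp(n) == 0 or np.ptp(vals) == 0:
                continue
            rho, p = stats.pearsonr(n, vals)
            out[f"corr_terms_vs_{name}"] = {"r": float(rho), "p": float(p)}
    return out


def antagonistic_proband_flags(
    records: Sequence[ProbandRecord],
    annotations: GeneAnnotationSet,
    registry: OpposingPairRegistry,
) -> dict[str, dict]:
    """Probands whose two diagnostic genes carry opposing phenotype terms.

    For each flagged proband the triggering opposing pair(s) are reported,
    together with whether the proband's own term set contains either member
    — absence of both is the cancellation signature the antagonism
    hypothesis predicts.
    """
    from .g2p import flag_antagonistic_pairs

    flagged_pairs = flag_antagonistic_pairs(annotations, registry)
    out: dict[str, dict] = {}
    for r in records:
        if r.gene1 not in annotations or r.gene2 not in annotations:
            logger.warning(
                "skipping proband %s: gene(s) missing from annotations",
                r.decipher_id,
            )
            continue
        key = tuple(sorted((r.gene1, r.gene2)))
        if key not in flagged_pairs:
            continue
        t1 = annotations[r.gene1].term_ids
        t2 = annotations[r.gene2].term_ids
        triggers = [
            (x, y)
            for x, y in registry
            if (x in t1 and y in t2) or (y in t1 and x in t2)
        ]
        proband_has = None
        if r.proband_terms is not None:
            opposing_terms = {t for pair in triggers for t in pair}
            proband_has = sorted(opposing_terms & r.proband_terms.term_ids)
        out[r.decipher_id] = {
            "genes": key,
            "opposing_pairs": triggers,
            "proband_opposing_terms": proband_has,
        }
    return out
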