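# Methods

## Model and procedure

phenoblend treats a phenotype ontology as a directed acyclic graph whose
only semantic edges are is-a (subclass) relations; all other relationship
types are ignored. Obsolete terms carry no edges and are handled purely as
redirects: a `replaced_by` target is followed (recursively, cycle-guarded),
otherwise the first `consider` entry, otherwise the identifier is dropped
with a logged warning.

Information content is **structure-based**: `IC(t) = −ln(d(t)/N)` where
`d(t)` counts the non-obsolete descendants of `t` including itself and `N`
is the number of non-obsolete terms. This choice is corpus-free — it
depends on the ontology file alone, so any two runs on the same release
agree exactly. The alternative, annotation-frequency IC, requires an
annotation corpus and is out of scope. Natural logarithms are used
throughout; the base cancels in the similarity ratio anyway.

Term–term similarity is Lin's measure through the most informative common
ancestor. Degenerate cases are fixed by convention: two terms with no
common ancestor (disconnected components — multiple roots are permitted
and no virtual super-root is added) score 0, as does the root-vs-root case
where both ICs vanish. MICA ties need no tie-breaking because only the IC
value enters the score.

Set-vs-set similarity is the **symmetric best-match average**: each term's
best Lin match in the other set, averaged per direction, then the two
directional means averaged. It is symmetric, bounded in [0, 1], and equal
to 1 on identical sets of informative terms. One sharp edge documented by
a property test: adding the *root* term to both sets lowers the score,
because the root's best match is 0 by the conventions above — the "shared
term never hurts" intuition holds only for informative terms.

Gene annotation sets are curated from a G2P-style table by (1) retaining
entries with confidence `strong` or `definitive` (case-insensitive;
configurable), (2) resolving obsolete term ids, (3) pooling terms per gene
across all of its entries, (4) removing the mode-of-inheritance subtree
(everything whose ancestor closure contains HP:0000005), and (5) dropping
genes left empty. Every drop is tallied in provenance counters rather than
raising, so curation is an audit trail, not a gate. Note that pooling per
gene deliberately merges distinct conditions caused by the same gene; this
mirrors how gene-level similarity grids are built and is a known source of
blur for pleiotropic genes.

**Antagonistic pairs** (opposing phenotypes such as micro-/macrocephaly)
are flagged when one gene carries term X and the other carries term Y for
some registry pair (X, Y). Matching is on exact term membership, not
ancestor closure: propagating to ancestors would flag vague terms
("abnormality of skull size") spuriously. The shipped registry is a small
curated starter list (head size, orbital spacing, jaw position, stature,
muscle tone); there is no official machine-readable opposite-of file, so
the registry is a plain TSV meant to be extended. **Synergistic pairs**
are those sharing at least k identical terms (defaults k = 1 and k = 5).

## Cohort analysis

Each proband record carries the two diagnostic genes, the gene-pair
similarity, the proband-vs-gene similarities, and five manual-attribution
counts (one gene / other gene / both / neither / excluded as common or
subjective) whose sum must equal the recorded term count; this row-sum
invariant is enforced on load. Attribution proportions divide by the terms
that entered attribution (one + both + neither) by default — excluded
terms were removed before analysis — with the all-recorded-terms
denominator available as a switch, since either convention is defensible.

Spectrum classes partition probands: *distinct* (no both-gene terms, at
least one single-gene term), *indistinguishable* (no single-gene terms, at
least one both-gene term), *unclassifiable* (nothing attributed), else
*blended*. The three blending regressions are ordinary least squares on
the gene-pair score: the one-gene proportion (negative slope), the
both-genes proportion (positive slope), and the absolute gap between the
two proband-vs-gene scores (negative slope). Subgroup phenotype burdens
use Welch's unequal-variance t-test, the conservative default when only a
significance threshold is of interest. The correlation between per-proband
term counts and attribution proportions is reported as an untested
diagnostic only, because its exact published specification is ambiguous.

On the packaged 62-proband table the per-proband term counts have an exact
median of 6.5 (the two middle order statistics are 6 and 7); summaries
report the exact value and round only at display time.

## Synthetic data generator

The generator produces the three study artifacts with a single seeded
`numpy` Generator each (no global RNG state) and byte-stable writers, so
identical seeds give identical files.

* **Ontology**: one root, `depth` levels whose sizes grow geometrically
  with `branching` (rescaled to `n_terms`); each term takes one uniform
  parent from the previous level and a second with probability 0.2,
  creating the diamond motifs of real ontologies.
* **Gene annotations**: genes split evenly into `n_families`, each family
  owning a disjoint term pool whose prefix is the family core. A gene of
  size s takes its first `round(core_fraction · s)` terms from the core
  sequence (so family members share them) and samples the rest privately
  from the pool. Sizes are log-normal (σ = 1, mean-matched to
  `terms_per_gene_mean` = 22, truncated to 1–242), reproducing the heavy
  right tail of real per-gene term counts. The resulting pairwise grid has
  the two-population structure of real gene panels: a high-scoring
  within-family mode over a lower between-family background, with the gap
  growing in `core_fraction`. With `opposing_injection` on, consecutive
  family pairs receive one member each of an opposing term pair drawn from
  held-out terms, so the implied antagonistic gene pairs are known exactly.
* **Cohort**: default 62 probands; each gets a random gene pair and 1–21
  terms; every term is background noise with probability `noise_rate`
  (ground truth: neither gene), otherwise drawn from gene 1 with the
  mixing weight `w` (default 0.5) or gene 2 with `1 − w`; a drawn term
  present in both gene sets is attributed to both, so shared phenotypes
  surface in proportion to the genes' overlap. The generating attribution
  of every term is recorded, giving the manual-curation columns a known
  truth, and similarity columns are computed with the same scorer as the
  analysis.

Because probands accumulate *distinct* terms by sequential draws, category
counts follow a multivariate Wallenius (biased-urn) law rather than simple
binomial proportions; the acceptance battery recovers the generating
relation by computing each proband's expected both-gene fraction from the
Wallenius mean equations `E[k_i] = m_i (1 − t^{w_i})` and checking that the
regression of realised on expected fractions has slope 1 within a
bootstrap confidence interval (200 probands, 1,000 resamples).

What the generator does **not** emulate: real HPO depth (~15 levels) and
term count (~17k), annotation noise from literature curation, pleiotropy
(each synthetic gene is one condition), ascertainment bias in cohort
composition, and correlated term co-occurrence beyond family cores.
Passing tests therefore demonstrate algorithmic correctness and the
qualitative structure of the statistics, not numeric reproduction of any
full-database figure — those require the external database snapshots and
are supported as an optional workflow through the same CLI.

## Numerical choices

* Sample standard deviation (ddof = 1); the SD of a single pair is
  reported as 0 to avoid NaN propagation.
* Scores are kept at full precision internally and rounded only in file
  output (6 decimals for pair grids, 3 for cohort tables, matching the
  precision such tables are published at).
* Pair grids are sorted by owner-id pair, making parallel or re-ordered
  computation bit-identical after sorting.
* OLS through statsmodels with an intercept; slope p-values are two-sided
  t-tests. Regressions refuse constant predictors and n < 3.
* Problem sizes in the test suite (ontologies ≤ 250 terms, ≤ 40 genes,
  cohorts ≤ 200 probands, 20-seed batches) were chosen as the smallest
  sizes at which the distributional properties under test are stable.

## Known limitations

* Descendant-count IC compresses similarity less than frequency-based IC
  on deep, unevenly annotated ontologies; absolute score values are not
  comparable across IC choices, only orderings are robust.
* Whether the original gene-pair grids used symmetric or asymmetric
  best-match combining is not documented; only the symmetric variant is
  implemented.
* Antagonistic flagging inherits the registry's coverage: unlisted
  opposing pairs are invisible. Down-weighting antagonistic matches inside
  the similarity score itself is a possible extension, deliberately not
  implemented.
* Gene-level pooling misrepresents pleiotropic genes with several distinct
  conditions; gene-condition dyads are out of scope.
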