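"""Cohort loading, attribution proportions, spectrum classes, regressions."""

from __future__ import annotations

import io

import numpy as np
import pytest

from phenoblend import (
    OpposingPairRegistry,
    ProbandRecord,
    SpectrumClass,
    TermSet,
    antagonistic_proband_flags,
    attribution_proportions,
    blending_regressions,
    classify_spectrum,
    cohort_summary,
    compute_descendants_ic,
    fit_ols,
    load_cohort,
    parse_obo,
    proband_gene_scores,
    subgroup_phenotype_counts,
)
from phenoblend.g2p import GeneAnnotationSet


@pytest.fixture(scope="module")
def cohort():
    return load_cohort()


def _record(g1, g2, both, neither=0, excluded=0, pair_score=0.5, **kw):
    n = g1 + g2 + both + neither + excluded
    defaults = dict(
        decipher_id="P1",
        age_years=5.0,
        sex="male",
        n_hpo_terms=n,
        gene1="GA",
        gene2="GB",
        pair_score=pair_score,
        score_g1=0.5,
        score_g2=0.4,
        n_attr_g1=g1,
        n_attr_g2=g2,
        n_attr_both=both,
        n_attr_neither=neither,
        n_excluded=excluded,
    )
    defaults.update(kw)
    return ProbandRecord(**defaults)


class TestLoadCohort:
    def test_packaged_fixture_has_62_probands(self, cohort):
        assert len(cohort) == 62
        assert len({r.decipher_id for r in cohort}) == 62

    def test_known_rows_transcribed(self, cohort):
        by_id = {r.decipher_id: r for r in cohort}
        r = by_id["258830"]
        assert r.n_hpo_terms == 18
        assert (
            r.n_attr_g1,
            r.n_attr_g2,
            r.n_attr_both,
            r.n_attr_neither,
            r.n_excluded,
        ) == (0, 5, 12, 0, 1)
        r2 = by_id["303270"]
        assert (r2.gene1, r2.gene2) == ("NF1", "CBL")
        assert (r2.n_attr_g1, r2.n_attr_g2, r2.n_attr_both) == (0, 0, 6)

    def test_row_sum_invariant_holds_for_every_row(self, cohort):
        for r in cohort:
            assert (
                r.n_attr_g1 + r.n_attr_g2 + r.n_attr_both
                + r.n_attr_neither + r.n_excluded
                == r.n_hpo_terms
            )

    def test_row_sum_violation_names_the_proband(self):
        header = (
            "decipher_id\tage_years\tsex\tn_hpo_terms\tgene1\tgene2\t"
            "pair_score\tscore_g1\tscore_g2\tn_attr_g1\tn_attr_g2\t"
            "n_attr_both\tn_attr_neither\tn_excluded\n"
        )
        bad = header + "900001\t5.0\tmale\t6\tA\tB\t0.5\t0.4\t0.3\t1\t1\t1\t0\t0\n"
        with pytest.raises(ValueError, match="900001"):
            load_cohort(io.StringIO(bad))

    def test_empty_and_malformed_inputs_rejected(self):
        with pytest.raises(ValueError):
            load_cohort(io.StringIO("decipher_id\n"))
        header = (
            "decipher_id\tage_years\tsex\tn_hpo_terms\tgene1\tgene2\t"
            "pair_score\tscore_g1\tscore_g2\tn_attr_g1\tn_attr_g2\t"
            "n_attr_both\tn_attr_neither\tn_excluded\n"
        )
        bad_sex = header + "900002\t5.0\tunknown\t1\tA\tB\t0.5\t0.4\t0.3\t1\t0\t0\t0\t0\n"
        with pytest.raises(ValueError, match="sex"):
            load_cohort(io.StringIO(bad_sex))


class TestAttributionProportions:
    def test_all_both_row(self):
        p = attribution_proportions(_record(0, 0, 6))
        assert (p.p_one, p.p_both, p.p_neither) == (0.0, 1.0, 0.0)

    def test_mostly_one_gene_row_with_exclusions(self):
        # seven to gene1, one to gene2, one neither, two excluded
        p = attribution_proportions(_record(7, 1, 0, neither=1, excluded=2))
        assert p.p_one == pytest.approx(8 / 9)
        assert p.p_both == 0.0
        assert p.denominator == 9

    def test_even_split_arithmetic(self):
        p = attribution_proportions(_record(1, 1, 1, neither=1))
        assert (p.p_one, p.p_both, p.p_neither) == (0.5, 0.25, 0.25)

    def test_recorded_denominator_counts_exclusions(self):
        r = _record(1, 1, 1, neither=1, excluded=4)
        assert attribution_proportions(r, "recorded").denominator == 8
        assert attribution_proportions(r, "attributed").denominator == 4

    def test_proportions_sum_to_one(self, cohort):
        for r in cohort:
            p = attribution_proportions(r)
            assert p.p_one + p.p_both + p.p_neither == pytest.approx(1.0)

    def test_all_excluded_proband_is_an_error(self):
        with pytest.raises(ValueError, match="unclassifiable"):
            attribution_proportions(_record(0, 0, 0, excluded=3))


class TestClassifySpectrum:
    @pytest.mark.parametrize(
        "g1, g2, both, neither, excluded, expected",
        [
            (7, 1, 0, 1, 2, SpectrumClass.DISTINCT),
            (0, 0, 6, 0, 0, SpectrumClass.INDISTINGUISHABLE),
            (2, 0, 3, 0, 0, SpectrumClass.BLENDED),
            (0, 0, 0, 2, 1, SpectrumClass.UNCLASSIFIABLE),
        ],
    )
    def test_classes(self, g1, g2, both, neither, excluded, expected):
        rec = _record(g1, g2, both, neither=neither, excluded=excluded)
        assert classify_spectrum(rec) is expected

    def test_partition_covers_cohort(self, cohort):
        counts = cohort_summary(cohort)["spectrum_counts"]
        assert sum(counts.values()) == len(cohort)


class TestCohortSummary:
    def test_fixture_totals(self, cohort):
        s = cohort_summary(cohort)
        assert s["total_phenotypes"] == 466
        assert (s["min_phenotypes"], s["max_phenotypes"]) == (1, 21)
        assert s["attributed_one_gene"] == 186
        assert s["attributed_both_genes"] == 242
        assert s["attributed_neither_gene"] == 13
        assert s["excluded_terms"] == 25

    def test_fixture_demographics(self, cohort):
        s = cohort_summary(cohort)
        assert round(s["percent_female"]) == 42
        assert s["mean_age_years"] == pytest.approx(7.8, abs=0.05)

    def test_single_proband_summary(self):
        s = cohort_summary([_record(2, 1, 1)])
        assert s["total_phenotypes"] == 4
        assert s["median_phenotypes"] == 4


class TestFitOls:
    def test_exact_linear_fit(self):
        x = np.arange(5.0)
        res = fit_ols(x, 2 * x + 1)
        assert res.beta == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.p_value < 1e-10

    def test_permuted_response_slope_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, size=62)
        y = rng.permutation(2 * x)
        res = fit_ols(x, y)
        assert abs(res.beta) < 0.5
        assert res.n == 62

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_ols(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            fit_ols(np.ones(5), np.arange(5.0))


class TestBlendingRegressions:
    def test_fixture_slopes(self, cohort):
        regs = blending_regressions(cohort)
        assert regs["p_one"].beta == pytest.approx(-1.01, abs=0.005)
        assert regs["p_both"].beta == pytest.approx(1.14, abs=0.005)
        assert regs["score_gap"].beta == pytest.approx(-0.44, abs=0.005)

    def test_row_order_invariance(self, cohort):
        shuffled = list(cohort)
        np.random.default_rng(1).shuffle(shuffled)
        a = blending_regressions(cohort)
        b = blending_regressions(shuffled)
        for key in a:
            assert a[key].beta == pytest.approx(b[key].beta)

    def test_proportion_slopes_compose(self, cohort):
        """slope(p_one) + slope(p_both) == -slope(p_neither) since the
        three proportions sum to 1 for every proband."""
        regs = blending_regressions(cohort)
        x = np.array([r.pair_score for r in cohort])
        p_neither = np.array(
            [attribution_proportions(r).p_neither for r in cohort]
        )
        neither_slope = fit_ols(x, p_neither).beta
        assert regs["p_one"].beta + regs["p_both"].beta == pytest.approx(
            -neither_slope
        )


class TestSubgroups:
    def test_fixture_extreme_class_means(self, cohort):
        out = subgroup_phenotype_counts(cohort)
        assert out["distinct"]["n"] == 5
        assert out["distinct"]["mean_n_hpo_terms"] == pytest.approx(10.2)
        assert out["indistinguishable"]["n"] == 9
        assert out["indistinguishable"]["mean_n_hpo_terms"] == pytest.approx(
            3.8, abs=0.05
        )
        assert out["distinct"]["welch_p"] < 0.05
        assert out["indistinguishable"]["welch_p"] < 0.001

    def test_identical_groups_give_p_one(self):
        recs = [
            _record(1, 0, 0, decipher_id=f"D{i}") for i in range(3)
        ] + [
            _record(0, 0, 1, decipher_id=f"I{i}") for i in range(3)
        ]
        # both groups have a single phenotype each: means equal, p == 1
        out = subgroup_phenotype_counts(recs)
        assert out["distinct"]["mean_n_hpo_terms"] == 1.0
        assert out["indistinguishable"]["mean_n_hpo_terms"] == 1.0
        assert out["distinct"]["welch_p"] == pytest.approx(1.0)


class TestProbandGeneScores:
    def test_identical_sets_score_one(self, toy_graph):
        ic = compute_descendants_ic(toy_graph)
        s = TermSet("p", frozenset({"HP:0000003", "HP:0000004"}))
        g = TermSet("g", frozenset({"HP:0000003", "HP:0000004"}))
        assert proband_gene_scores(toy_graph, ic, s, g) == pytest.approx(1.0)

    def test_disjoint_components_score_zero(self, two_component_graph):
        ic = compute_descendants_ic(two_component_graph)
        s = TermSet("p", frozenset({"X:2"}))
        g = TermSet("g", frozenset({"Y:2"}))
        assert proband_gene_scores(two_component_graph, ic, s, g) == 0.0


ANTAG_OBO = """format-version: 1.2

[Term]
id: HP:0000001
name: root

[Term]
id: HP:0000316
name: hypertelorism
is_a: HP:0000001

[Term]
id: HP:0000601
name: hypotelorism
is_a: HP:0000001

[Term]
id: HP:0000010
name: unrelated phenotype
is_a: HP:0000001
"""


class TestAntagonisticProbandFlags:
    @pytest.fixture(scope="class")
    @staticmethod
    def setup():
        graph = parse_obo(ANTAG_OBO)
        annotations = GeneAnnotationSet(
            term_sets={
                "ANKRD11": TermSet("ANKRD11", frozenset({"HP:0000316", "HP:0000010"})),
                "SMARCA4": TermSet("SMARCA4", frozenset({"HP:0000601"})),
                "OTHER": TermSet("OTHER", frozenset({"HP:0000010"})),
            }
        )
        registry = OpposingPairRegistry([("HP:0000316", "HP:0000601")])
        return graph, annotations, registry

    def test_opposing_pair_proband_flagged_without_either_term(self, setup):
        _, annotations, registry = setup
        rec = _record(
            1, 1, 4, excluded=1,
            decipher_id="266333", gene1="SMARCA4", gene2="ANKRD11",
            proband_terms=TermSet("266333", frozenset({"HP:0000010"})),
        )
        flags = antagonistic_proband_flags([rec], annotations, registry)
        assert "266333" in flags
        assert flags["266333"]["opposing_pairs"] == [("HP:0000316", "HP:0000601")]
        # absent-phenotype signature: the proband has neither eye term
        assert flags["266333"]["proband_opposing_terms"] == []

    def test_empty_registry_flags_nothing(self, setup):
        _, annotations, _ = setup
        rec = _record(1, 1, 4, decipher_id="X", gene1="SMARCA4", gene2="ANKRD11")
        assert (
            antagonistic_proband_flags([rec], annotations, OpposingPairRegistry([]))
            == {}
        )

    def test_matches_brute_force_scan(self, setup):
        _, annotations, registry = setup
        records = [
            _record(1, 0, 1, decipher_id="A", gene1="ANKRD11", gene2="SMARCA4"),
            _record(1, 0, 1, decipher_id="B", gene1="ANKRD11", gene2="OTHER"),
            _record(1, 0, 1, decipher_id="C", gene1="OTHER", gene2="SMARCA4"),
        ]
        flags = antagonistic_proband_flags(records, annotations, registry)
        expected = set()
        for r in records:
            t1 = annotations[r.gene1].term_ids
            t2 = annotations[r.gene2].term_ids
            for x, y in registry:
                if (x in t1 and y in t2) or (y in t1 and x in t2):
                    expected.add(r.decipher_id)
        assert set(flags) == expected == {"A"}

    def test_missing_gene_skipped_with_warning(self, setup, caplog):
        _, annotations, registry = setup
        rec = _record(1, 0, 1, decipher_id="Z", gene1="NOTTHERE", gene2="SMARCA4")
        flags = antagonistic_proband_flags([rec], annotations, registry)
        assert flags == {}
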