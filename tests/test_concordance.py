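"""Confusion classification, the six metrics, Wilson/bootstrap intervals,
equivalence-adjusted concordance, per-site and replicate reports."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pgxkit import concordance as conc
from pgxkit.genotype_qc import GenotypeTable
from pgxkit.model import ContentBundle, EquivalenceRules, VariantDef


class TestWilson:
    @pytest.mark.parametrize("k,n,lo,hi", [
        (24, 27, 71.94, 96.15),
        (52, 66, 67.49, 86.92),
        (14, 66, 13.08, 32.51),
        (9, 15, 35.75, 80.18),
        (23, 24, 79.76, 99.26),
        (0, 8, 0.00, 32.44),
        (8, 8, 67.56, 100.00),
    ])
    def test_reference_values(self, k, n, lo, hi):
        assert conc.wilson_interval(k, n) == (lo, hi)

    def test_zero_numerator_pins_lower_bound(self):
        lo, _ = conc.wilson_interval(0, 8)
        assert lo == 0.0

    @settings(max_examples=200, deadline=None)
    @given(st.integers(1, 500), st.data())
    def test_complement_symmetry(self, n, data):
        """wilson(k,n) and wilson(n-k,n) mirror each other to rounding."""
        k = data.draw(st.integers(0, n))
        lo1, hi1 = conc.wilson_interval(k, n)
        lo2, hi2 = conc.wilson_interval(n - k, n)
        assert lo1 == pytest.approx(100 - hi2, abs=0.011)
        assert hi1 == pytest.approx(100 - lo2, abs=0.011)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(1, 400), st.data())
    def test_matches_independent_implementation(self, n, data):
        from statsmodels.stats.proportion import proportion_confint
        k = data.draw(st.integers(0, n))
        lo, hi = conc.wilson_interval(k, n)
        slo, shi = proportion_confint(k, n, method="wilson")
        assert lo == pytest.approx(100 * slo, abs=0.006)
        assert hi == pytest.approx(100 * shi, abs=0.006)

    def test_interval_contains_point(self):
        for k, n in [(0, 5), (5, 5), (3, 7), (52, 66)]:
            lo, hi = conc.wilson_interval(k, n)
            assert lo <= round(100 * k / n, 2) <= hi


class TestClassification:
    @pytest.mark.parametrize("t,q,cat", [
        (1, 1, conc.CAT_TP_HET),
        (2, 2, conc.CAT_TP_HOM),
        (0, 0, conc.CAT_TN),
        (0, 1, conc.CAT_FP),
        (0, 2, conc.CAT_FP),
        (1, 0, conc.CAT_FN),
        (2, 0, conc.CAT_FN),
        (2, 1, conc.CAT_FN),   # assay under-calls the alt dosage
        (1, 2, conc.CAT_FP),   # assay over-calls the alt dosage
        (1, None, conc.CAT_NO_CALL),
    ])
    def test_dosage_pairs(self, t, q, cat):
        assert conc.classify_dosages(t, q) == cat

    def test_table_classification_and_not_in_reference(self):
        v1 = VariantDef("G", "rs1", "chr1", 100, "A", "C")
        v2 = VariantDef("G", "rs2", "chr1", 200, "A", "C")
        q = GenotypeTable(["S1"], [v1, v2])
        t = GenotypeTable(["S1"], [v1, v2])
        q.set("S1", v1, 1)
        q.set("S1", v2, 1)
        t.set("S1", v1, 1)  # v2 missing from truth
        counts, cats = conc.classify_site_calls(q, t)
        assert cats[("S1", v1)] == conc.CAT_TP_HET
        assert cats[("S1", v2)] == conc.CAT_NOT_IN_REF
        assert counts.considered == 1

    def test_counts_identity(self):
        c = conc.ConfusionCounts(tp=3, tn=5, fp=1, fn=2, no_call=4)
        assert c.tp + c.tn + c.fp + c.fn + c.no_call == c.considered

    def test_overrides_are_applied_by_sample_and_rsid(self):
        v1 = VariantDef("G", "rs1", "chr1", 100, "A", "C")
        cats = {("S1", v1): conc.CAT_FN, ("S2", v1): conc.CAT_FN}
        out = conc.apply_overrides(cats, [conc.CategoryOverride(
            "S1", "rs1", conc.CAT_TP_HET, "known single-copy sample")])
        assert out[("S1", v1)] == conc.CAT_TP_HET
        assert out[("S2", v1)] == conc.CAT_FN


class TestMetrics:
    def test_cnv_sensitivity_row(self):
        m = conc.metrics(conc.ConfusionCounts(tp=9, fn=6))
        s = m["sensitivity"]
        assert (s.point, s.ci_low, s.ci_high) == (60.00, 35.75, 80.18)

    def test_all_tn_gives_full_specificity(self):
        m = conc.metrics(conc.ConfusionCounts(tn=30))
        assert m["specificity"].point == 100.0
        assert m["precision"] is None  # tp+fp = 0

    def test_callability_no_call_complement(self):
        m = conc.metrics(conc.ConfusionCounts(tp=40, tn=8, fp=2, fn=2, no_call=14))
        assert m["callability"].point + m["no_call_rate"].point == pytest.approx(100.0)
        assert m["callability"].ci_low == pytest.approx(
            100 - m["no_call_rate"].ci_high, abs=0.011)

    def test_all_cis_contain_their_points(self):
        m = conc.metrics(conc.ConfusionCounts(tp=11, tn=7, fp=3, fn=2, no_call=5))
        for est in m.values():
            assert est.ci_low <= est.point <= est.ci_high


class TestBootstrap:
    def test_constant_vector_collapses(self):
        lo, hi = conc.bootstrap_mean_ci([4.2] * 10, reps=200, seed=0)
        assert lo == pytest.approx(4.2) and hi == pytest.approx(4.2)
        assert lo == hi

    def test_same_seed_same_interval(self):
        vals = list(np.random.default_rng(5).normal(10, 2, 50))
        a = conc.bootstrap_mean_ci(vals, reps=2000, seed=42)
        b = conc.bootstrap_mean_ci(vals, reps=2000, seed=42)
        assert a == b

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            conc.bootstrap_mean_ci([], seed=0)

    def test_coverage_near_nominal(self):
        """~95% of intervals from Normal(mu, sigma) samples cover mu."""
        rng = np.random.default_rng(2024)
        mu, sigma, n = 50.0, 8.0, 200
        covered = 0
        reps = 400
        for i in range(reps):
            vals = rng.normal(mu, sigma, n)
            lo, hi = conc.bootstrap_mean_ci(vals, reps=500, seed=int(i))
            covered += lo <= mu <= hi
        assert 0.91 <= covered / reps <= 0.985


def _rules(*triples):
    r = EquivalenceRules()
    for g, a, b in triples:
        r.add(g, a, b)
    return r


class TestDiplotypeConcordance:
    def test_equivalence_rewrites_make_pairs_concordant(self):
        rules = _rules(("CYP2D6", "*2", "*1"),
                       ("UGT1A1", "*60", "*1"), ("UGT1A1", "*28", "*80"),
                       ("UGT1A1", "*37", "*80"))
        assert conc.pairs_concordant(("*1", "*1"), ("*2", "*2"), "CYP2D6", rules)
        assert conc.pairs_concordant(("*80", "*1"), ("*28", "*1"), "UGT1A1", rules)
        assert conc.pairs_concordant(("*80", "*1"), ("*37", "*60"), "UGT1A1", rules)
        assert not conc.pairs_concordant(("*80", "*80"), ("*28", "*1"), "UGT1A1", rules)

    def test_order_and_rewrite_invariance(self):
        rules = _rules(("G", "*2", "*1"))
        assert conc.pairs_concordant(("*3", "*1"), ("*1", "*3"), "G", rules)
        q, t = ("*2", "*3"), ("*1", "*3")
        assert conc.pairs_concordant(q, t, "G", rules)
        # rewriting both sides first changes nothing
        qr = tuple(rules.rewrite("G", a) for a in q)
        tr = tuple(rules.rewrite("G", a) for a in t)
        assert conc.pairs_concordant(qr, tr, "G", rules)

    def test_variant_label_multisets_for_dpyd_style_genes(self):
        rules = EquivalenceRules()
        assert conc.pairs_concordant(("c.85T>C", "c.1627A>G"),
                                     ("c.1627A>G", "c.85T>C"), "DPYD", rules)

    def test_26_samples_24_concordant(self):
        rules = EquivalenceRules()
        truth = {(f"S{i}", "G"): ("*1", "*1") for i in range(26)}
        query = {k: ("*1", "*1") for k in truth}
        query[("S0", "G")] = ("*1", "*2")
        query[("S1", "G")] = ("*2", "*2")
        out = conc.diplotype_concordance(query, truth, rules)["G"]
        assert out.concordance.point == 92.31
        assert (out.concordance.k, out.concordance.n) == (24, 26)

    def test_callability_counts_no_calls_against_truth_denominator(self):
        rules = EquivalenceRules()
        truth = {(f"S{i}", "G"): ("*1", "*1") for i in range(27)}
        query = {k: ("*1", "*1") for k in truth}
        for i in range(3):
            query[(f"S{i}", "G")] = None
        out = conc.diplotype_concordance(query, truth, rules)["G"]
        assert (out.callability.k, out.callability.n) == (24, 27)
        assert (out.callability.ci_low, out.callability.ci_high) == (71.94, 96.15)
        assert out.concordance.n == 24


class TestPhenotypeConcordance:
    def test_possible_qualifier_ignored_by_default(self):
        assert conc.label_comparator("Possibly Normal Metabolizer",
                                     "Normal Metabolizer")
        assert conc.label_comparator("Possible Normal Metabolizer",
                                     "Normal Metabolizer")
        assert not conc.label_comparator("Possibly Poor Metabolizer",
                                         "Normal Metabolizer")

    def test_allele_presence_comparator(self):
        cmp = conc.allele_presence_comparator("*3")
        assert cmp("*1/*3", "*3/*3")
        assert cmp("*1/*1", "*1/*2")
        assert not cmp("*1/*3", "*1/*1")

    def test_empty_gene_estimate_absent(self):
        out = conc.phenotype_concordance({}, {})
        assert out == {}

    def test_per_gene_estimates(self):
        truth = {(f"S{i}", "G"): "Normal Metabolizer" for i in range(10)}
        query = dict(truth)
        query[("S0", "G")] = None
        query[("S1", "G")] = "Poor Metabolizer"
        out = conc.phenotype_concordance(query, truth)["G"]
        assert (out.callability.k, out.callability.n) == (9, 10)
        assert (out.concordance.k, out.concordance.n) == (8, 9)


class TestPerSiteReport:
    def _cats(self, spec):
        cats = {}
        for rsid, items in spec.items():
            v = VariantDef("G", rsid, "chr1", int(rsid[2:]), "A", "C")
            for i, cat in enumerate(items):
                cats[(f"S{i}", v)] = cat
        return cats

    def test_fully_concordant_site(self):
        cats = self._cats({"rs100": [conc.CAT_TP_HET] * 3 + [conc.CAT_TN] * 2})
        reports, summary = conc.per_site_report(cats)
        assert reports[0].concordance == 100.0
        assert reports[0].evaluable_with_tp
        assert summary["fraction_percent"] == 100.0

    def test_fraction_above_threshold(self):
        spec = {f"rs{100 + i}": [conc.CAT_TP_HET] * 20 for i in range(9)}
        spec["rs999"] = [conc.CAT_TP_HET] * 10 + [conc.CAT_FP] * 10  # 50%
        reports, summary = conc.per_site_report(self._cats(spec), threshold=95.0)
        assert summary["sites_scored"] == 10
        assert summary["sites_at_or_above_threshold"] == 9
        assert summary["fraction_percent"] == 90.0

    def test_site_absent_from_reference_excluded(self):
        cats = self._cats({"rs100": [conc.CAT_NOT_IN_REF] * 5})
        reports, summary = conc.per_site_report(cats)
        assert reports[0].concordance is None
        assert summary["sites_scored"] == 0


class TestReplicateConcordance:
    def _reps(self, triples):
        return [conc.ReplicateCall(s, run, rep, val)
                for s, run, rep, val in triples]

    def test_identical_triplicates_100_percent(self):
        calls = self._reps([("A", "r1", "1", "x"), ("A", "r1", "2", "x"),
                            ("A", "r2", "1", "x")])
        out = conc.replicate_concordance(calls)
        assert out["intra_run"].point == 100.0
        assert out["inter_run"].point == 100.0

    def test_one_disagreement_in_200_pairs(self):
        calls = []
        for i in range(200):
            val_b = "y" if i == 0 else "x"
            calls += self._reps([(f"S{i}", "r1", "1", "x"), (f"S{i}", "r2", "1", val_b)])
        out = conc.replicate_concordance(calls)
        assert out["inter_run"].point == 99.5
        assert out["intra_run"] is None

    def test_single_replicate_absent(self):
        out = conc.replicate_concordance(self._reps([("A", "r1", "1", "x")]))
        assert out["intra_run"] is None and out["inter_run"] is None

    def test_both_missing_pairs_excluded_one_missing_disagrees(self):
        calls = self._reps([("A", "r1", "1", None), ("A", "r1", "2", None),
                            ("B", "r1", "1", "x"), ("B", "r1", "2", None)])
        out = conc.replicate_concordance(calls)
        assert (out["intra_run"].k, out["intra_run"].n) == (0, 1)


class TestHaplotypeCoverage:
    def _bundle_with(self, alleles_per_gene):
        from pgxkit.model import (ActivityConfig, FrequencyTable, GeneDef,
                                  HaplotypeDef, PhenotypeMap)
        genes, haps = {}, {}
        for g, names in alleles_per_gene.items():
            genes[g] = GeneDef(g, "chr1", 1, 100, names[0])
            haps[g] = {n: HaplotypeDef(g, n) for n in names}
        return ContentBundle(genes, [], haps, FrequencyTable(), PhenotypeMap(),
                             EquivalenceRules())

    def test_full_coverage(self):
        b = self._bundle_with({"G": ["*1", "*2"]})
        truth = {("S1", "G"): ("*1", "*2")}
        assert conc.haplotype_coverage(truth, b).point == 100.0

    def test_3_of_12(self):
        b = self._bundle_with({"G": [f"*{i}" for i in range(1, 13)]})
        truth = {("S1", "G"): ("*1", "*2"), ("S2", "G"): ("*3", "*3")}
        est = conc.haplotype_coverage(truth, b)
        assert (est.k, est.n) == (3, 12)
        assert est.point == 25.0

    def test_empty_truth_zero(self):
        b = self._bundle_with({"G": ["*1", "*2"]})
        assert conc.haplotype_coverage({}, b).point == 0.0
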