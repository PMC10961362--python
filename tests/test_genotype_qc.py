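"""VCF ingestion, sample/site QC, source merging and allele frequencies."""

import numpy as np
import pytest

from pgxkit import genotype_qc as gq
from pgxkit.model import VariantDef

from conftest import write_vcf_text

GP_FORMAT = ('##FORMAT=<ID=GP,Number=G,Type=Float,'
             'Description="Genotype posterior probabilities">\n')


def _targets(bundle, gene=None):
    return bundle.variants if gene is None else bundle.variants_of(gene)


class TestReadVcf:
    def test_empty_vcf_all_missing(self, mini_bundle, tmp_path):
        p = write_vcf_text(tmp_path / "e.vcf", "", ["S1", "S2"])
        t = gq.read_vcf(p, mini_bundle.variants, gq.SOURCE_GENOTYPED)
        assert np.isnan(t.dosage).all()

    def test_het_dosage_and_source_label(self, mini_bundle, tmp_path):
        p = write_vcf_text(tmp_path / "v.vcf", """
            chr10 1000100 rsA1 G A . PASS . GT 0/1
            """, ["S1"])
        t = gq.read_vcf(p, mini_bundle.variants, gq.SOURCE_IMPUTED)
        v = next(x for x in mini_bundle.variants if x.rsid == "rsA1")
        i, j = t._sidx["S1"], t._tidx[v]
        assert t.dosage[i, j] == 1
        assert t.source[i, j] == gq.SOURCE_IMPUTED

    def test_multiallelic_line_matched_per_alt(self, tmp_path):
        # one VCF line with two alts; genotype 1/2 contributes dosage 1 to each
        targets = [VariantDef("G", "rsM", "chr10", 500, "A", "G"),
                   VariantDef("G", "rsM", "chr10", 500, "A", "T")]
        p = write_vcf_text(tmp_path / "m.vcf", """
            chr10 500 rsM A G,T . PASS . GT 1/2
            """, ["S1"])
        t = gq.read_vcf(p, targets, gq.SOURCE_GENOTYPED)
        assert t.get("S1", targets[0]) == 1
        assert t.get("S1", targets[1]) == 1

    def test_chr_prefix_dialects_interoperate(self, mini_bundle, tmp_path):
        p = write_vcf_text(tmp_path / "v.vcf", """
            10 1000100 rsA1 G A . PASS . GT 1/1
            """, ["S1"])
        # header declares chr10 but the record uses the bare dialect
        t = gq.read_vcf(p, mini_bundle.variants, gq.SOURCE_GENOTYPED)
        v = next(x for x in mini_bundle.variants if x.rsid == "rsA1")
        assert t.get("S1", v) == 2

    def test_missing_genotype_stays_missing(self, mini_bundle, tmp_path):
        p = write_vcf_text(tmp_path / "v.vcf", """
            chr10 1000100 rsA1 G A . PASS . GT ./.
            """, ["S1"])
        t = gq.read_vcf(p, mini_bundle.variants, gq.SOURCE_GENOTYPED)
        v = next(x for x in mini_bundle.variants if x.rsid == "rsA1")
        assert np.isnan(t.get("S1", v))

    def test_gp_vector_max_is_likelihood(self, mini_bundle, tmp_path):
        p = write_vcf_text(tmp_path / "v.vcf", """
            chr10 1000100 rsA1 G A . PASS . GT:GP 0/1:0.05,0.9,0.05
            """, ["S1"], extra_format=GP_FORMAT)
        t = gq.read_vcf(p, mini_bundle.variants, gq.SOURCE_IMPUTED)
        v = next(x for x in mini_bundle.variants if x.rsid == "rsA1")
        assert t.likelihood[t._sidx["S1"], t._tidx[v]] == pytest.approx(0.9)


def _table(samples, targets, rows):
    """rows: {sample: [dosage per target, None = missing]}"""
    t = gq.GenotypeTable(samples, targets)
    for s, ds in rows.items():
        for v, d in zip(targets, ds):
            if d is not None:
                t.set(s, v, float(d))
    return t


@pytest.fixture
def five_targets():
    return [VariantDef("G", f"rs{i}", "chr1", 100 + i, "A", "C") for i in range(5)]


class TestSampleQc:
    def test_call_rate_exactly_at_threshold_fails(self, five_targets):
        # strict "greater than": a rate equal to the threshold is a failure
        targets = [VariantDef("G", f"rs{i}", "chr1", 100 + i, "A", "C")
                   for i in range(100)]
        t = _table(["S1"], targets, {"S1": [0] * 98 + [None, None]})
        res = gq.sample_qc(t, gq.QcThresholds(min_sample_call_rate=0.98))
        assert not res["S1"].passed
        assert res["S1"].reasons == ("call_rate",)

    def test_fully_called_matching_sex_passes(self, five_targets):
        t = _table(["S1"], five_targets, {"S1": [0, 1, 2, 0, 1]})
        t.sample_meta["S1"].reported_sex = "F"
        t.sample_meta["S1"].inferred_sex = "F"
        assert gq.sample_qc(t)["S1"].passed

    def test_97_of_100_fails(self):
        targets = [VariantDef("G", f"rs{i}", "chr1", 100 + i, "A", "C")
                   for i in range(100)]
        t = _table(["S1"], targets, {"S1": [0] * 97 + [None] * 3})
        assert not gq.sample_qc(t)["S1"].passed

    def test_sex_mismatch_fails_but_unknown_never_conflicts(self, five_targets):
        t = _table(["S1", "S2"], five_targets,
                   {"S1": [0] * 5, "S2": [0] * 5})
        t.sample_meta["S1"].reported_sex = "M"
        t.sample_meta["S1"].inferred_sex = "F"
        t.sample_meta["S2"].reported_sex = "M"
        t.sample_meta["S2"].inferred_sex = "unknown"
        res = gq.sample_qc(t)
        assert res["S1"].reasons == ("sex_mismatch",)
        assert res["S2"].passed


class TestSitePrefilter:
    def test_91_percent_missing_removed(self):
        targets = [VariantDef("G", "rs1", "chr1", 100, "A", "C")]
        rows = {f"S{i}": [1 if i < 9 else None] for i in range(100)}
        t = _table(list(rows), targets, rows)
        kept, removed = gq.site_prefilter(t)
        assert kept.targets == []
        assert removed[0].reasons == ("missingness",)

    def test_maf_exactly_at_threshold_kept(self):
        # MAF 0.005 = 1 alt allele in 100 diploid samples: "less than" is strict
        targets = [VariantDef("G", "rs1", "chr1", 100, "A", "C")]
        rows = {f"S{i}": [1 if i == 0 else 0] for i in range(100)}
        t = _table(list(rows), targets, rows)
        kept, removed = gq.site_prefilter(t)
        assert kept.targets == targets and removed == []

    def test_common_fully_called_site_kept(self, five_targets):
        t = _table(["S1", "S2"], five_targets[:1], {"S1": [0], "S2": [2]})
        kept, removed = gq.site_prefilter(t)
        assert kept.targets and not removed

    def test_both_reasons_recorded(self):
        targets = [VariantDef("G", "rs1", "chr1", 100, "A", "C")]
        rows = {f"S{i}": [0 if i == 0 else None] for i in range(100)}
        t = _table(list(rows), targets, rows)
        _, removed = gq.site_prefilter(t)
        assert set(removed[0].reasons) == {"missingness", "maf"}


class TestMergeCalls:
    def _pair(self, five_targets, geno_d, imp_d, imp_lik):
        g = _table(["S1"], five_targets[:1], {"S1": [geno_d]})
        im = _table(["S1"], five_targets[:1], {"S1": [imp_d]})
        if imp_d is not None:
            im.likelihood[0, 0] = imp_lik
            im.source[0, 0] = gq.SOURCE_IMPUTED
        return g, im

    def test_genotyped_wins_over_imputed(self, five_targets):
        g, im = self._pair(five_targets, 2, 1, 0.99)
        merged = gq.merge_calls(g, im)
        assert merged.get("S1", five_targets[0]) == 2
        assert merged.source[0, 0] == gq.SOURCE_GENOTYPED

    @pytest.mark.parametrize("lik,expect_called", [(0.79, False), (0.81, True)])
    def test_imputed_likelihood_strictly_above_080(self, five_targets, lik, expect_called):
        g, im = self._pair(five_targets, None, 1, lik)
        merged = gq.merge_calls(g, im)
        d = merged.get("S1", five_targets[0])
        assert (not np.isnan(d)) == expect_called
        if expect_called:
            assert merged.source[0, 0] == gq.SOURCE_IMPUTED

    def test_only_genotyped_unchanged_and_empty_imputed_is_identity(self, five_targets):
        g = _table(["S1"], five_targets, {"S1": [0, 1, 2, None, 1]})
        empty = gq.GenotypeTable(["S1"], five_targets)
        merged = gq.merge_calls(g, empty)
        assert np.array_equal(merged.dosage, g.dosage, equal_nan=True)

    def test_merge_is_idempotent(self, five_targets):
        g, im = self._pair(five_targets, None, 1, 0.95)
        once = gq.merge_calls(g, im)
        twice = gq.merge_calls(once, im)
        assert np.array_equal(once.dosage, twice.dosage, equal_nan=True)
        assert (once.source == twice.source).all()

    def test_sample_mismatch_raises(self, five_targets):
        g = _table(["S1"], five_targets, {})
        im = _table(["S2"], five_targets, {})
        with pytest.raises(ValueError, match="sample"):
            gq.merge_calls(g, im)


class TestAlleleFrequencies:
    def test_all_hom_ref_is_zero(self, five_targets):
        t = _table(["S1", "S2"], five_targets[:1], {"S1": [0], "S2": [0]})
        af = gq.allele_frequencies(t)
        assert af[(five_targets[0], "ALL")] == 0.0

    def test_het_hom_ref_mix(self, five_targets):
        t = _table(["S1", "S2", "S3"], five_targets[:1],
                   {"S1": [1], "S2": [2], "S3": [0]})
        af = gq.allele_frequencies(t)
        assert af[(five_targets[0], "ALL")] == pytest.approx(0.5)

    def test_missing_sample_shrinks_denominator(self, five_targets):
        t = _table(["S1", "S2", "S3"], five_targets[:1],
                   {"S1": [1], "S2": [2], "S3": [None]})
        af = gq.allele_frequencies(t)
        assert af[(five_targets[0], "ALL")] == pytest.approx(3 / 4)

    def test_population_with_no_calls_absent(self, five_targets):
        t = _table(["S1", "S2"], five_targets[:1], {"S1": [1], "S2": [None]})
        af = gq.allele_frequencies(t, {"S1": "P1", "S2": "P2"})
        assert (five_targets[0], "P1") in af
        assert (five_targets[0], "P2") not in af

    def test_pooled_equals_weighted_mean_under_equal_missingness(self, five_targets):
        t = _table(["S1", "S2", "S3", "S4"], five_targets[:1],
                   {"S1": [1], "S2": [2], "S3": [0], "S4": [1]})
        af = gq.allele_frequencies(t, {"S1": "P1", "S2": "P1", "S3": "P2", "S4": "P2"})
        v = five_targets[0]
        pooled = af[(v, "ALL")]
        weighted = (2 * af[(v, "P1")] + 2 * af[(v, "P2")]) / 4
        assert pooled == pytest.approx(weighted)


class TestHemizygous:
    def test_diploid_call_at_male_x_locus_collapsed(self, tmp_path):
        from pgxkit.model import GeneDef
        v = VariantDef("GX", "rsX", "chrX", 100, "A", "C")
        genes = {"GX": GeneDef("GX", "chrX", 1, 1000, "*1", "x_linked")}
        t = _table(["S1"], [v], {"S1": [2]})
        t.sample_meta["S1"].inferred_sex = "M"
        with pytest.warns(UserWarning, match="haploid"):
            out = gq.collapse_hemizygous(t, genes)
        assert out.get("S1", v) == 1

    def test_callability_complement_identity(self, five_targets):
        t = _table(["S1"], five_targets, {"S1": [0, None, 1, None, 2]})
        rate = t.call_rate("S1")
        no_call = np.isnan(t.dosage[0]).mean()
        assert rate + no_call == pytest.approx(1.0)
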