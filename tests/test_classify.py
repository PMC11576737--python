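"""The triage decision tree, rule by rule and against a brute-force oracle."""

from __future__ import annotations

import pytest

from sftriage.classify import (
    Thresholds,
    classify_lp1,
    classify_lp2_pvus,
    classify_p,
    classify_variant,
    hgmd_conflict,
    is_novel,
    passes_global_maf,
    reject_benign,
)

from conftest import make_ann, make_entry, make_variant
from _oracles import brute_force_classify

T = Thresholds()


def var_with_maf(maf: float, gene="BRCA2"):
    an = 20000
    return make_variant(gene=gene, ac=round(maf * an), an=an)


class TestGlobalMaf:
    @pytest.mark.parametrize(
        "maf,expected", [(0.019, True), (0.02, False), (0.0, True)]
    )
    def test_strict_two_percent_gate(self, maf, expected):
        assert passes_global_maf(var_with_maf(maf), T) is expected


class TestBenignRejection:
    @pytest.mark.parametrize(
        "sig,expected",
        [("LB", True), ("B", True), ("B/LB", True), ("VUS", False), (None, False)],
    )
    def test_clinvar_benign_values(self, sig, expected):
        assert reject_benign(make_ann(clinvar_significance=sig)) is expected


class TestPathogenicLists:
    def test_clinvar_plus_hgmd_dm_is_p1(self):
        ann = make_ann(clinvar_significance="P", hgmd_class="DM")
        assert classify_p(ann, T) == "P1"

    def test_two_stars_without_hgmd_is_p2(self):
        ann = make_ann(clinvar_significance="LP", clinvar_stars=2)
        assert classify_p(ann, T) == "P2"

    def test_conflicting_hgmd_excluded_from_both(self):
        ann = make_ann(clinvar_significance="P", clinvar_stars=3, hgmd_class="other")
        assert classify_p(ann, T) is None
        assert hgmd_conflict(ann)

    def test_one_star_without_hgmd_is_not_p(self):
        ann = make_ann(clinvar_significance="P", clinvar_stars=1)
        assert classify_p(ann, T) is None


class TestLp1:
    def lof_ann(self, **kw):
        defaults = dict(
            consequence=("stop_gained",), impact="HIGH",
            pvs1_strength="VeryStrong", gnomad_af=0.0002,
        )
        defaults.update(kw)
        return make_ann(**defaults)

    def test_rare_high_impact_lof_passes(self):
        assert classify_lp1(self.lof_ann(), var_with_maf(0.0005), T, True)

    def test_cohort_maf_above_rare_cut_fails(self):
        assert not classify_lp1(self.lof_ann(), var_with_maf(0.005), T, True)

    def test_pvs1_below_very_strong_fails(self):
        ann = self.lof_ann(pvs1_strength="Moderate")
        assert not classify_lp1(ann, var_with_maf(0.0005), T, True)

    def test_gnomad_absent_counts_as_rare(self):
        ann = self.lof_ann(gnomad_af=None)
        assert classify_lp1(ann, var_with_maf(0.0005), T, True)

    def test_non_lof_mechanism_gene_fails(self):
        assert not classify_lp1(self.lof_ann(), var_with_maf(0.0005), T, False)


class TestLp2Pvus:
    def missense_ann(self, **kw):
        defaults = dict(
            clinvar_significance="VUS", revel=0.82, external_verdict="LP",
            gnomad_af=0.0002, dbsnp_id="rs1",
        )
        defaults.update(kw)
        return make_ann(**defaults)

    def args(self, ann, maf=0.0004, carriers=3, category="cardiovascular",
             evidence=True):
        entry = make_entry(category=category)
        return (ann, var_with_maf(maf), carriers, T, entry, evidence)

    def test_plp_verdict_gives_lp2(self):
        assert classify_lp2_pvus(*self.args(self.missense_ann())) == "LP2"

    def test_vus_verdict_gives_pvus(self):
        ann = self.missense_ann(external_verdict="VUS")
        assert classify_lp2_pvus(*self.args(ann)) == "pVUS"

    def test_revel_exactly_at_threshold_fails(self):
        ann = self.missense_ann(revel=0.7)
        assert classify_lp2_pvus(*self.args(ann)) is None

    def test_single_carrier_fails(self):
        assert classify_lp2_pvus(*self.args(self.missense_ann(), carriers=1)) is None

    def test_no_cohort_evidence_fails(self):
        assert classify_lp2_pvus(*self.args(self.missense_ann(), evidence=False)) is None

    def test_miscellaneous_gene_fails(self):
        res = classify_lp2_pvus(*self.args(self.missense_ann(),
                                           category="miscellaneous"))
        assert res is None

    def test_novelty_requires_all_four_sources_absent(self):
        novel = make_ann()
        assert is_novel(novel)
        assert not is_novel(make_ann(dbsnp_id="rs1"))
        assert not is_novel(make_ann(gnomad_af=0.0001))


class TestMasterTree:
    def test_p1_through_master(self):
        ann = make_ann(clinvar_significance="P", hgmd_class="DM")
        res = classify_variant(ann, var_with_maf(0.001), 5, T, make_entry(), False)
        assert res.list == "P1"
        assert "clinvar_plp_and_hgmd_dm" in res.reasons

    def test_benign_precedence_over_everything(self):
        ann = make_ann(
            clinvar_significance="B", hgmd_class="DM", consequence=("stop_gained",),
            impact="HIGH", pvs1_strength="VeryStrong",
        )
        res = classify_variant(ann, var_with_maf(0.0001), 5, T, make_entry(), True)
        assert res.list == "rejected"

    def test_global_maf_rejects_before_any_rule(self):
        ann = make_ann(clinvar_significance="P", hgmd_class="DM")
        res = classify_variant(ann, var_with_maf(0.03), 5, T, make_entry(), False)
        assert res.list == "rejected"
        assert res.reasons == ("global_maf_fail",)

    def test_conflict_is_terminal(self):
        ann = make_ann(
            clinvar_significance="P", clinvar_stars=3, hgmd_class="other",
            consequence=("stop_gained",), impact="HIGH", pvs1_strength="VeryStrong",
        )
        res = classify_variant(ann, var_with_maf(0.0001), 5, T, make_entry(), True)
        assert res.list == "unclassified"
        assert "clinvar_hgmd_conflict" in res.reasons

    def test_reasons_nonempty_for_all_classified(self):
        ann = make_ann(clinvar_significance="VUS")
        res = classify_variant(ann, var_with_maf(0.001), 0, T, make_entry(), False)
        assert res.reasons  # even unclassified keeps its trail

    def test_exhaustive_truth_table_matches_oracle(self):
        """Full cross-product of annotation fields against the flat oracle."""
        significances = ["P", "LP", "P/LP", "VUS", "conflicting", "B", "LB",
                         "B/LB", None]
        hgmds = ["DM", "other", None]
        stars_opts = [0, 2]
        pvs1_opts = ["VeryStrong", "Moderate"]
        consequence_opts = [("stop_gained",), ("missense_variant",)]
        revel_opts = [0.5, 0.8, None]
        verdict_opts = ["LP", "VUS", None]
        maf_opts = [0.0004, 0.004, 0.03]
        carriers_opts = [1, 3]
        entry = make_entry(category="cardiovascular")
        n = 0
        for sig in significances:
            for hgmd in hgmds:
                for stars in stars_opts:
                    for pvs1 in pvs1_opts:
                        for cons in consequence_opts:
                            for revel in revel_opts:
                                for verdict in verdict_opts:
                                    for maf in maf_opts:
                                        for carriers in carriers_opts:
                                            impact = ("HIGH" if cons[0] ==
                                                      "stop_gained" else "MODERATE")
                                            ann = make_ann(
                                                clinvar_significance=sig,
                                                clinvar_stars=(stars if sig else None),
                                                hgmd_class=hgmd,
                                                consequence=cons,
                                                impact=impact,
                                                revel=revel,
                                                pvs1_strength=pvs1,
                                                external_verdict=verdict,
                                                gnomad_af=0.0002,
                                                dbsnp_id="rs1",
                                            )
                                            v = var_with_maf(maf)
                                            got = classify_variant(
                                                ann, v, carriers, T, entry, True
                                            ).list
                                            want = brute_force_classify(
                                                clinvar=sig,
                                                stars=(stars if sig else None),
                                                hgmd=hgmd,
                                                consequences=cons,
                                                impact=impact,
                                                pvs1=pvs1,
                                                revel=revel,
                                                verdict=verdict,
                                                dbsnp="rs1",
                                                cohort_maf=v.cohort_maf,
                                                gnomad_af=0.0002,
                                                carriers=carriers,
                                                gene_category="cardiovascular",
                                                lof_gene=True,
                                                cohort_evidence=True,
                                            )
                                            assert got == want, (
                                                sig, hgmd, stars, pvs1, cons,
                                                revel, verdict, maf, carriers,
                                                got, want,
                                            )
                                            n += 1
        assert n == 9 * 3 * 2 * 2 * 2 * 3 * 3 * 3 * 2

    def test_partition_every_variant_lands_in_exactly_one_list(self):
        import itertools
        counts = {"P1": 0, "P2": 0, "LP1": 0, "LP2": 0, "pVUS": 0,
                  "rejected": 0, "unclassified": 0}
        entry = make_entry(category="cancer")
        combos = itertools.product(
            ["P", "VUS", None], ["DM", None], [0.0004, 0.03], [0.6, 0.9, None]
        )
        total = 0
        for sig, hgmd, maf, revel in combos:
            ann = make_ann(clinvar_significance=sig, hgmd_class=hgmd, revel=revel)
            res = classify_variant(ann, var_with_maf(maf), 2, T, entry, True)
            counts[res.list] += 1
            total += 1
        assert sum(counts.values()) == total


class TestThresholds:
    def test_defaults_match_stated_cutpoints(self):
        assert (T.global_maf_max, T.rare_maf_max, T.revel_min,
                T.min_carriers_lp2, T.min_stars_p2) == (0.02, 0.001, 0.7, 2, 2)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(global_maf_max=0.001, rare_maf_max=0.02)
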