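"""GPP identification, reportability, prevalence and summaries."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy.stats import norm

from sftriage.classify import ClassificationResult
from sftriage.cohort_stats import (
    ParticipantFinding,
    annotate_reportability,
    format_percent,
    identify_gpps,
    multi_variant_carriers,
    prevalence,
    reportable_under_acmg,
    summarize_by_category,
    summarize_by_gene,
)
from sftriage.io_formats import MISSING, GenotypeMatrix

from conftest import make_entry, make_variant


def finding(participant="p1", list_="P1", zygosity="HET", gene="BRCA2",
            inheritance="AD", key_pos=100, **kw):
    return ParticipantFinding(
        participant=participant,
        variant=make_variant(gene=gene, pos=key_pos),
        list=list_,
        zygosity=zygosity,
        gene=gene,
        inheritance=inheritance,
        **kw,
    )


def small_catalog():
    return {
        "BRCA2": make_entry("BRCA2", "AD", "cancer"),
        "ATP7B": make_entry("ATP7B", "AR", "miscellaneous",
                            phenotype="Wilson disease"),
        "LDLR": make_entry("LDLR", "SD", "cardiovascular",
                           phenotype="Familial hypercholesterolemia"),
        "TTN": make_entry("TTN", "AD", "cardiovascular",
                          phenotype="Dilated cardiomyopathy"),
    }


class TestIdentifyGpps:
    def _classified(self, genes_lists):
        return [
            ClassificationResult(make_variant(gene=g, pos=100 + 10 * i), lst,
                                 ("r",) if lst != "unclassified" else ())
            for i, (g, lst) in enumerate(genes_lists)
        ]

    def test_all_zero_dosage_gives_empty(self):
        classified = self._classified([("BRCA2", "P1")])
        gm = GenotypeMatrix(["a", "b"], [classified[0].variant.key],
                            np.zeros((2, 1), dtype=np.int8))
        assert identify_gpps(classified, gm, small_catalog()) == []

    def test_hom_dosage_two(self):
        classified = self._classified([("ATP7B", "P1")])
        gm = GenotypeMatrix(["a"], [classified[0].variant.key],
                            np.array([[2]], dtype=np.int8))
        (f,) = identify_gpps(classified, gm, small_catalog())
        assert f.zygosity == "HOM" and f.inheritance == "AR"

    def test_rejected_and_unclassified_produce_no_findings(self):
        classified = self._classified([("BRCA2", "rejected"),
                                       ("TTN", "unclassified")])
        gm = GenotypeMatrix(
            ["a"], [c.variant.key for c in classified],
            np.array([[1, 1]], dtype=np.int8),
        )
        assert identify_gpps(classified, gm, small_catalog()) == []

    def test_variant_absent_from_matrix_is_an_error(self):
        classified = self._classified([("BRCA2", "P1")])
        gm = GenotypeMatrix(["a"], [], np.zeros((1, 0), dtype=np.int8))
        with pytest.raises(KeyError):
            identify_gpps(classified, gm, small_catalog())

    def test_random_matrix_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        genes = ["BRCA2", "ATP7B", "TTN"]
        classified = self._classified([(g, "P1") for g in genes])
        participants = [f"s{i}" for i in range(5)]
        dosages = rng.choice(
            np.array([0, 1, 2, MISSING], dtype=np.int8), size=(5, 3),
            p=[0.4, 0.3, 0.2, 0.1],
        )
        gm = GenotypeMatrix(participants, [c.variant.key for c in classified],
                            dosages)
        got = {(f.participant, f.variant.key, f.zygosity)
               for f in identify_gpps(classified, gm, small_catalog())}
        want = set()
        for i, p in enumerate(participants):
            for j, c in enumerate(classified):
                if dosages[i, j] >= 1:
                    want.add((p, c.variant.key,
                              "HOM" if dosages[i, j] == 2 else "HET"))
        assert got == want


class TestReportability:
    def test_het_p1_in_dominant_gene_reportable(self):
        assert reportable_under_acmg(finding(inheritance="AD"))

    def test_het_p1_in_recessive_gene_not_reportable(self):
        f = finding(gene="ATP7B", inheritance="AR")
        assert not reportable_under_acmg(f, [f])

    def test_hom_p1_in_recessive_gene_reportable(self):
        f = finding(gene="ATP7B", inheritance="AR", zygosity="HOM")
        assert reportable_under_acmg(f, [f])

    def test_second_distinct_variant_makes_ar_het_reportable(self):
        f1 = finding(gene="ATP7B", inheritance="AR", key_pos=100)
        f2 = finding(gene="ATP7B", inheritance="AR", key_pos=200, list_="LP1")
        assert reportable_under_acmg(f1, [f1, f2])

    def test_pvus_never_reportable(self):
        for inh, zyg in itertools.product(["AD", "SD", "AR", "XL"], ["HET", "HOM"]):
            f = finding(list_="pVUS", inheritance=inh, zygosity=zyg)
            assert not reportable_under_acmg(f, [f, finding(key_pos=999)])

    def test_exhaustive_rule_enumeration(self):
        """list x inheritance x zygosity x second-hit, all combinations."""
        for lst, inh, zyg, second in itertools.product(
            ["P1", "P2", "LP1", "LP2", "pVUS"],
            ["AD", "SD", "AR", "XL"],
            ["HET", "HOM"],
            [False, True],
        ):
            f = finding(list_=lst, inheritance=inh, zygosity=zyg, key_pos=100)
            group = [f] + (
                [finding(list_="P1", inheritance=inh, key_pos=200)] if second else []
            )
            got = reportable_under_acmg(f, group)
            want = lst != "pVUS" and (
                inh in ("AD", "SD", "XL") or zyg == "HOM" or second
            )
            assert got == want, (lst, inh, zyg, second)

    def test_annotate_marks_carrier_only_and_phase(self):
        f1 = finding("p1", gene="ATP7B", inheritance="AR", key_pos=100)
        f2 = finding("p1", gene="ATP7B", inheritance="AR", key_pos=200, list_="LP1")
        f3 = finding("p2", gene="ATP7B", inheritance="AR", key_pos=100)
        out = annotate_reportability([f1, f2, f3])
        assert out[0].reportable and out[0].phase_unknown
        assert out[1].reportable
        assert not out[2].reportable and out[2].carrier_only


class TestPrevalence:
    def test_reportable_rate_from_printed_counts(self):
        est = prevalence(509, 14392)
        assert est.proportion == pytest.approx(0.035367, abs=1e-6)
        assert format_percent(509, 14392) == 3.5

    def test_zero_numerator(self):
        est = prevalence(0, 100)
        assert est.proportion == 0 and est.ci_low == 0

    def test_wald_interval_matches_closed_form(self):
        est = prevalence(509, 14392)
        p = 509 / 14392
        z = norm.ppf(0.975)
        half = z * math.sqrt(p * (1 - p) / 14392)
        assert est.ci_low == pytest.approx(p - half, abs=1e-12)
        assert est.ci_high == pytest.approx(p + half, abs=1e-12)
        # and the frozen closed-form values for the cohort rate near 3.5%
        assert est.ci_low == pytest.approx(0.032346, abs=5e-6)
        assert est.ci_high == pytest.approx(0.038388, abs=5e-6)

    def test_interval_shrinks_with_denominator(self):
        widths = [
            (lambda e: e.ci_high - e.ci_low)(prevalence(int(0.035 * n), n))
            for n in (1000, 10000, 100000)
        ]
        assert widths[0] > widths[1] > widths[2]

    def test_zero_denominator_is_an_error(self):
        with pytest.raises(ValueError):
            prevalence(0, 0)

    def test_wilson_option(self):
        est = prevalence(509, 14392, method="wilson")
        assert est.ci_low < 509 / 14392 < est.ci_high


class TestPercentFormatting:
    @pytest.mark.parametrize(
        "num,den,decimals,mode,expected",
        [
            (509, 14392, 1, "round", 3.5),
            (1036, 14392, 1, "round", 7.2),
            (245, 14392, 1, "round", 1.7),
            (709, 14392, 0, "round", 5.0),
            (200, 14392, 1, "round", 1.4),
            (87, 151, 0, "truncate", 57.0),
            (87, 151, 0, "round", 58.0),
            (218, 508, 0, "round", 43.0),
        ],
    )
    def test_both_conventions(self, num, den, decimals, mode, expected):
        assert format_percent(num, den, decimals, mode) == expected


class TestSummaries:
    def test_single_gene_row(self):
        fs = annotate_reportability([
            finding("p1", key_pos=100), finding("p2", key_pos=100),
            finding("p3", key_pos=200),
        ])
        df = summarize_by_gene(fs, small_catalog())
        row = df.iloc[0]
        assert (row.Gene, row.Variants, row.GPP, row.HET, row.HOMO) == (
            "BRCA2", 2, 3, 3, 0,
        )

    def test_cross_category_participant_counts_once_per_category(self):
        fs = annotate_reportability([
            finding("p1", gene="BRCA2", key_pos=100),
            finding("p1", gene="TTN", inheritance="AD", key_pos=200),
        ])
        df = summarize_by_category(fs, small_catalog()).set_index("Category")
        assert df.loc["cancer", "GPP"] == 1
        assert df.loc["cardiovascular", "GPP"] == 1
        assert len({f.participant for f in fs}) == 1

    def test_random_findings_match_groupby_oracle(self):
        rng = np.random.default_rng(9)
        genes = ["BRCA2", "ATP7B", "LDLR", "TTN"]
        fs = []
        for i in range(60):
            fs.append(
                finding(
                    participant=f"p{rng.integers(0, 12)}",
                    gene=(g := genes[rng.integers(0, 4)]),
                    inheritance=small_catalog()[g].inheritance,
                    zygosity="HOM" if rng.random() < 0.2 else "HET",
                    key_pos=100 + 10 * int(rng.integers(0, 5)),
                )
            )
        fs = annotate_reportability(fs)
        df = summarize_by_gene(fs, small_catalog()).set_index("Gene")
        for gene in {f.gene for f in fs}:
            sub = [f for f in fs if f.gene == gene]
            assert df.loc[gene, "Variants"] == len({f.variant.key for f in sub})
            assert df.loc[gene, "GPP"] == len({f.participant for f in sub})
            hom = {f.participant for f in sub if f.zygosity == "HOM"}
            assert df.loc[gene, "HOMO"] == len(hom)
            assert df.loc[gene, "HET"] == len({f.participant for f in sub} - hom)

    def test_reportable_tallies_reproduce_cohort_scale_pattern(self):
        """Fixture shaped like the published tallies: 509 reportable GPPs
        (508 HET, 1 HOM) and 200 AR carrier-only participants."""
        fs = []
        for i in range(508):
            fs.append(finding(f"r{i}", gene="TTN", inheritance="AD", key_pos=100))
        fs.append(finding("hom", gene="LDLR", list_="P1", inheritance="SD",
                          zygosity="HOM", key_pos=300))
        for i in range(200):
            fs.append(finding(f"c{i}", gene="ATP7B", inheritance="AR", key_pos=400))
        fs = annotate_reportability(fs)
        reportable = [f for f in fs if f.reportable]
        assert len({f.participant for f in reportable}) == 509
        zyg = {f.participant: f.zygosity for f in reportable}
        assert sum(1 for z in zyg.values() if z == "HET") == 508
        assert sum(1 for z in zyg.values() if z == "HOM") == 1
        carrier_only = {f.participant for f in fs if f.carrier_only}
        assert len(carrier_only) == 200
        assert format_percent(len(carrier_only), 14392) == 1.4


class TestMultiVariantCarriers:
    def test_two_reportable_genes_qualify(self):
        fs = annotate_reportability([
            finding("p1", gene="BRCA2", key_pos=100),
            finding("p1", gene="TTN", key_pos=200),
            finding("p2", gene="BRCA2", key_pos=100),
        ])
        (entry,) = multi_variant_carriers(fs)
        assert entry[0] == "p1" and len(entry[1]) == 2

    def test_same_gene_twice_does_not_qualify(self):
        fs = annotate_reportability([
            finding("p1", gene="BRCA2", key_pos=100),
            finding("p1", gene="BRCA2", key_pos=200),
        ])
        assert multi_variant_carriers(fs) == []

    def test_no_reportable_findings_empty(self):
        fs = annotate_reportability([
            finding("p1", list_="pVUS", key_pos=100),
            finding("p1", list_="pVUS", gene="TTN", key_pos=200),
        ])
        assert multi_variant_carriers(fs) == []
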