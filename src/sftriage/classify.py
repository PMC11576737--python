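"""The variant triage decision tree.

Each selected-transcript variant is assigned to exactly one of seven lists:

``P1``
    Reported pathogenic/likely pathogenic in ClinVar *and* disease-causing
    (DM) in HGMD — the two databases concur.
``P2``
    ClinVar P/LP with two or more review gold stars, absent from HGMD.
``LP1``
    Rare (cohort and gnomAD MAF < 0.1%) high-impact loss-of-function
    variant (nonsense, frameshift, splice site, insertion/deletion) with a
    Very Strong PVS1 assessment, in a gene where LOF is an established
    disease mechanism.
``LP2``
    Rare missense variant of uncertain/conflicting/novel status carried by
    more than one participant, REVEL > 0.7, in a cancer or cardiovascular
    gene with cohort disease evidence, and called P/LP by the external
    combinatory verdict.
``pVUS``
    As LP2 but lacking the external P/LP verdict.
``rejected``
    ClinVar benign/likely benign, or cohort MAF >= 2%.
``unclassified``
    Everything else, including variants whose ClinVar and HGMD assessments
    conflict (ClinVar P/LP but HGMD present and not DM) — the conflict
    excludes them from the pathogenic lists without forwarding them to the
    LP/pVUS branches.

All threshold comparisons are strict in the stated direction (< 2%,
< 0.1%, > 0.7, more than one carrier, >= 2 stars).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .io_formats import GeneCatalogEntry, NormalizedVariant
from .transcript_select import TranscriptAnnotation

__all__ = [
    "Thresholds",
    "ClassificationResult",
    "LISTS",
    "LOF_CONSEQUENCES",
    "P_LP_SIGNIFICANCE",
    "BENIGN_SIGNIFICANCE",
    "passes_global_maf",
    "reject_benign",
    "hgmd_conflict",
    "classify_p",
    "classify_lp1",
    "classify_lp2_pvus",
    "classify_variant",
    "is_novel",
    "is_missense",
]

LISTS = ("P1", "P2", "LP1", "LP2", "pVUS", "rejected", "unclassified")

P_LP_SIGNIFICANCE = frozenset({"P", "LP", "P/LP"})
BENIGN_SIGNIFICANCE = frozenset({"B", "LB", "B/LB"})
LP2_ELIGIBLE_SIGNIFICANCE = frozenset({"VUS", "conflicting"})

#: Consequence classes counted as loss of function for the LP1 rule.
LOF_CONSEQUENCES = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "inframe_insertion",
        "inframe_deletion",
    }
)


@dataclass(frozen=True)
class Thresholds:
    """Tunable cut-points of the triage rules.

    global_maf_max
        Cohort minor-allele-frequency gate applied to every variant
        (strict ``<``); default 2%.
    rare_maf_max
        Rarity required of LP1/LP2/pVUS variants in both the cohort and
        gnomAD (strict ``<``); default 0.1%.
    revel_min
        Missense deleteriousness floor (strict ``>``); default 0.7.
    min_carriers_lp2
        Minimum genotype-positive participants for LP2/pVUS ("more than
        one"); default 2.
    min_stars_p2
        Minimum ClinVar review gold stars for P2; default 2.
    """

    global_maf_max: float = 0.02
    rare_maf_max: float = 0.001
    revel_min: float = 0.7
    min_carriers_lp2: int = 2
    min_stars_p2: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.rare_maf_max < self.global_maf_max < 0.5:
            raise ValueError("need 0 < rare_maf_max < global_maf_max < 0.5")
        if not 0 < self.revel_min < 1:
            raise ValueError("need 0 < revel_min < 1")

    @classmethod
    def from_mapping(cls, mapping: Optional[dict]) -> "Thresholds":
        return cls(**(mapping or {}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Thresholds":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "global_maf_max": self.global_maf_max,
            "rare_maf_max": self.rare_maf_max,
            "revel_min": self.revel_min,
            "min_carriers_lp2": self.min_carriers_lp2,
            "min_stars_p2": self.min_stars_p2,
        }


@dataclass(frozen=True)
class ClassificationResult:
    """List assignment for one variant plus the trail of rules that fired."""

    variant: NormalizedVariant
    list: str
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.list not in LISTS:
            raise ValueError(f"unknown list {self.list!r}")
        if self.list != "unclassified" and not self.reasons:
            raise ValueError("reasons required for any classified variant")


# ---------------------------------------------------------------------------
# Individual rules
# ---------------------------------------------------------------------------


def passes_global_maf(variant: NormalizedVariant, t: Thresholds) -> bool:
    """Cohort MAF gate: strict ``cohort_maf < global_maf_max``."""
    return variant.cohort_maf < t.global_maf_max


def reject_benign(ann: TranscriptAnnotation) -> bool:
    """True iff ClinVar calls the variant benign or likely benign."""
    return ann.clinvar_significance in BENIGN_SIGNIFICANCE


def hgmd_conflict(ann: TranscriptAnnotation) -> bool:
    """ClinVar P/LP but HGMD present and not DM: conflicting assessments."""
    return (
        ann.clinvar_significance in P_LP_SIGNIFICANCE
        and ann.hgmd_class is not None
        and ann.hgmd_class != "DM"
    )


def classify_p(ann: TranscriptAnnotation, t: Thresholds) -> str | None:
    """Pathogenic sub-lists: database-concordant (P1) or well-reviewed (P2).

    Variants whose ClinVar and HGMD assessments conflict are excluded from
    both sub-lists (the caller treats the conflict as terminal).
    """
    if ann.clinvar_significance not in P_LP_SIGNIFICANCE:
        return None
    if ann.hgmd_class == "DM":
        return "P1"
    if ann.hgmd_class is not None:
        return None  # conflicting databases: excluded from P entirely
    if ann.clinvar_stars is not None and ann.clinvar_stars >= t.min_stars_p2:
        return "P2"
    return None


def _rare_everywhere(ann: TranscriptAnnotation, variant: NormalizedVariant, t: Thresholds) -> bool:
    # a variant unseen in gnomAD is rare there
    if variant.cohort_maf >= t.rare_maf_max:
        return False
    return ann.gnomad_af is None or ann.gnomad_af < t.rare_maf_max


def classify_lp1(
    ann: TranscriptAnnotation,
    variant: NormalizedVariant,
    t: Thresholds,
    lof_gene: bool,
) -> bool:
    """Rare high-impact LOF variant with Very Strong PVS1 in a LOF gene."""
    return (
        any(c in LOF_CONSEQUENCES for c in ann.consequence)
        and ann.pvs1_strength == "VeryStrong"
        and ann.impact == "HIGH"
        and _rare_everywhere(ann, variant, t)
        and lof_gene
    )


def is_missense(ann: TranscriptAnnotation) -> bool:
    return "missense_variant" in ann.consequence


def is_novel(ann: TranscriptAnnotation) -> bool:
    """Absent from dbSNP, gnomAD, ClinVar and HGMD."""
    return (
        ann.clinvar_significance is None
        and ann.hgmd_class is None
        and ann.gnomad_af is None
        and ann.dbsnp_id is None
    )


def lp2_status_eligible(ann: TranscriptAnnotation) -> bool:
    """ClinVar VUS/conflicting, or novel across all four sources."""
    return ann.clinvar_significance in LP2_ELIGIBLE_SIGNIFICANCE or is_novel(ann)


def classify_lp2_pvus(
    ann: TranscriptAnnotation,
    variant: NormalizedVariant,
    carriers: int,
    t: Thresholds,
    gene_entry: GeneCatalogEntry,
    cohort_evidence: bool,
) -> str | None:
    """Rare multi-carrier deleterious missense with cohort disease evidence.

    Returns ``"LP2"`` when the external combinatory verdict is P/LP,
    ``"pVUS"`` when the verdict is anything else (or absent), and ``None``
    when any shared requirement fails.
    """
    if not (
        _rare_everywhere(ann, variant, t)
        and carriers >= t.min_carriers_lp2
        and ann.revel is not None
        and ann.revel > t.revel_min
        and gene_entry.category in {"cancer", "cardiovascular"}
        and cohort_evidence
    ):
        return None
    return "LP2" if ann.external_verdict in {"P", "LP"} else "pVUS"


# ---------------------------------------------------------------------------
# Master decision tree
# ---------------------------------------------------------------------------


def classify_variant(
    ann: TranscriptAnnotation,
    variant: NormalizedVariant,
    carriers: int,
    t: Thresholds,
    gene_entry: GeneCatalogEntry,
    cohort_evidence: bool,
    lof_gene: bool | None = None,
) -> ClassificationResult:
    """Run the full decision tree for one selected-transcript variant.

    Precedence: global MAF gate, benign rejection, conflict exclusion,
    P1/P2, LP1, LP2/pVUS, unclassified.  Every rule that fires is recorded
    in the reason trail.
    """
    if lof_gene is None:
        lof_gene = gene_entry.lof_gene
    reasons: list[str] = []

    if not passes_global_maf(variant, t):
        return ClassificationResult(variant, "rejected", ("global_maf_fail",))
    reasons.append("global_maf_pass")

    if reject_benign(ann):
        return ClassificationResult(
            variant, "rejected", tuple(reasons + ["clinvar_benign"])
        )

    if hgmd_conflict(ann):
        return ClassificationResult(
            variant, "unclassified", tuple(reasons + ["clinvar_hgmd_conflict"])
        )

    p = classify_p(ann, t)
    if p == "P1":
        return ClassificationResult(
            variant, "P1", tuple(reasons + ["clinvar_plp_and_hgmd_dm"])
        )
    if p == "P2":
        return ClassificationResult(
            variant, "P2", tuple(reasons + ["clinvar_plp_ge_2_stars"])
        )

    if classify_lp1(ann, variant, t, lof_gene):
        return ClassificationResult(
            variant, "LP1", tuple(reasons + ["rare_high_impact_lof_pvs1"])
        )

    if is_missense(ann) and lp2_status_eligible(ann):
        sub = classify_lp2_pvus(ann, variant, carriers, t, gene_entry, cohort_evidence)
        if sub == "LP2":
            return ClassificationResult(
                variant, "LP2", tuple(reasons + ["rare_missense_evidence_plp_verdict"])
            )
        if sub == "pVUS":
            return ClassificationResult(
                variant,
                "pVUS",
                tuple(reasons + ["rare_missense_evidence_no_plp_verdict"]),
            )

    return ClassificationResult(
        variant, "unclassified", tuple(reasons + ["no_rule_matched"])
    )
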