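"""Genotype-positive participants, reportability and cohort summaries.

A genotype-positive participant (GPP) carries at least one allele of a
classified variant.  Reportability follows the secondary-findings policy:
P/LP variants are reportable for dominant (AD/SD, and X-linked) conditions,
while recessive (AR) conditions require biallelic involvement — either a
homozygote or two distinct P/LP variants in the same gene (treated as
biallelic without phase, flagged ``phase_unknown``).  Heterozygous
single-variant AR carriers are flagged ``carrier_only``: not reportable,
but relevant for counselling in consanguineous cohorts.  pVUS findings are
never reportable.

Prevalence estimates use the one-proportion normal-approximation (Wald)
interval by default, with the Wilson interval behind a switch.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, replace
from decimal import ROUND_FLOOR, ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import norm

from .classify import ClassificationResult
from .io_formats import GeneCatalogEntry, GenotypeMatrix, NormalizedVariant

__all__ = [
    "ParticipantFinding",
    "PrevalenceEstimate",
    "REPORTABLE_LISTS",
    "GPP_LISTS",
    "identify_gpps",
    "reportable_under_acmg",
    "annotate_reportability",
    "prevalence",
    "summarize_by_gene",
    "summarize_by_category",
    "multi_variant_carriers",
    "format_percent",
]

#: Lists whose carriers count as genotype-positive participants.
GPP_LISTS = frozenset({"P1", "P2", "LP1", "LP2", "pVUS"})

#: Lists eligible for reporting (pVUS never is).
REPORTABLE_LISTS = frozenset({"P1", "P2", "LP1", "LP2"})

#: Inheritance modes where a single heterozygous P/LP variant is reportable.
_DOMINANT_LIKE = frozenset({"AD", "SD", "XL"})


@dataclass(frozen=True)
class ParticipantFinding:
    """One (participant, variant) genotype-positive observation."""

    participant: str
    variant: NormalizedVariant
    list: str
    zygosity: str  # HET | HOM
    gene: str
    inheritance: str
    reportable: bool = False
    carrier_only: bool = False
    phase_unknown: bool = False

    def __post_init__(self) -> None:
        if self.zygosity not in {"HET", "HOM"}:
            raise ValueError(f"zygosity must be HET or HOM, got {self.zygosity!r}")
        if self.reportable and self.list not in REPORTABLE_LISTS:
            raise ValueError(f"list {self.list} can never be reportable")


@dataclass(frozen=True)
class PrevalenceEstimate:
    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95


def identify_gpps(
    classified: Iterable[ClassificationResult],
    gm: GenotypeMatrix,
    catalog: Mapping[str, GeneCatalogEntry],
) -> list[ParticipantFinding]:
    """One finding per (participant, variant) with dosage >= 1.

    Only variants assigned to the P/LP/pVUS lists produce findings.  Raises
    ``KeyError`` when a classified variant has no genotype column.
    """
    findings: list[ParticipantFinding] = []
    for res in classified:
        if res.list not in GPP_LISTS:
            continue
        col = gm.column(res.variant.key)  # KeyError if absent
        entry = catalog[res.variant.gene]
        for participant, dosage in zip(gm.participants, col):
            if dosage >= 1:
                findings.append(
                    ParticipantFinding(
                        participant=participant,
                        variant=res.variant,
                        list=res.list,
                        zygosity="HOM" if dosage == 2 else "HET",
                        gene=res.variant.gene,
                        inheritance=entry.inheritance,
                    )
                )
    return findings


def reportable_under_acmg(
    finding: ParticipantFinding,
    all_findings_for_participant_gene: Sequence[ParticipantFinding] = (),
) -> bool:
    """Inheritance-aware reportability of a single finding.

    ``all_findings_for_participant_gene`` is the participant's findings in
    the same gene (used for the AR second-hit rule); the finding itself may
    or may not be included in the sequence.
    """
    if finding.list not in REPORTABLE_LISTS:
        return False
    if finding.inheritance in _DOMINANT_LIKE:
        return True
    if finding.inheritance == "AR":
        if finding.zygosity == "HOM":
            return True
        second_hits = [
            f
            for f in all_findings_for_participant_gene
            if f.list in REPORTABLE_LISTS and f.variant.key != finding.variant.key
        ]
        return bool(second_hits)
    return False


def annotate_reportability(
    findings: Sequence[ParticipantFinding],
) -> list[ParticipantFinding]:
    """Return findings with reportable / carrier_only / phase_unknown set."""
    by_pg: dict[tuple[str, str], list[ParticipantFinding]] = defaultdict(list)
    for f in findings:
        by_pg[(f.participant, f.gene)].append(f)
    out: list[ParticipantFinding] = []
    for f in findings:
        group = by_pg[(f.participant, f.gene)]
        rep = reportable_under_acmg(f, group)
        carrier_only = (
            f.list in REPORTABLE_LISTS
            and f.inheritance == "AR"
            and f.zygosity == "HET"
            and not rep
        )
        # compound heterozygote without phase information
        phase_unknown = (
            rep
            and f.inheritance == "AR"
            and f.zygosity == "HET"
        )
        out.append(
            replace(
                f,
                reportable=rep,
                carrier_only=carrier_only,
                phase_unknown=phase_unknown,
            )
        )
    return out


def prevalence(
    numerator: int,
    denominator: int,
    confidence: float = 0.95,
    method: str = "wald",
) -> PrevalenceEstimate:
    """One-proportion estimate with a normal-approximation interval.

    ``method="wald"`` gives the estimate +/- z * SE interval of the
    one-proportion Z-test, clamped to [0, 1]; ``method="wilson"`` gives the
    score interval instead.
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("need 0 <= numerator <= denominator")
    p = numerator / denominator
    if method == "wald":
        z = norm.ppf(1 - (1 - confidence) / 2)
        half = z * math.sqrt(p * (1 - p) / denominator)
        low, high = p - half, p + half
    elif method == "wilson":
        from statsmodels.stats.proportion import proportion_confint

        low, high = proportion_confint(
            numerator, denominator, alpha=1 - confidence, method="wilson"
        )
    else:
        raise ValueError(f"unknown interval method {method!r}")
    return PrevalenceEstimate(
        numerator=numerator,
        denominator=denominator,
        proportion=p,
        ci_low=max(0.0, float(low)),
        ci_high=min(1.0, float(high)),
        confidence=confidence,
    )


def format_percent(
    numerator: float, denominator: float, decimals: int = 1, mode: str = "round"
) -> float:
    """Percentage formatting with an explicit convention.

    ``mode="round"`` applies round-half-up at ``decimals`` places;
    ``mode="truncate"`` floors instead.  Both conventions are exposed
    because printed summary percentages in the literature mix the two.
    """
    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    pct = Decimal(numerator) / Decimal(denominator) * 100
    quantum = Decimal(1).scaleb(-decimals)
    rounding = ROUND_HALF_UP if mode == "round" else ROUND_FLOOR
    if mode not in {"round", "truncate"}:
        raise ValueError(f"unknown percent mode {mode!r}")
    return float(pct.quantize(quantum, rounding=rounding))


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def _zygosity_by_participant(
    findings: Iterable[ParticipantFinding],
) -> dict[str, str]:
    """Participant-level zygosity: HOM when any finding is homozygous."""
    zyg: dict[str, str] = {}
    for f in findings:
        if f.zygosity == "HOM":
            zyg[f.participant] = "HOM"
        else:
            zyg.setdefault(f.participant, "HET")
    return zyg


def summarize_by_gene(
    findings: Sequence[ParticipantFinding],
    catalog: Mapping[str, GeneCatalogEntry],
) -> pd.DataFrame:
    """Per-gene tallies: distinct variants, GPPs and the HET/HOM split.

    Column layout mirrors a standard actionable-findings summary: Gene,
    Inheritance, Variants, GPP, HET, HOMO, Phenotype.  A participant with
    any homozygous finding in the gene counts as HOM for that gene.
    """
    rows = []
    by_gene: dict[str, list[ParticipantFinding]] = defaultdict(list)
    for f in findings:
        by_gene[f.gene].append(f)
    for gene in sorted(by_gene):
        fs = by_gene[gene]
        zyg = _zygosity_by_participant(fs)
        rows.append(
            {
                "Gene": gene,
                "Inheritance": catalog[gene].inheritance,
                "Category": catalog[gene].category,
                "Variants": len({f.variant.key for f in fs}),
                "GPP": len(zyg),
                "HET": sum(1 for z in zyg.values() if z == "HET"),
                "HOMO": sum(1 for z in zyg.values() if z == "HOM"),
                "Phenotype": catalog[gene].phenotype,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "Gene",
            "Inheritance",
            "Category",
            "Variants",
            "GPP",
            "HET",
            "HOMO",
            "Phenotype",
        ],
    )


def summarize_by_category(
    findings: Sequence[ParticipantFinding],
    catalog: Mapping[str, GeneCatalogEntry],
) -> pd.DataFrame:
    """Per-category distinct-variant/GPP counts and reportable shares.

    A participant carrying variants in two categories counts once per
    category; overall distinct-participant counts are computed by the
    caller from the findings directly.
    """
    rows = []
    cats = sorted({e.category for e in catalog.values()})
    reportable = [f for f in findings if f.reportable]
    total_rep_gpp = len({f.participant for f in reportable})
    total_rep_var = len({f.variant.key for f in reportable})
    for cat in cats:
        fs = [f for f in findings if catalog[f.gene].category == cat]
        rep = [f for f in fs if f.reportable]
        rows.append(
            {
                "Category": cat,
                "Variants": len({f.variant.key for f in fs}),
                "GPP": len({f.participant for f in fs}),
                "ReportableVariants": len({f.variant.key for f in rep}),
                "ReportableGPP": len({f.participant for f in rep}),
                "ReportableVariantSharePct": (
                    format_percent(len({f.variant.key for f in rep}), total_rep_var)
                    if total_rep_var
                    else 0.0
                ),
                "ReportableGPPSharePct": (
                    format_percent(len({f.participant for f in rep}), total_rep_gpp)
                    if total_rep_gpp
                    else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)


def multi_variant_carriers(
    findings: Sequence[ParticipantFinding],
) -> list[tuple[str, list[ParticipantFinding]]]:
    """Participants with reportable findings in two or more distinct genes.

    Returns ``(participant, findings)`` pairs sorted by participant; only
    reportable findings qualify and are listed.
    """
    by_participant: dict[str, list[ParticipantFinding]] = defaultdict(list)
    for f in findings:
        if f.reportable:
            by_participant[f.participant].append(f)
    out = []
    for participant in sorted(by_participant):
        fs = by_participant[participant]
        if len({f.gene for f in fs}) >= 2:
            out.append((participant, sorted(fs, key=lambda f: (f.gene, f.variant.key))))
    return out
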