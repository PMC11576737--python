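"""Disease-evidence flags, candidate selection and carrier-phenotype tests.

Evidence is derived per participant from questionnaire/biochemistry
components:

* cardiovascular (CVD): abnormal ECG, self-reported heart disease, heart
  revascularization, or parents'/siblings' history of heart disease;
* cancer: personal or parental cancer history, tumor-related surgery, or
  cancer screening performed below the sex-specific recommended age;
* familial hypercholesterolemia (FH): a hypercholesterolemia diagnosis or
  an LDL measurement at/above a configurable threshold (default 4.9
  mmol/L).

Candidate variants for phenotype review need at least two evidenced
carriers for cardiovascular genes, or at least one for cancer genes.
Association is tested with the two-sided Fisher exact test on the 2x2
carrier x evidence table; the odds ratio and its confidence interval come
from the conditional maximum-likelihood estimator (matching the exact-test
convention of standard statistical environments), with the sample odds
ratio available as an option.  No multiple-testing correction alters the
significance tier; a Benjamini-Hochberg column is emitted alongside for
transparency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .io_formats import GeneCatalogEntry

__all__ = [
    "ParticipantPhenotype",
    "AssociationResult",
    "load_phenotype_table",
    "derive_cvd_evidence",
    "derive_cancer_evidence",
    "derive_fh_evidence",
    "evidence_flags",
    "gene_evidence_type",
    "select_candidates",
    "fisher_association",
    "significance_stars",
    "DEFAULT_LDL_THRESHOLD",
]

#: LDL cut-point (mmol/L) marking laboratory FH evidence; inclusive.
DEFAULT_LDL_THRESHOLD = 4.9

EVIDENCE_TYPES = ("CVD", "cancer", "FH")

PHENOTYPE_COLUMNS = (
    "participant",
    "ecg_abnormal",
    "self_heart_disease",
    "revascularization",
    "family_heart_disease",
    "self_cancer",
    "parent_cancer",
    "tumor_surgery",
    "early_screening",
    "total_chol",
    "hdl",
    "ldl",
    "hypercholesterolemia_dx",
    "age",
    "sex",
)


@dataclass(frozen=True)
class ParticipantPhenotype:
    """Questionnaire and laboratory phenotype flags for one participant."""

    participant: str
    ecg_abnormal: bool = False
    self_heart_disease: bool = False
    revascularization: bool = False
    family_heart_disease: bool = False
    self_cancer: bool = False
    parent_cancer: bool = False
    tumor_surgery: bool = False
    early_screening: bool = False
    total_chol: float | None = None
    hdl: float | None = None
    ldl: float | None = None
    hypercholesterolemia_dx: bool = False
    age: int = 0
    sex: str = "F"

    def __post_init__(self) -> None:
        for name in ("total_chol", "hdl", "ldl"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive when present")
        if self.sex not in {"F", "M"}:
            raise ValueError(f"sex must be F or M, got {self.sex!r}")


@dataclass(frozen=True)
class AssociationResult:
    """Fisher exact result for one candidate variant.

    ``table`` is ``(a, b, c, d)`` = (carriers with evidence, carriers
    without, non-carriers with, non-carriers without).  ``testable`` is
    false when a margin of the table is zero, in which case no p-value is
    reported rather than a silent ``p = 1``.
    """

    variant_key: str
    evidence_type: str
    table: tuple[int, int, int, int]
    p_value: float | None
    odds_ratio: float | None
    ci_low: float | None
    ci_high: float | None
    stars: str
    testable: bool = True
    note: str = ""


# ---------------------------------------------------------------------------
# Phenotype table and evidence derivation
# ---------------------------------------------------------------------------


def _cell_bool(cell: object) -> bool:
    return str(cell).strip().lower() in {"1", "true", "yes", "t"}


def load_phenotype_table(path: str | Path) -> dict[str, ParticipantPhenotype]:
    """Load the participant phenotype TSV into a mapping by identifier."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    out: dict[str, ParticipantPhenotype] = {}
    for row in df.itertuples(index=False):
        if row.participant in out:
            raise ValueError(f"duplicate participant {row.participant}")
        out[row.participant] = ParticipantPhenotype(
            participant=row.participant,
            ecg_abnormal=_cell_bool(row.ecg_abnormal),
            self_heart_disease=_cell_bool(row.self_heart_disease),
            revascularization=_cell_bool(row.revascularization),
            family_heart_disease=_cell_bool(row.family_heart_disease),
            self_cancer=_cell_bool(row.self_cancer),
            parent_cancer=_cell_bool(row.parent_cancer),
            tumor_surgery=_cell_bool(row.tumor_surgery),
            early_screening=_cell_bool(row.early_screening),
            total_chol=float(row.total_chol) if row.total_chol.strip() else None,
            hdl=float(row.hdl) if row.hdl.strip() else None,
            ldl=float(row.ldl) if row.ldl.strip() else None,
            hypercholesterolemia_dx=_cell_bool(row.hypercholesterolemia_dx),
            age=int(row.age),
            sex=row.sex,
        )
    return out


def derive_cvd_evidence(p: ParticipantPhenotype) -> bool:
    """Any cardiovascular component: ECG, self report, revascularization,
    or first-degree family history."""
    return (
        p.ecg_abnormal
        or p.self_heart_disease
        or p.revascularization
        or p.family_heart_disease
    )


def derive_cancer_evidence(p: ParticipantPhenotype) -> bool:
    """Personal/parental cancer history, tumor surgery, or early screening."""
    return p.self_cancer or p.parent_cancer or p.tumor_surgery or p.early_screening


def derive_fh_evidence(
    p: ParticipantPhenotype, ldl_threshold: float = DEFAULT_LDL_THRESHOLD
) -> bool:
    """Hypercholesterolemia diagnosis or LDL at/above the threshold."""
    return p.hypercholesterolemia_dx or (p.ldl is not None and p.ldl >= ldl_threshold)


def evidence_flags(
    p: ParticipantPhenotype, ldl_threshold: float = DEFAULT_LDL_THRESHOLD
) -> dict[str, bool]:
    return {
        "CVD": derive_cvd_evidence(p),
        "cancer": derive_cancer_evidence(p),
        "FH": derive_fh_evidence(p, ldl_threshold),
    }


def gene_evidence_type(entry: GeneCatalogEntry) -> str | None:
    """Evidence stream a gene's carriers are reviewed against.

    Cancer genes map to cancer evidence; familial-hypercholesterolemia
    genes map to the FH (lipid) stream; other cardiovascular genes to CVD.
    Miscellaneous genes have no phenotype stream in this dataset.
    """
    if entry.category == "cancer":
        return "cancer"
    if entry.category == "cardiovascular":
        if "hypercholesterolemia" in entry.phenotype.lower():
            return "FH"
        return "CVD"
    return None


def select_candidates(
    findings: Sequence,
    phenotypes: Mapping[str, ParticipantPhenotype],
    catalog: Mapping[str, GeneCatalogEntry],
    ldl_threshold: float = DEFAULT_LDL_THRESHOLD,
    min_cvd_carriers: int = 2,
    min_cancer_carriers: int = 1,
) -> dict[str, str]:
    """Variants warranting phenotype review, keyed by variant.

    A cardiovascular-gene variant qualifies with at least
    ``min_cvd_carriers`` carriers showing CVD *or* FH evidence; a
    cancer-gene variant with at least ``min_cancer_carriers`` carriers
    showing cancer evidence (the stricter "evidenced carriers" reading).
    Returns ``variant_key -> evidence_type`` for qualifying variants.

    ``findings`` may be any objects exposing ``participant``, ``gene`` and
    ``variant`` (with a ``key``) attributes.
    """
    carriers: dict[str, set[str]] = {}
    genes: dict[str, str] = {}
    for f in findings:
        carriers.setdefault(f.variant.key, set()).add(f.participant)
        genes[f.variant.key] = f.gene
    out: dict[str, str] = {}
    for key, people in carriers.items():
        entry = catalog[genes[key]]
        etype = gene_evidence_type(entry)
        if etype is None:
            continue
        evidenced = 0
        for person in people:
            pheno = phenotypes.get(person)
            if pheno is None:
                continue
            flags = evidence_flags(pheno, ldl_threshold)
            if etype == "cancer":
                ok = flags["cancer"]
            else:  # cardiovascular gene: CVD or lipid evidence qualifies
                ok = flags["CVD"] or flags["FH"]
            evidenced += ok
        needed = min_cancer_carriers if etype == "cancer" else min_cvd_carriers
        if evidenced >= needed:
            out[key] = etype
    return out


# ---------------------------------------------------------------------------
# Fisher exact association
# ---------------------------------------------------------------------------


def fisher_association(
    carriers_with: int,
    carriers_without: int,
    noncarriers_with: int,
    noncarriers_without: int,
    confidence: float = 0.95,
    estimator: str = "cmle",
    variant_key: str = "",
    evidence_type: str = "",
) -> AssociationResult:
    """Two-sided Fisher exact test on a 2x2 carrier x evidence table.

    The odds ratio is the conditional maximum-likelihood estimate with its
    conditional-likelihood confidence interval (``estimator="cmle"``), or
    the sample (cross-product) estimate with a Woolf log interval
    (``estimator="sample"``).  Tables with a zero cell yield a finite bound
    on one side only and are flagged in ``note``; tables with a zero row or
    column margin are untestable and returned as such.
    """
    a, b, c, d = (int(carriers_with), int(carriers_without), int(noncarriers_with), int(noncarriers_without))
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    table = (a, b, c, d)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return AssociationResult(
            variant_key=variant_key,
            evidence_type=evidence_type,
            table=table,
            p_value=None,
            odds_ratio=None,
            ci_low=None,
            ci_high=None,
            stars="ns",
            testable=False,
            note="zero margin: association untestable",
        )
    contingency = [[a, b], [c, d]]
    p = float(fisher_exact(contingency, alternative="two-sided").pvalue)
    note = ""
    if estimator == "cmle":
        res = _odds_ratio(contingency, kind="conditional")
        or_hat = float(res.statistic)
        ci = res.confidence_interval(confidence_level=confidence)
        ci_low, ci_high = float(ci.low), float(ci.high)
    elif estimator == "sample":
        or_hat = math.inf if b * c == 0 else (a * d) / (b * c)
        if min(a, b, c, d) == 0:
            ci_low, ci_high = (0.0, math.inf)
        else:
            from scipy.stats import norm

            z = norm.ppf(1 - (1 - confidence) / 2)
            se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            ci_low = math.exp(math.log(or_hat) - z * se)
            ci_high = math.exp(math.log(or_hat) + z * se)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if min(a, b, c, d) == 0:
        note = "zero cell: one-sided confidence bound only"
    return AssociationResult(
        variant_key=variant_key,
        evidence_type=evidence_type,
        table=table,
        p_value=p,
        odds_ratio=or_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        stars=significance_stars(p),
        testable=True,
        note=note,
    )


def significance_stars(p: float) -> str:
    """Star tier for a p-value; strict at each cut-point."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value out of [0, 1]: {p}")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
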