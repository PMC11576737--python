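"""Self-consistent synthetic fixture cohorts.

Real population-cohort genotype/phenotype data of the kind this pipeline
targets is access-restricted, so every other module is exercised on
generated cohorts with the same statistical structure:

* genotypes drawn per variant under Hardy-Weinberg with a cohort-wide
  inbreeding coefficient ``F`` (hom-alt ``q^2 + Fq(1-q)``, het
  ``2q(1-q)(1-F)``), reflecting the elevated homozygosity of a highly
  consanguineous population;
* an annotation table whose rows are constructed from per-class recipes so
  the deterministic triage rules must recover each variant's planted truth
  label, plus adversarial near-miss variants that differ from a passing
  recipe in exactly one field;
* phenotype flags whose composite evidence rate is ``p0`` for non-carriers
  and ``OR * p0/(1-p0) / (1 + OR * p0/(1-p0))`` for carriers of a variant
  with a planted odds ratio.

Variant classes whose definition depends on exact carrier counts (the rare
missense lists need >1 carrier *and* MAF < 0.1%) are planted with fixed
carrier counts so the truth label is deterministic; carriers of those
variants get their disease-evidence flag set deterministically as well.
Everything is reproducible: the same config and seed give a byte-identical
fixture bundle.

Genotypes are independent across variants (no linkage disequilibrium) and
the inbreeding coefficient is a single cohort-wide scalar rather than a
pedigree model; both simplifications are sufficient for the zygosity and
recessive-reportability logic the pipeline exercises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .io_formats import (
    MISSING,
    GeneCatalogEntry,
    GenotypeMatrix,
    NormalizedVariant,
    builtin_catalog,
)

__all__ = [
    "VariantSpec",
    "SimulationConfig",
    "PlantedVariant",
    "TRUTH_CLASSES",
    "expected_list_for_truth",
    "build_reference",
    "simulate_genotypes",
    "emit_annotations",
    "simulate_phenotypes",
    "write_fixture_bundle",
    "demo_config",
    "full_cohort_config",
    "association_replicate",
]

TRUTH_CLASSES = (
    "P1",
    "P2",
    "LP1",
    "LP2",
    "pVUS",
    "benign",
    "common",
    "unclassified",
)

_EXPECTED = {
    "P1": "P1",
    "P2": "P2",
    "LP1": "LP1",
    "LP2": "LP2",
    "pVUS": "pVUS",
    "benign": "rejected",
    "common": "rejected",
    "unclassified": "unclassified",
}


def expected_list_for_truth(truth: str) -> str:
    """Pipeline list a planted truth class must land in."""
    return _EXPECTED[truth]


@dataclass(frozen=True)
class VariantSpec:
    """Recipe for one planted variant.

    Either ``n_het``/``n_hom`` fix carrier counts exactly (used for classes
    whose label depends on counts), or ``allele_frequency`` drives a
    Hardy-Weinberg-with-inbreeding draw.  ``near_miss`` names a recipe
    perturbation for adversarial truth-``unclassified`` variants.
    """

    gene: str
    truth_list: str
    allele_frequency: float = 0.0
    n_het: int | None = None
    n_hom: int = 0
    kind: str = "snv"  # snv | del | ins
    planted_or: float | None = None
    evidence_type: str | None = None  # CVD | cancer | FH
    forced_evidence: bool | None = None
    near_miss: str | None = None
    share_carrier_with: int | None = None  # index of an earlier spec
    same_site_as: int | None = None  # merge into one multi-allelic VCF line
    denormalized: str | None = None  # None | "pad" | "rightshift"

    def __post_init__(self) -> None:
        if self.truth_list not in TRUTH_CLASSES:
            raise ValueError(f"unknown truth class {self.truth_list!r}")
        if self.n_het is None and not 0 < self.allele_frequency <= 0.5:
            raise ValueError("allele_frequency must be in (0, 0.5]")
        if self.kind not in {"snv", "del", "ins"}:
            raise ValueError(f"unknown variant kind {self.kind!r}")


@dataclass
class SimulationConfig:
    n_participants: int
    seed: int
    variant_specs: list[VariantSpec]
    inbreeding_f: float = 0.0375
    phenotype_baseline: dict = field(
        default_factory=lambda: {"CVD": 0.08, "cancer": 0.05, "FH": 0.06}
    )
    ldl_threshold: float = 4.9
    screening_age: dict = field(default_factory=lambda: {"F": 40, "M": 50})
    include_decoys: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.inbreeding_f < 1:
            raise ValueError("inbreeding_f must be in [0, 1)")


@dataclass
class PlantedVariant:
    """A realized planted variant with its carriers and truth label."""

    index: int
    spec: VariantSpec
    chrom: str
    pos: int  # normalized, 1-based
    ref: str
    alt: str
    vcf_pos: int
    vcf_ref: str
    vcf_alt: str
    het_carriers: list[str]
    hom_carriers: list[str]

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def expected_list(self) -> str:
        return expected_list_for_truth(self.spec.truth_list)

    @property
    def carriers(self) -> list[str]:
        return self.het_carriers + self.hom_carriers


# ---------------------------------------------------------------------------
# Reference genome and variant placement
# ---------------------------------------------------------------------------

_GENE_LENGTH = 2000
_GENE_SPACING = 500
_CHROM = "chr1"


def gene_intervals(
    catalog: Mapping[str, GeneCatalogEntry],
) -> dict[str, tuple[str, int, int]]:
    """Deterministic 1-based closed intervals tiling genes along one contig."""
    out = {}
    start = _GENE_SPACING + 1
    for symbol in catalog:
        out[symbol] = (_CHROM, start, start + _GENE_LENGTH - 1)
        start += _GENE_LENGTH + _GENE_SPACING
    return out


def _allocate_positions(
    cfg: SimulationConfig, intervals: Mapping[str, tuple[str, int, int]]
) -> list[int]:
    """Stable per-spec positions inside each gene, honoring shared sites."""
    per_gene_slot: dict[str, int] = {}
    positions: list[int] = []
    for i, spec in enumerate(cfg.variant_specs):
        if spec.same_site_as is not None:
            positions.append(positions[spec.same_site_as])
            continue
        slot = per_gene_slot.get(spec.gene, 0)
        per_gene_slot[spec.gene] = slot + 1
        _, start, end = intervals[spec.gene]
        pos = start + 100 + 80 * slot
        if pos + 20 > end:
            raise ValueError(f"too many variants planted in {spec.gene}")
        positions.append(pos)
    return positions


def build_reference(
    cfg: SimulationConfig, catalog: Mapping[str, GeneCatalogEntry] | None = None
) -> tuple[dict[str, str], dict[str, tuple[str, int, int]]]:
    """Random reference sequence with repeat runs planted for indel specs."""
    catalog = catalog if catalog is not None else builtin_catalog()
    intervals = gene_intervals(catalog)
    length = max(end for _, _, end in intervals.values()) + _GENE_SPACING
    rng = np.random.default_rng([cfg.seed, 17])
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length).astype(object)
    positions = _allocate_positions(cfg, intervals)
    for spec, pos in zip(cfg.variant_specs, positions):
        if spec.kind in {"del", "ins"}:
            run_base = "A" if seq[pos - 2] != "A" else "C"
            seq[pos - 1 : pos + 7] = run_base  # 8-copy homopolymer at pos..pos+7
            if seq[pos - 2] == run_base:
                seq[pos - 2] = "G"
            if seq[pos + 7] == run_base:
                seq[pos + 7] = "T"
    return {_CHROM: "".join(seq)}, intervals


def _variant_alleles(
    spec: VariantSpec,
    pos: int,
    seq: str,
    taken_alts: set[str],
) -> tuple[int, str, str, int, str, str]:
    """Normalized and as-written (possibly denormalized) representations."""

    def base_at(p: int) -> str:
        return seq[p - 1]

    if spec.kind == "snv":
        ref = base_at(pos)
        alt = next(b for b in "ACGT" if b != ref and b not in taken_alts)
        norm = (pos, ref, alt)
        written = (pos, ref, alt)
        if spec.denormalized == "pad":
            nxt = base_at(pos + 1)
            written = (pos, ref + nxt, alt + nxt)
    elif spec.kind == "del":
        run_base = base_at(pos)
        anchor = base_at(pos - 1)
        norm = (pos - 1, anchor + run_base, anchor)
        written = norm
        if spec.denormalized == "rightshift":
            written = (pos + 2, run_base * 2, run_base)
    else:  # ins
        run_base = base_at(pos)
        anchor = base_at(pos - 1)
        norm = (pos - 1, anchor, anchor + run_base)
        written = norm
    return (*norm, *written)


# ---------------------------------------------------------------------------
# Genotype simulation
# ---------------------------------------------------------------------------


def hwe_genotype_probs(q: float, f: float) -> tuple[float, float, float]:
    """(hom-ref, het, hom-alt) probabilities under inbreeding coefficient f."""
    hom_alt = q * q + f * q * (1 - q)
    het = 2 * q * (1 - q) * (1 - f)
    hom_ref = 1.0 - hom_alt - het
    return (hom_ref, het, hom_alt)


def simulate_genotypes(
    cfg: SimulationConfig, catalog: Mapping[str, GeneCatalogEntry] | None = None
) -> tuple[GenotypeMatrix, list[PlantedVariant], dict[str, str]]:
    """Draw the cohort genotype matrix and realize every planted variant.

    Returns the matrix, the planted variants (with carrier lists) and the
    reference sequences.  Fixed-count specs assign carriers by sampling
    without replacement; frequency specs draw genotypes independently per
    participant from the inbreeding-adjusted Hardy-Weinberg proportions.
    """
    catalog = catalog if catalog is not None else builtin_catalog()
    reference, intervals = build_reference(cfg, catalog)
    seq = reference[_CHROM]
    positions = _allocate_positions(cfg, intervals)
    participants = [f"P{i:05d}" for i in range(cfg.n_participants)]
    rng = np.random.default_rng([cfg.seed, 23])

    # alt alleles already used at a shared site must stay distinct
    taken_at: dict[int, set[str]] = {}
    planted: list[PlantedVariant] = []
    dosage_cols: list[np.ndarray] = []
    for i, spec in enumerate(cfg.variant_specs):
        pos = positions[i]
        taken = taken_at.setdefault(pos, set())
        npos, nref, nalt, wpos, wref, walt = _variant_alleles(spec, pos, seq, taken)
        taken.add(nalt)
        col = np.zeros(cfg.n_participants, dtype=np.int8)
        if spec.n_het is not None:
            exclude: set[int] = set()
            if spec.same_site_as is not None:
                partner = planted[spec.same_site_as]
                exclude = {participants.index(p) for p in partner.carriers}
            pool = np.array(
                [j for j in range(cfg.n_participants) if j not in exclude]
            )
            forced: list[int] = []
            if spec.share_carrier_with is not None:
                donor = planted[spec.share_carrier_with]
                forced = [participants.index(donor.het_carriers[0])]
            n_draw = spec.n_hom + spec.n_het - len(forced)
            pool = pool[~np.isin(pool, forced)]
            drawn = rng.choice(pool, size=n_draw, replace=False)
            chosen = list(drawn[: spec.n_hom])
            hets = list(drawn[spec.n_hom :]) + forced
            col[chosen] = 2
            col[hets] = 1
            hom_idx, het_idx = chosen, hets
        else:
            probs = hwe_genotype_probs(spec.allele_frequency, cfg.inbreeding_f)
            col = rng.choice(
                np.array([0, 1, 2], dtype=np.int8),
                size=cfg.n_participants,
                p=probs,
            )
            if spec.same_site_as is not None:
                partner = planted[spec.same_site_as]
                for p in partner.carriers:  # keep total alleles per person <= 2
                    col[participants.index(p)] = 0
            het_idx = list(np.flatnonzero(col == 1))
            hom_idx = list(np.flatnonzero(col == 2))
        planted.append(
            PlantedVariant(
                index=i,
                spec=spec,
                chrom=_CHROM,
                pos=npos,
                ref=nref,
                alt=nalt,
                vcf_pos=wpos,
                vcf_ref=wref,
                vcf_alt=walt,
                het_carriers=sorted(participants[j] for j in het_idx),
                hom_carriers=sorted(participants[j] for j in hom_idx),
            )
        )
        dosage_cols.append(col)

    gm = GenotypeMatrix(
        participants=participants,
        variant_keys=[pv.key for pv in planted],
        dosages=np.stack(dosage_cols, axis=1),
    )
    return gm, planted, reference


# ---------------------------------------------------------------------------
# Annotation recipes
# ---------------------------------------------------------------------------


def _recipe(pv: PlantedVariant, idx: int) -> dict:
    """Annotation fields that make the decision tree produce the truth label."""
    spec = pv.spec
    rs = f"rs{100000 + idx}"
    base = {
        "is_mane": "1",
        "consequence": "missense_variant",
        "impact": "MODERATE",
        "transcript_length": "3000",
        "clinvar_significance": "",
        "clinvar_stars": "",
        "hgmd_class": "",
        "revel": "",
        "pvs1_strength": "",
        "external_verdict": "",
        "gnomad_af": "",
        "dbsnp_id": "",
    }
    truth = spec.near_miss or spec.truth_list
    lof_consequence = {
        "snv": "stop_gained",
        "del": "frameshift_variant",
        "ins": "frameshift_variant",
    }[spec.kind]
    if truth == "P1":
        base.update(
            clinvar_significance="P",
            clinvar_stars="1",
            hgmd_class="DM",
            dbsnp_id=rs,
            gnomad_af="0.0005",
        )
    elif truth == "P2":
        base.update(
            clinvar_significance="LP",
            clinvar_stars="2",
            dbsnp_id=rs,
            gnomad_af="0.0003",
        )
    elif truth == "LP1":
        base.update(
            consequence=lof_consequence,
            impact="HIGH",
            pvs1_strength="VeryStrong",
            gnomad_af="0.0002",
        )
    elif truth in {"LP2", "pVUS"}:
        verdict = {"LP2": "LP", "pVUS": "VUS"}[truth]
        base.update(revel="0.82", external_verdict=verdict)
        status = ["VUS", "novel", "conflicting"][idx % 3]
        if status == "novel":
            base.update(external_verdict="" if truth == "pVUS" else "P")
        else:
            base.update(
                clinvar_significance=status, dbsnp_id=rs, gnomad_af="0.0002"
            )
    elif truth == "benign":
        base.update(
            consequence="synonymous_variant",
            impact="LOW",
            clinvar_significance="LB" if idx % 2 else "B",
            clinvar_stars="1",
            dbsnp_id=rs,
            gnomad_af="0.01",
        )
    elif truth == "common":
        base.update(dbsnp_id=rs, gnomad_af="0.06")
    # --- near-miss perturbations: one field off a passing recipe ---
    elif truth == "impact_moderate":
        base.update(
            consequence="inframe_deletion",
            impact="MODERATE",
            pvs1_strength="VeryStrong",
            gnomad_af="0.0002",
        )
    elif truth == "pvs1_moderate":
        base.update(
            consequence=lof_consequence,
            impact="HIGH",
            pvs1_strength="Moderate",
            gnomad_af="0.0002",
        )
    elif truth in {"not_rare", "lof_gene_false"}:
        base.update(
            consequence=lof_consequence,
            impact="HIGH",
            pvs1_strength="VeryStrong",
            gnomad_af="0.0002",
        )
    elif truth == "hgmd_conflict":
        base.update(
            clinvar_significance="P",
            clinvar_stars="3",
            hgmd_class="other",
            dbsnp_id=rs,
            gnomad_af="0.0005",
        )
    elif truth == "one_star":
        base.update(
            clinvar_significance="LP",
            clinvar_stars="1",
            dbsnp_id=rs,
            gnomad_af="0.0003",
        )
    elif truth == "revel_low":
        base.update(
            clinvar_significance="VUS",
            revel="0.65",
            external_verdict="LP",
            dbsnp_id=rs,
            gnomad_af="0.0002",
        )
    elif truth in {"single_carrier", "misc_gene", "no_evidence"}:
        base.update(
            clinvar_significance="VUS",
            revel="0.82",
            external_verdict="LP",
            dbsnp_id=rs,
            gnomad_af="0.0002",
        )
    elif truth == "dbsnp_only":
        base.update(revel="0.85", dbsnp_id=rs)
    else:
        raise ValueError(f"no annotation recipe for truth {truth!r}")
    return base


def emit_annotations(
    cfg: SimulationConfig,
    planted: Sequence[PlantedVariant],
) -> list[dict]:
    """Annotation rows (one or more transcripts per planted variant).

    Most variants get a single MANE transcript.  A few get extra
    transcripts to exercise selection: a decoy transcript behind a MANE
    flag, and MANE-less variants decided by severity rank or length.
    """
    rows: list[dict] = []
    for pv in planted:
        fields = _recipe(pv, pv.index)
        tx = f"ENST{pv.index:011d}"
        row = {
            "chrom": pv.chrom,
            "pos": str(pv.pos),
            "ref": pv.ref,
            "alt": pv.alt,
            "gene": pv.spec.gene,
            "transcript_id": tx,
            **fields,
        }
        rows.append(row)
        mod = pv.index % 10
        if cfg.include_decoys and mod == 0:
            # non-MANE decoy; MANE must still win
            decoy = dict(row)
            decoy.update(
                transcript_id=f"ENST{90_000_000_000 + pv.index}",
                is_mane="0",
                consequence="synonymous_variant",
                impact="LOW",
                transcript_length="9000",
            )
            rows.append(decoy)
        elif cfg.include_decoys and mod == 4 and pv.spec.near_miss is None:
            # MANE-less pair decided by length (same consequence class)
            row["is_mane"] = "0"
            row["transcript_length"] = "3500"
            decoy = dict(row)
            decoy.update(
                transcript_id=f"ENST{91_000_000_000 + pv.index}",
                transcript_length="2000",
                revel="0.50" if fields["revel"] else "",
            )
            rows.append(decoy)
        elif cfg.include_decoys and mod == 7 and pv.spec.near_miss is None:
            # MANE-less pair decided by severity rank
            row["is_mane"] = "0"
            decoy = dict(row)
            decoy.update(
                transcript_id=f"ENST{92_000_000_000 + pv.index}",
                consequence="intron_variant",
                impact="MODIFIER",
                transcript_length="9000",
            )
            rows.append(decoy)
    return rows


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------

_CVD_COMPONENTS = (
    "ecg_abnormal",
    "self_heart_disease",
    "revascularization",
    "family_heart_disease",
)
_CANCER_COMPONENTS = ("self_cancer", "parent_cancer", "tumor_surgery", "early_screening")


def _carrier_rate(p0: float, or_: float) -> float:
    odds = or_ * p0 / (1 - p0)
    return odds / (1 + odds)


def simulate_phenotypes(
    cfg: SimulationConfig,
    gm: GenotypeMatrix,
    planted: Sequence[PlantedVariant],
):
    """Draw per-participant phenotype records consistent with the truth.

    The composite evidence flag per stream (CVD / cancer / FH) is drawn
    first — baseline rate for non-carriers, odds-scaled rate for carriers
    of an OR-planted variant, forced for carriers of variants whose truth
    label requires (or forbids) evidence — and is then attributed to one
    concrete component.  Lipid values for participants without FH evidence
    are kept below the threshold so the composite rate is exact.
    """
    from .phenotype_assoc import ParticipantPhenotype

    rng = np.random.default_rng([cfg.seed, 31])
    n = len(gm.participants)
    idx_of = {p: j for j, p in enumerate(gm.participants)}

    or_mult = {t: np.ones(n) for t in ("CVD", "cancer", "FH")}
    forced_true = {t: np.zeros(n, dtype=bool) for t in ("CVD", "cancer", "FH")}
    forced_false = {t: np.zeros(n, dtype=bool) for t in ("CVD", "cancer", "FH")}
    for pv in planted:
        etype = pv.spec.evidence_type
        if etype is None:
            continue
        members = [idx_of[p] for p in pv.carriers]
        if pv.spec.forced_evidence is True:
            forced_true[etype][members] = True
        elif pv.spec.forced_evidence is False:
            forced_false[etype][members] = True
        if pv.spec.planted_or is not None:
            or_mult[etype][members] = np.maximum(
                or_mult[etype][members], pv.spec.planted_or
            )

    ages = rng.integers(18, 80, size=n)
    sexes = rng.choice(np.array(["F", "M"]), size=n)

    composite = {}
    for t in ("CVD", "cancer", "FH"):
        p0 = cfg.phenotype_baseline[t]
        rates = np.array(
            [_carrier_rate(p0, m) if m != 1 else p0 for m in or_mult[t]]
        )
        flags = rng.random(n) < rates
        flags[forced_true[t]] = True
        flags[forced_false[t]] = False
        composite[t] = flags

    phenotypes = []
    for j, participant in enumerate(gm.participants):
        rec: dict = {name: False for name in _CVD_COMPONENTS + _CANCER_COMPONENTS}
        age, sex = int(ages[j]), str(sexes[j])
        if composite["CVD"][j]:
            rec[_CVD_COMPONENTS[rng.integers(0, len(_CVD_COMPONENTS))]] = True
        if composite["cancer"][j]:
            allowed = list(_CANCER_COMPONENTS)
            if age >= cfg.screening_age[sex]:
                allowed.remove("early_screening")
            rec[allowed[rng.integers(0, len(allowed))]] = True
        dx = False
        if composite["FH"][j]:
            if rng.random() < 0.5:
                dx = True
                ldl = round(float(np.clip(rng.normal(3.0, 0.8), 0.5, cfg.ldl_threshold - 0.1)), 2)
            else:
                ldl = round(float(cfg.ldl_threshold + abs(rng.normal(0.8, 0.5))), 2)
        else:
            ldl = round(float(np.clip(rng.normal(3.0, 0.8), 0.5, cfg.ldl_threshold - 0.1)), 2)
            if rng.random() < 0.05:
                ldl = None
        hdl = round(float(np.clip(rng.normal(1.3, 0.3), 0.4, None)), 2)
        total = round((ldl or 3.0) + hdl + round(float(np.clip(rng.normal(1.0, 0.3), 0.2, None)), 2), 2)
        phenotypes.append(
            ParticipantPhenotype(
                participant=participant,
                ecg_abnormal=rec["ecg_abnormal"],
                self_heart_disease=rec["self_heart_disease"],
                revascularization=rec["revascularization"],
                family_heart_disease=rec["family_heart_disease"],
                self_cancer=rec["self_cancer"],
                parent_cancer=rec["parent_cancer"],
                tumor_surgery=rec["tumor_surgery"],
                early_screening=rec["early_screening"],
                total_chol=total,
                hdl=hdl,
                ldl=ldl,
                hypercholesterolemia_dx=dx,
                age=age,
                sex=sex,
            )
        )
    return phenotypes


# ---------------------------------------------------------------------------
# Bundle writing
# ---------------------------------------------------------------------------


def _format_bool(value: bool) -> str:
    return "1" if value else "0"


def _write_fasta(reference: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def _vcf_lines(
    cfg: SimulationConfig,
    gm: GenotypeMatrix,
    planted: Sequence[PlantedVariant],
    reference: Mapping[str, str],
    intervals: Mapping[str, tuple[str, int, int]],
) -> str:
    """Assemble the multisample VCF, merging shared sites into one
    multi-allelic line and appending decoy lines when configured."""
    participants = gm.participants
    n = len(participants)

    # group planted variants by written site
    sites: dict[tuple[str, int, str], list[PlantedVariant]] = {}
    for pv in planted:
        sites.setdefault((pv.chrom, pv.vcf_pos, pv.vcf_ref), []).append(pv)

    rows = []
    for (chrom, pos, ref), pvs in sites.items():
        alts = [pv.vcf_alt for pv in pvs]
        codes = np.zeros((n, 2), dtype=int)
        for k, pv in enumerate(pvs, start=1):
            col = gm.column(pv.key)
            for j in np.flatnonzero(col == 1):
                slot = 1 if codes[j, 0] != 0 else 0
                codes[j, slot] = k
            for j in np.flatnonzero(col == 2):
                codes[j, 0] = codes[j, 1] = k
        gts = "\t".join(f"{a}/{b}" for a, b in np.sort(codes, axis=1))
        star = ""
        if cfg.include_decoys and pvs[0].index == 0:
            star = ",*"  # spanning-deletion allele, no carriers
        rows.append((chrom, pos, ref, ",".join(alts) + star, "PASS", gts))

    if cfg.include_decoys:
        seq = reference[_CHROM]
        first = next(iter(intervals.values()))
        # off-gene PASS site in the spacer before the first gene
        off_pos = 50
        gt = "\t".join(["0/1"] + ["0/0"] * (n - 1))
        ref_b = seq[off_pos - 1]
        alt_b = "A" if ref_b != "A" else "G"
        rows.append((_CHROM, off_pos, ref_b, alt_b, "PASS", gt))
        # in-gene LowQual site
        lq_pos = first[1] + 10
        ref_b = seq[lq_pos - 1]
        alt_b = "A" if ref_b != "A" else "G"
        gt = "\t".join(["0/1", "0/1"] + ["0/0"] * (n - 2))
        rows.append((_CHROM, lq_pos, ref_b, alt_b, "LowQual", gt))

    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    header = (
        "##fileformat=VCFv4.2\n"
        '##FILTER=<ID=LowQual,Description="Low quality site">\n'
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        f"##contig=<ID={_CHROM},length={len(reference[_CHROM])}>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(participants)
        + "\n"
    )
    body = "".join(
        f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t50\t{filt}\t.\tGT\t{gts}\n"
        for chrom, pos, ref, alt, filt, gts in rows
    )
    return header + body


def _truth_payload(
    cfg: SimulationConfig, planted: Sequence[PlantedVariant]
) -> dict:
    gpp_lists = {"P1", "P2", "LP1", "LP2", "pVUS"}
    gpp: set[str] = set()
    counts: dict[str, int] = {}
    for pv in planted:
        counts[pv.expected_list] = counts.get(pv.expected_list, 0) + 1
        if pv.expected_list in gpp_lists:
            gpp.update(pv.carriers)
    return {
        "seed": cfg.seed,
        "n_participants": cfg.n_participants,
        "inbreeding_f": cfg.inbreeding_f,
        "variants": [
            {
                "key": pv.key,
                "gene": pv.spec.gene,
                "truth_list": pv.spec.truth_list,
                "near_miss": pv.spec.near_miss,
                "expected_list": pv.expected_list,
                "n_het": len(pv.het_carriers),
                "n_hom": len(pv.hom_carriers),
                "planted_or": pv.spec.planted_or,
                "evidence_type": pv.spec.evidence_type,
            }
            for pv in planted
        ],
        "expected_list_counts": dict(sorted(counts.items())),
        "distinct_gpp": len(gpp),
    }


def write_fixture_bundle(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete, immediately runnable fixture bundle.

    Produces the cohort VCF, annotation/phenotype/catalog/region TSVs, the
    reference FASTA and a truth JSON.  Regenerating with the same config is
    byte-identical.
    """
    from importlib.resources import files

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = builtin_catalog()
    gm, planted, reference = simulate_genotypes(cfg, catalog)
    intervals = gene_intervals(catalog)

    paths = {name: outdir / fname for name, fname in [
        ("vcf", "cohort.vcf"),
        ("annotations", "annotations.tsv"),
        ("phenotypes", "phenotypes.tsv"),
        ("catalog", "catalog.tsv"),
        ("truth", "truth.json"),
        ("regions", "regions.tsv"),
        ("reference", "reference.fa"),
    ]}

    paths["vcf"].write_text(_vcf_lines(cfg, gm, planted, reference, intervals))
    _write_fasta(reference, paths["reference"])

    with open(paths["regions"], "w") as fh:
        for symbol, (chrom, start, end) in intervals.items():
            fh.write(f"{chrom}\t{start}\t{end}\t{symbol}\n")

    catalog_src = (files("sftriage.data") / "acmg_sf_v3_1_catalog.tsv").read_text()
    paths["catalog"].write_text(catalog_src)

    ann_rows = emit_annotations(cfg, planted)
    ann_cols = [
        "chrom", "pos", "ref", "alt", "gene", "transcript_id", "is_mane",
        "consequence", "impact", "transcript_length", "clinvar_significance",
        "clinvar_stars", "hgmd_class", "revel", "pvs1_strength",
        "external_verdict", "gnomad_af", "dbsnp_id",
    ]
    with open(paths["annotations"], "w") as fh:
        fh.write("\t".join(ann_cols) + "\n")
        for row in ann_rows:
            fh.write("\t".join(str(row[c]) for c in ann_cols) + "\n")

    phenotypes = simulate_phenotypes(cfg, gm, planted)
    pheno_cols = [
        "participant", "ecg_abnormal", "self_heart_disease", "revascularization",
        "family_heart_disease", "self_cancer", "parent_cancer", "tumor_surgery",
        "early_screening", "total_chol", "hdl", "ldl", "hypercholesterolemia_dx",
        "age", "sex",
    ]
    with open(paths["phenotypes"], "w") as fh:
        fh.write("\t".join(pheno_cols) + "\n")
        for p in phenotypes:
            cells = []
            for c in pheno_cols:
                v = getattr(p, c)
                if isinstance(v, bool):
                    cells.append(_format_bool(v))
                elif v is None:
                    cells.append("")
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")

    with open(paths["truth"], "w") as fh:
        json.dump(_truth_payload(cfg, planted), fh, indent=1, sort_keys=True)
        fh.write("\n")

    return paths


# ---------------------------------------------------------------------------
# Shipped configurations
# ---------------------------------------------------------------------------


def demo_config(seed: int = 0, n_participants: int = 500) -> SimulationConfig:
    """Small bundle: pathogenic lists, rejections and near-misses only.

    The rare-missense lists need simultaneously MAF < 0.1% and more than
    one carrier, which is arithmetically impossible below ~2000
    participants, so the demo plants none of them.
    """
    v = VariantSpec
    specs = [
        v("TTN", "P1", n_het=4),
        v("BRCA2", "P1", n_het=3),
        v("ATP7B", "P1", n_het=3, n_hom=1),
        v("LDLR", "P2", n_het=2),
        v("MSH6", "P2", n_het=2, share_carrier_with=1),
        v("RYR1", "P1", n_het=2),
        v("TTN", "benign", allele_frequency=0.01),
        v("APC", "benign", allele_frequency=0.01),
        v("TTR", "common", allele_frequency=0.06),
        v("VHL", "unclassified", n_het=2, near_miss="hgmd_conflict"),
        v("PALB2", "unclassified", n_het=2, near_miss="one_star"),
        v("TNNI3", "unclassified", n_het=2, near_miss="dbsnp_only",
          evidence_type="CVD", forced_evidence=True),
    ]
    return SimulationConfig(n_participants=n_participants, seed=seed, variant_specs=specs)


def full_cohort_config(seed: int = 0, n_participants: int = 2000) -> SimulationConfig:
    """Forty planted variants spanning every truth class and near-miss."""
    v = VariantSpec
    specs = [
        # validated pathogenic
        v("TTN", "P1", n_het=8),                                   # 0
        v("BRCA2", "P1", n_het=5),                                 # 1
        v("ATP7B", "P1", n_het=6, n_hom=1),                        # 2
        v("RYR1", "P1", n_het=4),                                  # 3
        v("MYH7", "P1", n_het=3),                                  # 4
        v("LDLR", "P2", n_het=4),                                  # 5
        v("MSH6", "P2", n_het=3, share_carrier_with=1),            # 6
        v("KCNQ1", "P2", n_het=2),                                 # 7
        # rare loss-of-function
        v("TTN", "LP1", n_het=3, kind="del"),                      # 8
        v("PKP2", "LP1", n_het=3, kind="del", denormalized="rightshift"),  # 9
        v("DSP", "LP1", n_het=2),                                  # 10
        v("GAA", "LP1", n_het=3),                                  # 11
        v("BTD", "LP1", n_het=2, kind="ins"),                      # 12
        v("ATP7B", "LP1", n_het=2, share_carrier_with=2),          # 13
        # rare missense with evidence, external P/LP verdict
        v("MYH7", "LP2", n_het=3, evidence_type="CVD", forced_evidence=True),    # 14
        v("BRCA1", "LP2", n_het=2, evidence_type="cancer", forced_evidence=True),  # 15
        v("TSC2", "LP2", n_het=3, evidence_type="cancer", forced_evidence=True),   # 16
        v("DSG2", "LP2", n_het=2, evidence_type="CVD", forced_evidence=True),      # 17
        # rare missense with evidence, no external P/LP verdict
        v("LMNA", "pVUS", n_het=3, evidence_type="CVD", forced_evidence=True),     # 18
        v("MSH2", "pVUS", n_het=2, evidence_type="cancer", forced_evidence=True),  # 19
        v("LDLR", "pVUS", n_het=3, evidence_type="FH", forced_evidence=True),      # 20
        v("TTN", "pVUS", n_het=3, evidence_type="CVD", forced_evidence=True,
          same_site_as=0),                                         # 21
        v("RYR2", "pVUS", n_het=2, evidence_type="CVD", forced_evidence=True),     # 22
        v("MSH6", "pVUS", n_het=2, evidence_type="cancer", forced_evidence=True),  # 23
        # rejected
        v("TTN", "benign", allele_frequency=0.005),                # 24
        v("APC", "benign", allele_frequency=0.004),                # 25
        v("SCN5A", "benign", allele_frequency=0.008),              # 26
        v("TTR", "common", allele_frequency=0.06),                 # 27
        v("KCNH2", "common", allele_frequency=0.08),               # 28
        v("PMS2", "common", allele_frequency=0.05),                # 29
        # adversarial near-misses (one field off a passing recipe)
        v("DSC2", "unclassified", n_het=2, kind="del", near_miss="impact_moderate"),  # 30
        v("COL3A1", "unclassified", n_het=2, near_miss="pvs1_moderate"),       # 31
        v("FLNC", "unclassified", n_het=12, near_miss="not_rare"),             # 32
        v("RYR1", "unclassified", n_het=2, near_miss="lof_gene_false"),        # 33
        v("VHL", "unclassified", n_het=3, near_miss="hgmd_conflict"),          # 34
        v("PALB2", "unclassified", n_het=2, near_miss="one_star"),             # 35
        v("MYBPC3", "unclassified", n_het=2, near_miss="revel_low",
          evidence_type="CVD", forced_evidence=True),                          # 36
        v("PTEN", "unclassified", n_het=1, near_miss="single_carrier",
          evidence_type="cancer", forced_evidence=True),                       # 37
        v("TNNI3", "unclassified", n_het=2, near_miss="dbsnp_only",
          evidence_type="CVD", forced_evidence=True),                          # 38
        v("MYL3", "unclassified", n_het=3, near_miss="no_evidence",
          evidence_type="CVD", forced_evidence=False),                         # 39
    ]
    return SimulationConfig(n_participants=n_participants, seed=seed, variant_specs=specs)


# ---------------------------------------------------------------------------
# Association-recovery helper
# ---------------------------------------------------------------------------


def association_replicate(
    seed: int,
    n_participants: int = 5000,
    allele_frequency: float = 0.01,
    planted_or: float = 5.0,
    baseline: float = 0.05,
    evidence_type: str = "cancer",
) -> tuple[int, int, int, int, int]:
    """One cohort draw for planted-odds-ratio recovery studies.

    Simulates a single OR-planted variant through the standard genotype and
    phenotype generators and tabulates carriers x evidence.  Returns
    ``(a, b, c, d, n_carriers)``.
    """
    from .phenotype_assoc import evidence_flags

    gene = {"cancer": "BRCA2", "CVD": "MYH7", "FH": "LDLR"}[evidence_type]
    cfg = SimulationConfig(
        n_participants=n_participants,
        seed=seed,
        inbreeding_f=0.0,
        variant_specs=[
            VariantSpec(
                gene,
                "pVUS",
                allele_frequency=allele_frequency,
                planted_or=planted_or,
                evidence_type=evidence_type,
            )
        ],
        phenotype_baseline={"CVD": baseline, "cancer": baseline, "FH": baseline},
        include_decoys=False,
    )
    gm, planted, _ = simulate_genotypes(cfg)
    phenotypes = simulate_phenotypes(cfg, gm, planted)
    carriers = set(planted[0].carriers)
    a = b = c = d = 0
    for p in phenotypes:
        has = evidence_flags(p, cfg.ldl_threshold)[evidence_type]
        if p.participant in carriers:
            a, b = a + has, b + (not has)
        else:
            c, d = c + has, d + (not has)
    return a, b, c, d, len(carriers)
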