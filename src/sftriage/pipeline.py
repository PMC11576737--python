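"""End-to-end orchestration: VCF to classified lists, tallies and tests.

The run proceeds through the same funnel as the analysis it packages:
read passing-filter sites in catalog genes, decompose multi-allelics,
normalize, compute cohort allele statistics, select one transcript per
variant, classify (with the cohort-evidence gate for the rare-missense
lists), identify genotype-positive participants, apply the
inheritance-aware reportability rule, summarize per gene/category with
prevalence intervals, and finally test carrier-phenotype association for
the candidate variants.

Every stage logs one line with its input/output record counts, so the
funnel is reconstructable from the log; all outputs are deterministic
functions of the inputs (no unseeded randomness anywhere), so re-running
on identical inputs yields byte-identical tables.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import cohort_stats as _stats
from . import io_formats as _io
from . import phenotype_assoc as _assoc
from .transcript_select import select_transcript

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

__all__ = [
    "PipelineError",
    "ValidationReport",
    "RunReport",
    "load_run_config",
    "validate_inputs",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names the failing module."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def fatal(self) -> bool:
        return bool(self.errors)

    @property
    def findings(self) -> list[str]:
        return self.errors + self.warnings


@dataclass
class RunReport:
    thresholds: dict
    n_participants: int
    variant_counts: dict
    gpp_counts: dict
    distinct_gpp: int
    reportable_gpp: int
    carrier_only_gpp: int
    prevalence: dict
    skip_log: dict
    association: list
    multi_variant_carriers: list
    schema_version: str = SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "thresholds": self.thresholds,
            "n_participants": self.n_participants,
            "variant_counts": self.variant_counts,
            "gpp_counts": self.gpp_counts,
            "distinct_gpp": self.distinct_gpp,
            "reportable_gpp": self.reportable_gpp,
            "carrier_only_gpp": self.carrier_only_gpp,
            "prevalence": self.prevalence,
            "skip_log": self.skip_log,
            "association": self.association,
            "multi_variant_carriers": self.multi_variant_carriers,
        }


def load_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config", f"{path} does not contain a mapping")
    base = Path(path).parent
    for key in ("vcf", "annotations", "phenotypes", "catalog", "regions", "reference"):
        if key in cfg and cfg[key] is not None:
            cfg[key] = str((base / cfg[key]).resolve())
    return cfg


@dataclass
class _Provisional:
    """Minimal carrier record used for candidate selection pre-classification."""

    participant: str
    gene: str
    variant: _io.NormalizedVariant


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage attribution
                raise PipelineError(name, str(exc)) from exc

        return inner

    return wrap


@_stage("io_formats")
def _read_cohort(cfg: dict, catalog, skip_log: Counter):
    regions = _io.load_region_map(cfg["regions"], catalog)
    ref_fetch = (
        _io.fasta_fetcher(cfg["reference"]) if cfg.get("reference") else None
    )
    samples = _io.read_vcf_samples(cfg["vcf"])
    records: dict[tuple[str, str], np.ndarray] = {}
    order: list[tuple[str, str]] = []
    meta: dict[tuple[str, str], tuple[str, int, str, str]] = {}
    n_sites = 0
    for site, gene, _ in _io.read_multisample_vcf(cfg["vcf"], regions, skip_log):
        n_sites += 1
        for chrom, pos, ref, alt, dosages in _io.decompose_multiallelic(
            site, skip_log
        ):
            chrom, pos, ref, alt = _io.normalize_variant(
                chrom, pos, ref, alt, ref_fetch
            )
            rec_key = (f"{chrom}:{pos}:{ref}:{alt}", gene)
            if rec_key in records:
                log.warning("duplicate record %s; keeping max dosage", rec_key)
                records[rec_key] = np.maximum(records[rec_key], dosages)
            else:
                records[rec_key] = dosages
                order.append(rec_key)
                meta[rec_key] = (chrom, pos, ref, alt)
    variants: list[_io.NormalizedVariant] = []
    cols: list[np.ndarray] = []
    for rec_key in order:
        dosages = records[rec_key]
        called = dosages != _io.MISSING
        an = 2 * int(called.sum())
        if an == 0:
            skip_log["an_zero"] += 1
            continue
        chrom, pos, ref, alt = meta[rec_key]
        variants.append(
            _io.NormalizedVariant(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=rec_key[1],
                allele_count=int(dosages[called].sum()),
                allele_number=an,
            )
        )
        cols.append(dosages)
    gm = _io.GenotypeMatrix(
        participants=samples,
        variant_keys=[v.key for v in variants],
        dosages=(
            np.stack(cols, axis=1)
            if cols
            else np.zeros((len(samples), 0), dtype=np.int8)
        ),
    )
    log.info(
        "io_formats: %d sites read, %d biallelic variants kept, skips=%s",
        n_sites,
        len(variants),
        dict(skip_log),
    )
    return variants, gm


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path | None = None,
    skip_association: bool = False,
) -> RunReport:
    """Execute the full analysis described by a run config.

    ``config`` maps input paths (vcf, annotations, phenotypes, catalog,
    regions, optional reference) plus optional ``thresholds`` overrides and
    an ``association`` flag.  When ``out_dir`` is given, all result tables
    and a JSON report are written there.
    """
    if not isinstance(config, dict):
        config = load_run_config(config)
    thresholds = _classify.Thresholds.from_mapping(config.get("thresholds"))
    ldl_threshold = float(config.get("ldl_threshold", _assoc.DEFAULT_LDL_THRESHOLD))
    skip_log: Counter = Counter()

    try:
        catalog = _io.load_gene_catalog(config["catalog"])
    except Exception as exc:
        raise PipelineError("io_formats", str(exc)) from exc
    variants, gm = _read_cohort(config, catalog, skip_log)

    try:
        annotations = _io.load_annotation_table(config["annotations"])
    except Exception as exc:
        raise PipelineError("io_formats", str(exc)) from exc

    # ------------------------------------------------------------------ #
    # transcript selection
    selected = {}
    for v in variants:
        anns = annotations.get(v.key)
        if not anns:
            skip_log["unannotated"] += 1
            continue
        try:
            selected[v.key] = select_transcript(anns)
        except Exception as exc:
            raise PipelineError("transcript_select", str(exc)) from exc
    log.info("transcript_select: %d/%d variants annotated", len(selected), len(variants))

    # ------------------------------------------------------------------ #
    # phenotypes and evidence candidates
    association_requested = bool(config.get("association", True)) and not skip_association
    phenotypes: dict[str, _assoc.ParticipantPhenotype] = {}
    pheno_path = config.get("phenotypes")
    if pheno_path and Path(pheno_path).exists():
        try:
            phenotypes = _assoc.load_phenotype_table(pheno_path)
        except Exception as exc:
            raise PipelineError("phenotype_assoc", str(exc)) from exc
    elif association_requested:
        raise PipelineError(
            "phenotype_assoc",
            f"association requested but phenotype table missing: {pheno_path!r}",
        )

    pool: list[_Provisional] = []
    for v in variants:
        ann = selected.get(v.key)
        if ann is None:
            continue
        if not (_classify.is_missense(ann) and _classify.lp2_status_eligible(ann)):
            continue
        if catalog[v.gene].category not in {"cancer", "cardiovascular"}:
            continue
        for participant in gm.carriers(v.key):
            pool.append(_Provisional(participant, v.gene, v))
    candidates = (
        _assoc.select_candidates(pool, phenotypes, catalog, ldl_threshold)
        if phenotypes
        else {}
    )
    log.info(
        "phenotype_assoc: %d review-pool variants, %d candidates with evidence",
        len({p.variant.key for p in pool}),
        len(candidates),
    )

    # ------------------------------------------------------------------ #
    # classification
    results = []
    for v in variants:
        ann = selected.get(v.key)
        if ann is None:
            results.append(
                _classify.ClassificationResult(v, "unclassified", ("no_annotation",))
            )
            continue
        try:
            results.append(
                _classify.classify_variant(
                    ann,
                    v,
                    carriers=len(gm.carriers(v.key)),
                    t=thresholds,
                    gene_entry=catalog[v.gene],
                    cohort_evidence=v.key in candidates,
                )
            )
        except Exception as exc:
            raise PipelineError("classify", str(exc)) from exc
    variant_counts = Counter(r.list for r in results)
    log.info("classify: %s", dict(variant_counts))

    # ------------------------------------------------------------------ #
    # genotype-positive participants and reportability
    try:
        findings = _stats.identify_gpps(results, gm, catalog)
        findings = _stats.annotate_reportability(findings)
    except Exception as exc:
        raise PipelineError("cohort_stats", str(exc)) from exc
    distinct_gpp = len({f.participant for f in findings})
    reportable_participants = {f.participant for f in findings if f.reportable}
    carrier_only_participants = {
        f.participant for f in findings if f.carrier_only
    } - reportable_participants
    gpp_counts = {
        lst: len({f.participant for f in findings if f.list == lst})
        for lst in ("P1", "P2", "LP1", "LP2", "pVUS")
    }
    log.info(
        "cohort_stats: %d findings, %d distinct GPPs, %d reportable",
        len(findings),
        distinct_gpp,
        len(reportable_participants),
    )

    n_participants = len(gm.participants)
    prevalence: dict = {}
    if n_participants:
        for name, num in [
            ("any_list_gpp", distinct_gpp),
            ("reportable_gpp", len(reportable_participants)),
            ("carrier_only_gpp", len(carrier_only_participants)),
        ]:
            est = _stats.prevalence(num, n_participants)
            prevalence[name] = {
                "numerator": est.numerator,
                "denominator": est.denominator,
                "proportion": est.proportion,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }

    gene_summary = _stats.summarize_by_gene(findings, catalog)
    category_summary = _stats.summarize_by_category(findings, catalog)
    multi = _stats.multi_variant_carriers(findings)

    # ------------------------------------------------------------------ #
    # association
    association_rows: list[dict] = []
    if association_requested and phenotypes:
        final_list = {r.variant.key: r.list for r in results}
        for key, etype in sorted(candidates.items()):
            if final_list.get(key) not in {"LP2", "pVUS"}:
                continue
            carriers = set(gm.carriers(key))
            a = b = c = d = 0
            for participant, pheno in phenotypes.items():
                flags = _assoc.evidence_flags(pheno, ldl_threshold)
                has = flags[etype]
                if participant in carriers:
                    a, b = a + has, b + (not has)
                else:
                    c, d = c + has, d + (not has)
            res = _assoc.fisher_association(
                a, b, c, d, variant_key=key, evidence_type=etype
            )
            association_rows.append(
                {
                    "variant": key,
                    "list": final_list[key],
                    "evidence_type": etype,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": res.odds_ratio,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p_value": res.p_value,
                    "stars": res.stars,
                    "testable": res.testable,
                    "note": res.note,
                }
            )
        testable = [r for r in association_rows if r["testable"]]
        if testable:
            from statsmodels.stats.multitest import multipletests

            _, q, _, _ = multipletests(
                [r["p_value"] for r in testable], method="fdr_bh"
            )
            for r, qv in zip(testable, q):
                r["bh_fdr"] = float(qv)
        log.info("phenotype_assoc: %d associations tested", len(association_rows))

    report = RunReport(
        thresholds=thresholds.to_dict(),
        n_participants=n_participants,
        variant_counts={k: int(variant_counts.get(k, 0)) for k in _classify.LISTS},
        gpp_counts=gpp_counts,
        distinct_gpp=distinct_gpp,
        reportable_gpp=len(reportable_participants),
        carrier_only_gpp=len(carrier_only_participants),
        prevalence=prevalence,
        skip_log=dict(skip_log),
        association=association_rows,
        multi_variant_carriers=[
            {
                "participant": participant,
                "findings": [
                    {
                        "gene": f.gene,
                        "variant": f.variant.key,
                        "list": f.list,
                        "phenotype": catalog[f.gene].phenotype,
                    }
                    for f in fs
                ],
            }
            for participant, fs in multi
        ],
    )

    if out_dir is not None:
        _write_outputs(
            Path(out_dir), report, results, findings, gene_summary, category_summary
        )
    return report


def _write_outputs(
    out_dir: Path,
    report: RunReport,
    results,
    findings,
    gene_summary: pd.DataFrame,
    category_summary: pd.DataFrame,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cls_rows = [
        {
            "variant": r.variant.key,
            "gene": r.variant.gene,
            "list": r.list,
            "cohort_maf": f"{r.variant.cohort_maf:.6g}",
            "allele_count": r.variant.allele_count,
            "allele_number": r.variant.allele_number,
            "reasons": ";".join(r.reasons),
        }
        for r in results
    ]
    pd.DataFrame(cls_rows).to_csv(out_dir / "classifications.tsv", sep="\t", index=False)
    fnd_rows = [
        {
            "participant": f.participant,
            "gene": f.gene,
            "variant": f.variant.key,
            "list": f.list,
            "zygosity": f.zygosity,
            "inheritance": f.inheritance,
            "reportable": int(f.reportable),
            "carrier_only": int(f.carrier_only),
            "phase_unknown": int(f.phase_unknown),
        }
        for f in findings
    ]
    pd.DataFrame(fnd_rows).to_csv(out_dir / "findings.tsv", sep="\t", index=False)
    gene_summary.to_csv(out_dir / "gene_summary.tsv", sep="\t", index=False)
    category_summary.to_csv(out_dir / "category_summary.tsv", sep="\t", index=False)
    pd.DataFrame(report.association).to_csv(
        out_dir / "associations.tsv", sep="\t", index=False
    )
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------


def validate_inputs(config: dict | str | Path) -> ValidationReport:
    """Consistency checks across all inputs; never raises.

    Fatal findings (catalog defects, missing mandatory annotation columns)
    are separated from warnings (sample-identifier mismatches between the
    VCF and the phenotype table, unexpected catalog size).
    """
    report = ValidationReport()
    if not isinstance(config, dict):
        try:
            config = load_run_config(config)
        except Exception as exc:
            report.errors.append(f"config: {exc}")
            return report

    catalog = None
    try:
        catalog = _io.load_gene_catalog(config["catalog"])
        versions = {e.sf_version for e in catalog.values()}
        if versions == {"v3.1"} and len(catalog) != 78:
            report.errors.append(
                f"catalog: v3.1 must contain 78 genes, found {len(catalog)}"
            )
    except Exception as exc:
        report.errors.append(f"catalog: {exc}")

    if catalog is not None:
        try:
            _io.load_region_map(config["regions"], catalog)
        except Exception as exc:
            report.errors.append(f"regions: {exc}")

    try:
        _io.load_annotation_table(config["annotations"])
    except Exception as exc:
        report.errors.append(f"annotations: {exc}")

    samples: list[str] = []
    try:
        samples = _io.read_vcf_samples(config["vcf"])
    except Exception as exc:
        report.errors.append(f"vcf: {exc}")

    pheno_path = config.get("phenotypes")
    if pheno_path and Path(pheno_path).exists():
        try:
            phenotypes = _assoc.load_phenotype_table(pheno_path)
            missing = [s for s in samples if s not in phenotypes]
            if missing:
                report.warnings.append(
                    f"phenotypes: {len(missing)} VCF samples missing from the "
                    f"phenotype table (e.g. {missing[:5]})"
                )
        except Exception as exc:
            report.errors.append(f"phenotypes: {exc}")
    elif pheno_path:
        report.warnings.append(f"phenotypes: file not found: {pheno_path}")
    return report
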