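"""Readers, writers and variant normalization for the triage pipeline.

This module owns every external format the pipeline touches:

* multisample VCF v4.2 (read through :mod:`cyvcf2`, written as plain text),
* the actionable-gene catalog (TSV, one row per gene),
* the gene region map (TSV, 1-based fully-closed intervals — *not* BED
  half-open),
* the per-variant/per-transcript annotation table (TSV),
* a reference FASTA used only for indel left-alignment (via :mod:`pyfaidx`).

It also implements the representation layer of the analysis: multi-allelic
decomposition into biallelic records and normalization to the minimal,
left-aligned representation, so that every downstream rule sees exactly one
canonical key per variant site.

Conventions
-----------
Coordinates are 1-based and fully closed throughout.  Autosomal diploid
calls are assumed; haploid calls are doubled with a warning.  A genotype
containing any missing allele is treated as fully missing and excluded from
both AC and AN.  After decomposition, AN at each biallelic record counts all
called alleles at the original site, so other-ALT alleles count toward AN as
reference.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = [
    "NormalizedVariant",
    "GeneCatalogEntry",
    "GenotypeMatrix",
    "RawSite",
    "VcfFormatError",
    "ReferenceMismatchError",
    "CatalogError",
    "AnnotationTableError",
    "read_multisample_vcf",
    "read_vcf_samples",
    "decompose_multiallelic",
    "normalize_variant",
    "load_annotation_table",
    "load_gene_catalog",
    "builtin_catalog",
    "load_region_map",
    "fasta_fetcher",
    "write_genotype_vcf",
    "MISSING",
]

_ALLELE_RE = re.compile(r"^[ACGTN]+$")

#: Sentinel dosage for a missing genotype in :class:`GenotypeMatrix`.
MISSING: int = -1

INHERITANCE_CODES = frozenset({"AD", "AR", "SD", "XL"})
CATEGORIES = frozenset({"cancer", "cardiovascular", "miscellaneous"})

ANNOTATION_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript_id",
    "is_mane",
    "consequence",
    "impact",
    "transcript_length",
    "clinvar_significance",
    "clinvar_stars",
    "hgmd_class",
    "revel",
    "pvs1_strength",
    "external_verdict",
    "gnomad_af",
    "dbsnp_id",
)


class VcfFormatError(ValueError):
    """The VCF violates the contract required by the pipeline."""


class ReferenceMismatchError(ValueError):
    """A REF allele disagrees with the reference sequence oracle."""


class CatalogError(ValueError):
    """The gene catalog or region map is inconsistent."""


class AnnotationTableError(ValueError):
    """The annotation TSV is malformed."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalizedVariant:
    """One biallelic variant site with cohort allele statistics.

    ``pos`` is 1-based.  ``cohort_maf`` folds the alternate-allele frequency
    onto [0, 0.5] (``min(AC/AN, 1 - AC/AN)``) so that the minor-allele
    filters downstream are orientation-free.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    allele_count: int
    allele_number: int

    def __post_init__(self) -> None:
        if not _ALLELE_RE.match(self.ref) or not _ALLELE_RE.match(self.alt):
            raise ValueError(
                f"alleles must be non-empty A/C/G/T/N strings, got "
                f"ref={self.ref!r} alt={self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.allele_number <= 0:
            raise ValueError("allele_number must be > 0")
        if not 0 <= self.allele_count <= self.allele_number:
            raise ValueError("need 0 <= AC <= AN")

    @property
    def cohort_maf(self) -> float:
        af = self.allele_count / self.allele_number
        return min(af, 1.0 - af)

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_minimal(self) -> bool:
        """True when the allele pair is in minimal, anchored representation."""
        r, a = self.ref, self.alt
        if len(r) > 1 and len(a) > 1:
            return False  # shared context must have been trimmed to an anchor
        if r[-1] == a[-1] and (len(r) > 1 or len(a) > 1):
            return False  # shared suffix never survives normalization
        return True


@dataclass(frozen=True)
class GeneCatalogEntry:
    """One actionable gene: inheritance, disease category and phenotype.

    ``lof_gene`` flags genes where loss of function is an established
    disease mechanism; it gates the rare-LOF likely-pathogenic rule and is
    shipped as data, not code.
    """

    symbol: str
    inheritance: str
    category: str
    phenotype: str
    sf_version: str = "v3.1"
    lof_gene: bool = True

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_CODES:
            raise CatalogError(
                f"{self.symbol}: unknown inheritance code {self.inheritance!r}"
            )
        if self.category not in CATEGORIES:
            raise CatalogError(f"{self.symbol}: unknown category {self.category!r}")


@dataclass
class GenotypeMatrix:
    """Participant x variant allele-dosage matrix.

    Dosages are ``0``, ``1``, ``2`` or :data:`MISSING` (``-1``).  Column AC
    equals the sum of non-missing dosages and AN equals twice the number of
    non-missing calls.
    """

    participants: list[str]
    variant_keys: list[str]
    dosages: np.ndarray  # int8, shape (n_participants, n_variants)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.participants), len(self.variant_keys)):
            raise ValueError("dosage matrix shape does not match labels")
        self._col = {k: j for j, k in enumerate(self.variant_keys)}
        if len(self._col) != len(self.variant_keys):
            raise ValueError("duplicate variant keys in genotype matrix")

    def column(self, key: str) -> np.ndarray:
        try:
            return self.dosages[:, self._col[key]]
        except KeyError:
            raise KeyError(f"variant {key} absent from genotype matrix") from None

    def ac(self, key: str) -> int:
        col = self.column(key)
        return int(col[col != MISSING].sum())

    def an(self, key: str) -> int:
        col = self.column(key)
        return 2 * int((col != MISSING).sum())

    def carriers(self, key: str) -> list[str]:
        col = self.column(key)
        return [p for p, d in zip(self.participants, col) if d >= 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.participants, columns=self.variant_keys
        )


@dataclass(frozen=True)
class RawSite:
    """One VCF line before decomposition: possibly multi-allelic."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    filter: str | None  # None <=> PASS
    genotypes: tuple[tuple[int, int], ...]  # allele indices, -1 missing

    @property
    def end(self) -> int:
        """Last reference base covered, 1-based closed."""
        return self.pos + len(self.ref) - 1


# ---------------------------------------------------------------------------
# Catalog / region map / reference
# ---------------------------------------------------------------------------


def _parse_bool(cell: str) -> bool:
    return str(cell).strip().lower() in {"1", "true", "yes", "t"}


def load_gene_catalog(path: str | Path) -> dict[str, GeneCatalogEntry]:
    """Load a gene catalog TSV into an ordered ``symbol -> entry`` mapping.

    Required columns: symbol, inheritance, category, phenotype, sf_version.
    An optional ``lof_gene`` boolean column defaults to true.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"symbol", "inheritance", "category", "phenotype", "sf_version"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogError(f"catalog missing columns: {sorted(missing)}")
    catalog: dict[str, GeneCatalogEntry] = {}
    for row in df.itertuples(index=False):
        if row.symbol in catalog:
            raise CatalogError(f"duplicate gene symbol {row.symbol} in catalog")
        catalog[row.symbol] = GeneCatalogEntry(
            symbol=row.symbol,
            inheritance=row.inheritance,
            category=row.category,
            phenotype=row.phenotype,
            sf_version=row.sf_version,
            lof_gene=_parse_bool(getattr(row, "lof_gene", "1")),
        )
    return catalog


def builtin_catalog() -> dict[str, GeneCatalogEntry]:
    """The packaged ACMG secondary-findings v3.1 catalog (78 genes)."""
    from importlib.resources import files

    path = files("sftriage.data") / "acmg_sf_v3_1_catalog.tsv"
    return load_gene_catalog(str(path))


def load_region_map(
    path: str | Path, catalog: Mapping[str, GeneCatalogEntry] | None = None
) -> dict[str, IntervalTree]:
    """Load gene intervals (TSV: chrom, start, end, symbol; 1-based closed).

    Returns per-chromosome interval trees whose payload is the gene symbol.
    When ``catalog`` is given, every catalog gene must be covered.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "symbol"],
        dtype={"chrom": str, "start": int, "end": int, "symbol": str},
        comment="#",
        header=None,
    )
    trees: dict[str, IntervalTree] = {}
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.end < row.start:
            raise CatalogError(f"region for {row.symbol} has end < start")
        # store half-open internally: [start, end + 1)
        trees.setdefault(row.chrom, IntervalTree()).addi(
            row.start, row.end + 1, row.symbol
        )
        seen.add(row.symbol)
    if catalog is not None:
        uncovered = set(catalog) - seen
        if uncovered:
            raise CatalogError(
                f"region map does not cover catalog genes: {sorted(uncovered)}"
            )
    return trees


def genes_overlapping(
    trees: Mapping[str, IntervalTree], chrom: str, start: int, end: int
) -> list[str]:
    """Gene symbols whose interval overlaps [start, end] (1-based closed)."""
    tree = trees.get(chrom)
    if tree is None:
        return []
    return sorted({iv.data for iv in tree.overlap(start, end + 1)})


def fasta_fetcher(path: str | Path) -> Callable[[str, int, int], str]:
    """Return a ``fetch(chrom, start, end)`` oracle over a FASTA file.

    Coordinates are 1-based closed, matching the rest of the module.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    def fetch(chrom: str, start: int, end: int) -> str:
        return str(fasta[chrom][start - 1 : end])

    return fetch


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


def _as_diploid(genotype: Sequence[object], warn_state: dict) -> tuple[int, int]:
    """Convert a cyvcf2 genotype entry to an (a1, a2) allele pair.

    cyvcf2 yields ``[a1, a2, phased]`` for diploid calls and ``[a, phased]``
    for haploid ones.  Haploid calls are doubled (logged once); any missing
    allele makes the whole call missing.
    """
    alleles = [int(a) for a in genotype[:-1]]  # last element is the phased flag
    if len(alleles) == 1:
        if not warn_state.get("haploid"):
            log.warning("haploid genotype call(s) doubled to diploid")
            warn_state["haploid"] = True
        alleles = alleles * 2
    elif len(alleles) != 2:
        raise VcfFormatError(f"unsupported ploidy {len(alleles)}")
    a1, a2 = alleles
    if a1 < 0 or a2 < 0:
        return (MISSING, MISSING)
    return (a1, a2)


def read_vcf_samples(path: str | Path) -> list[str]:
    """Sample identifiers from the VCF header (works for empty bodies)."""
    import cyvcf2

    return list(cyvcf2.VCF(str(path)).samples)


def read_multisample_vcf(
    path: str | Path,
    region_map: Mapping[str, IntervalTree],
    skip_log: Counter | None = None,
) -> Iterator[tuple[RawSite, str, list[str]]]:
    """Stream passing-filter sites overlapping catalog gene intervals.

    Yields ``(site, gene, samples)`` triples.  Sites failing FILTER or not
    overlapping any region are counted in ``skip_log`` (keys ``non_pass``
    and ``off_gene``) and skipped.  A site overlapping several genes is
    yielded once per gene.

    Raises :class:`VcfFormatError` when the file declares no GT format field.
    """
    import cyvcf2

    skip_log = skip_log if skip_log is not None else Counter()
    vcf = cyvcf2.VCF(str(path))
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise VcfFormatError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    warn_state: dict = {}
    for rec in vcf:
        if rec.FILTER is not None:  # cyvcf2: None <=> PASS or '.'
            skip_log["non_pass"] += 1
            log.info("skip non-PASS site %s:%s (%s)", rec.CHROM, rec.POS, rec.FILTER)
            continue
        site = RawSite(
            chrom=rec.CHROM,
            pos=rec.POS,
            ref=rec.REF,
            alts=tuple(rec.ALT),
            filter=rec.FILTER,
            genotypes=tuple(_as_diploid(g, warn_state) for g in rec.genotypes),
        )
        genes = genes_overlapping(region_map, site.chrom, site.pos, site.end)
        if not genes:
            skip_log["off_gene"] += 1
            log.info("skip off-gene site %s:%s", site.chrom, site.pos)
            continue
        for gene in genes:
            yield site, gene, samples


# ---------------------------------------------------------------------------
# Decomposition and normalization
# ---------------------------------------------------------------------------


def decompose_multiallelic(
    site: RawSite, skip_log: Counter | None = None
) -> list[tuple[str, int, str, str, np.ndarray]]:
    """Split a raw site into one biallelic record per ALT allele.

    Returns ``(chrom, pos, ref, alt, dosages)`` tuples; ``dosages`` holds
    per-sample counts of the record's ALT allele (other ALT alleles count as
    reference), with :data:`MISSING` for missing calls.  Spanning-deletion
    alleles (``*``) are dropped and logged.
    """
    skip_log = skip_log if skip_log is not None else Counter()
    out = []
    for k, alt in enumerate(site.alts, start=1):
        if alt == "*":
            skip_log["spanning_allele"] += 1
            log.info("drop spanning allele at %s:%s", site.chrom, site.pos)
            continue
        dosages = np.empty(len(site.genotypes), dtype=np.int8)
        for i, (a1, a2) in enumerate(site.genotypes):
            if a1 == MISSING:
                dosages[i] = MISSING
            else:
                dosages[i] = int(a1 == k) + int(a2 == k)
        out.append((site.chrom, site.pos, site.ref, alt, dosages))
    return out


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    ref_fetch: Callable[[str, int, int], str] | None = None,
) -> tuple[str, int, str, str]:
    """Reduce an allele pair to its minimal, left-aligned representation.

    Implements the standard normalization recursion: trim shared trailing
    bases (extending left from the reference when an allele would empty),
    then trim shared leading bases down to a single anchor.  Left extension
    requires a reference oracle; without one, trimming is still performed
    but left-alignment across repeat copies is skipped with a warning.

    The operation is idempotent.  Raises :class:`ReferenceMismatchError`
    when REF disagrees with the oracle.
    """
    if not _ALLELE_RE.match(ref) or not _ALLELE_RE.match(alt):
        raise ValueError(f"alleles must be non-empty A/C/G/T/N strings: {ref}/{alt}")
    if ref_fetch is not None:
        expected = ref_fetch(chrom, pos, pos + len(ref) - 1)
        if expected != ref:
            raise ReferenceMismatchError(
                f"{chrom}:{pos} REF={ref} disagrees with reference ({expected})"
            )
    warned = False
    while True:
        # trim shared suffix
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if len(ref) == 1 or len(alt) == 1:
                if ref_fetch is None:
                    if not warned:
                        log.warning(
                            "no reference oracle: left-alignment skipped at %s:%s",
                            chrom,
                            pos,
                        )
                        warned = True
                    break
                if pos == 1:
                    break  # cannot extend past the contig start
                base = ref_fetch(chrom, pos - 1, pos - 1)
                pos -= 1
                ref = base + ref
                alt = base + alt
            ref = ref[:-1]
            alt = alt[:-1]
            continue
        break
    # trim shared prefix down to one anchor base
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1
    return (chrom, pos, ref, alt)


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------


def _absent_if_blank(cell: object) -> str | None:
    s = "" if cell is None else str(cell).strip()
    return s if s else None


def load_annotation_table(path: str | Path):
    """Load the per-variant/per-transcript annotation TSV.

    Returns a ``dict`` mapping variant key (``chrom:pos:ref:alt``) to the
    list of :class:`~sftriage.transcript_select.TranscriptAnnotation` rows
    for that variant.  Blank cells become explicit ``None`` ("absent")
    markers.  Unknown columns are ignored.

    Raises :class:`AnnotationTableError` on a missing mandatory column or a
    duplicate (variant, transcript) key.
    """
    from .transcript_select import TranscriptAnnotation

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationTableError(f"annotation table missing columns: {sorted(missing)}")

    table: dict[str, list[TranscriptAnnotation]] = {}
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        key = f"{row.chrom}:{int(row.pos)}:{row.ref}:{row.alt}"
        tx = row.transcript_id
        if (key, tx) in seen:
            raise AnnotationTableError(f"duplicate annotation for {key} / {tx}")
        seen.add((key, tx))
        consequence = tuple(
            t for t in re.split(r"[&,]", row.consequence) if t
        )
        stars = _absent_if_blank(row.clinvar_stars)
        revel = _absent_if_blank(row.revel)
        gnomad = _absent_if_blank(row.gnomad_af)
        tlen = _absent_if_blank(row.transcript_length)
        ann = TranscriptAnnotation(
            transcript_id=tx,
            is_mane=_parse_bool(row.is_mane),
            consequence=consequence,
            impact=row.impact,
            transcript_length=int(tlen) if tlen is not None else 0,
            clinvar_significance=_absent_if_blank(row.clinvar_significance),
            clinvar_stars=int(stars) if stars is not None else None,
            hgmd_class=_absent_if_blank(row.hgmd_class),
            revel=float(revel) if revel is not None else None,
            pvs1_strength=_absent_if_blank(row.pvs1_strength),
            external_verdict=_absent_if_blank(row.external_verdict),
            gnomad_af=float(gnomad) if gnomad is not None else None,
            dbsnp_id=_absent_if_blank(row.dbsnp_id),
            gene=row.gene,
        )
        table.setdefault(key, []).append(ann)
    return table


# ---------------------------------------------------------------------------
# VCF writing (round-trip support and fixtures)
# ---------------------------------------------------------------------------

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FILTER=<ID=LowQual,Description="Low quality site">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_genotype_vcf(
    gm: GenotypeMatrix,
    variants: Sequence[NormalizedVariant],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write biallelic variants and dosages as a minimal multisample VCF.

    Dosage 1 is emitted as ``0/1``, dosage 2 as ``1/1`` and missing as
    ``./.``, so re-reading the file reproduces the matrix exactly.
    """
    by_key = {v.key: v for v in variants}
    unknown = [k for k in gm.variant_keys if k not in by_key]
    if unknown:
        raise ValueError(f"variants missing for matrix columns: {unknown[:3]}")
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = [_VCF_HEADER]
    if contig_lengths:
        for contig, length in contig_lengths.items():
            lines.append(f"##contig=<ID={contig},length={length}>\n")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.participants)
        + "\n"
    )
    order = sorted(gm.variant_keys, key=lambda k: (by_key[k].chrom, by_key[k].pos, by_key[k].alt))
    for key in order:
        v = by_key[key]
        col = gm.column(key)
        gts = "\t".join(gt_code[int(d)] for d in col)
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n"
        )
    Path(path).write_text("".join(lines))
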