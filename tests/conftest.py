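from __future__ import annotations

import json

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sftriage.io_formats import GeneCatalogEntry, NormalizedVariant, builtin_catalog
from sftriage.synthetic_data import (
    demo_config,
    full_cohort_config,
    write_fixture_bundle,
)
from sftriage.transcript_select import TranscriptAnnotation


@pytest.fixture(scope="session")
def catalog():
    return builtin_catalog()


def make_variant(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="G",
    gene="BRCA2",
    ac=2,
    an=4000,
) -> NormalizedVariant:
    return NormalizedVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        allele_count=ac, allele_number=an,
    )


def make_ann(
    transcript_id="ENST00000000001",
    is_mane=True,
    consequence=("missense_variant",),
    impact="MODERATE",
    transcript_length=3000,
    **kwargs,
) -> TranscriptAnnotation:
    return TranscriptAnnotation(
        transcript_id=transcript_id,
        is_mane=is_mane,
        consequence=tuple(consequence),
        impact=impact,
        transcript_length=transcript_length,
        **kwargs,
    )


def make_entry(
    symbol="BRCA2",
    inheritance="AD",
    category="cancer",
    phenotype="Hereditary breast and/or ovarian cancer",
    lof_gene=True,
) -> GeneCatalogEntry:
    return GeneCatalogEntry(
        symbol=symbol, inheritance=inheritance, category=category,
        phenotype=phenotype, lof_gene=lof_gene,
    )


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("demo_bundle")
    paths = write_fixture_bundle(demo_config(seed=1), outdir)
    return paths


@pytest.fixture(scope="session")
def full_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("full_bundle")
    paths = write_fixture_bundle(full_cohort_config(seed=1), outdir)
    return paths


def bundle_run_config(paths) -> dict:
    return {
        k: str(v)
        for k, v in paths.items()
        if k in ("vcf", "annotations", "phenotypes", "catalog", "regions", "reference")
    }


def load_truth(paths) -> dict:
    with open(paths["truth"]) as fh:
        return json.load(fh)
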