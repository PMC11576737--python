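"""Independent oracles used to cross-check the implementation.

Everything here is deliberately written from first principles — flat
rule re-derivations, exact integer enumeration, haplotype-equivalence
search — and never calls into the code paths it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


# ---------------------------------------------------------------------------
# Brute-force variant classifier
# ---------------------------------------------------------------------------

LOF_TERMS = {
    "stop_gained",
    "frameshift_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "inframe_insertion",
    "inframe_deletion",
}


def brute_force_classify(
    *,
    clinvar: str | None,
    stars: int | None,
    hgmd: str | None,
    consequences: tuple[str, ...],
    impact: str,
    pvs1: str | None,
    revel: float | None,
    verdict: str | None,
    dbsnp: str | None,
    cohort_maf: float,
    gnomad_af: float | None,
    carriers: int,
    gene_category: str,
    lof_gene: bool,
    cohort_evidence: bool,
    global_maf_max: float = 0.02,
    rare_maf_max: float = 0.001,
    revel_min: float = 0.7,
    min_carriers: int = 2,
    min_stars: int = 2,
) -> str:
    """Flat, independent restatement of the triage rules."""
    plp = clinvar in ("P", "LP", "P/LP")
    if cohort_maf >= global_maf_max:
        return "rejected"
    if clinvar in ("B", "LB", "B/LB"):
        return "rejected"
    # conflicting databases exclude the variant from the pathogenic lists
    # without forwarding it anywhere else
    if plp and hgmd is not None and hgmd != "DM":
        return "unclassified"
    if plp and hgmd == "DM":
        return "P1"
    if plp and hgmd is None and stars is not None and stars >= min_stars:
        return "P2"
    rare = cohort_maf < rare_maf_max and (gnomad_af is None or gnomad_af < rare_maf_max)
    if (
        bool(set(consequences) & LOF_TERMS)
        and pvs1 == "VeryStrong"
        and impact == "HIGH"
        and rare
        and lof_gene
    ):
        return "LP1"
    novel = clinvar is None and hgmd is None and gnomad_af is None and dbsnp is None
    eligible = clinvar in ("VUS", "conflicting") or novel
    if (
        "missense_variant" in consequences
        and eligible
        and rare
        and carriers >= min_carriers
        and revel is not None
        and revel > revel_min
        and gene_category in ("cancer", "cardiovascular")
        and cohort_evidence
    ):
        return "LP2" if verdict in ("P", "LP") else "pVUS"
    return "unclassified"


# ---------------------------------------------------------------------------
# Exact Fisher p-value by hypergeometric enumeration
# ---------------------------------------------------------------------------


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer enumeration of the null.

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities no greater than the observed table's (ties included),
    using exact rational arithmetic.
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    total = sum(weights.values())
    w_obs = weights[a]
    tail = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(tail, total))


# ---------------------------------------------------------------------------
# Normalization equivalence search
# ---------------------------------------------------------------------------


def minimal_leftmost_representation(
    seq: str, pos: int, ref: str, alt: str, window: int = 30, max_len: int = 12
) -> tuple[int, str, str]:
    """Exhaustively search all representations equivalent to (pos, ref, alt).

    Builds the alternate haplotype, enumerates every (p, r, a) with
    non-empty alleles of bounded length that reproduces it, and returns
    the one with minimal combined allele length, breaking ties by smallest
    position.  ``pos`` is 1-based; ``seq`` is the full contig.
    """
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref, "input REF must match contig"
    alt_hap = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]
    delta = len(alt_hap) - len(seq)
    candidates: list[tuple[int, int, str, str]] = []
    for p in range(max(1, pos - window), min(len(seq), pos + window) + 1):
        for lr in range(0, max_len + 1):
            la = lr + delta
            if la < 0 or la > max_len:
                continue
            if lr == 0 or la == 0:
                continue  # VCF requires non-empty alleles
            r = seq[p - 1 : p - 1 + lr]
            if len(r) < lr:
                continue
            a = alt_hap[p - 1 : p - 1 + la]
            if len(a) < la:
                continue
            if seq[: p - 1] + a + seq[p - 1 + lr :] == alt_hap:
                if r != a:
                    candidates.append((lr + la, p, r, a))
    assert candidates, "no equivalent representation found in window"
    _, p, r, a = min(candidates)
    return (p, r, a)
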