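"""Single-transcript selection for classification.

Effect predictors annotate every transcript of a gene; the triage rules
need exactly one annotation per variant.  Selection follows the MANE-first
policy: the MANE transcript when one is flagged, otherwise the transcript
whose most severe consequence ranks highest in the packaged severity table,
with ties broken by transcript length (longest wins) and finally by
lexicographically smallest transcript identifier so the choice is
deterministic.

The severity table is a frozen copy of the published Ensembl consequence
ordering shipped with the package, so results never drift with an external
release.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

__all__ = [
    "TranscriptAnnotation",
    "UnknownConsequenceError",
    "TranscriptSelectionError",
    "severity_table",
    "rank_consequence",
    "most_severe_rank",
    "select_transcript",
]

IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER")


class UnknownConsequenceError(ValueError):
    """A consequence term is absent from the packaged severity table."""


class TranscriptSelectionError(ValueError):
    """The annotation set is inconsistent (e.g. two MANE transcripts)."""


@dataclass(frozen=True)
class TranscriptAnnotation:
    """All external evidence for one variant on one transcript.

    ``None`` means the field is absent from the upstream source — never a
    default value.  ``consequence`` is the ordered set of sequence-ontology
    terms the predictor reported for this transcript.
    """

    transcript_id: str
    is_mane: bool
    consequence: tuple[str, ...]
    impact: str
    transcript_length: int
    clinvar_significance: str | None = None
    clinvar_stars: int | None = None
    hgmd_class: str | None = None
    revel: float | None = None
    pvs1_strength: str | None = None
    external_verdict: str | None = None
    gnomad_af: float | None = None
    dbsnp_id: str | None = None
    gene: str = ""

    def __post_init__(self) -> None:
        if self.clinvar_stars is not None and self.clinvar_significance is None:
            raise ValueError(
                f"{self.transcript_id}: review stars present without a ClinVar "
                "significance"
            )
        if self.revel is not None and not 0.0 <= self.revel <= 1.0:
            raise ValueError(f"REVEL score out of [0, 1]: {self.revel}")


@lru_cache(maxsize=1)
def severity_table() -> tuple[str, ...]:
    """The packaged consequence terms, most severe first."""
    from importlib.resources import files

    text = (files("sftriage.data") / "consequence_severity.txt").read_text()
    terms = tuple(
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )
    return terms


@lru_cache(maxsize=None)
def rank_consequence(term: str) -> int:
    """Severity rank of a consequence term; lower is more severe."""
    table = severity_table()
    try:
        return table.index(term)
    except ValueError:
        raise UnknownConsequenceError(
            f"consequence term {term!r} is not in the packaged severity table"
        ) from None


def most_severe_rank(ann: TranscriptAnnotation) -> int:
    """Best (minimum) severity rank over the transcript's consequence terms."""
    if not ann.consequence:
        raise ValueError(f"{ann.transcript_id}: no consequence terms")
    return min(rank_consequence(t) for t in ann.consequence)


def select_transcript(
    annotations: Sequence[TranscriptAnnotation],
) -> TranscriptAnnotation:
    """Pick the single annotation used for all downstream classification.

    Pure in its input: permuting ``annotations`` never changes the choice.
    """
    if not annotations:
        raise ValueError("no transcript annotations to select from")
    mane = [a for a in annotations if a.is_mane]
    if len(mane) > 1:
        ids = sorted(a.transcript_id for a in mane)
        raise TranscriptSelectionError(f"multiple MANE transcripts flagged: {ids}")
    if mane:
        return mane[0]
    return min(
        annotations,
        key=lambda a: (most_severe_rank(a), -a.transcript_length, a.transcript_id),
    )
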