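"""Splice-junction chains, motif classification and chain validation.

The validation stage implements the toolkit's central quality-control rule:
a long-read isoform model is kept only if EVERY intron in its chain has an
exact-coordinate short-read junction record. Exact matching is deliberate —
any tolerance window would silently admit wobbly junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

from .formats import (
    GenomeAccessor,
    IntegrityError,
    SJTable,
    TranscriptModel,
    reverse_complement,
)

#: donor/acceptor dinucleotide pairs, read in transcription orientation
CANONICAL_PAIRS = frozenset({("GT", "AG"), ("GC", "AG"), ("AT", "AC")})

VALID = "valid"
INVALID = "invalid"
MONO_EXON = "mono_exon"


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """An intron: [start, end) with start = first intron base."""

    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start < 4:
            raise IntegrityError(
                f"intron [{self.start}, {self.end}) too short to carry "
                "donor and acceptor dinucleotides"
            )


SJChain = Tuple[SpliceJunction, ...]


@dataclass(frozen=True)
class JunctionMotif:
    donor: str
    acceptor: str

    @property
    def canonical(self) -> bool:
        return (self.donor, self.acceptor) in CANONICAL_PAIRS


@dataclass(frozen=True)
class ValidationOutcome:
    isoform_id: str
    status: str  # valid | invalid | mono_exon
    missing_junctions: Tuple[SpliceJunction, ...] = ()
    min_support_observed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.status == VALID and self.missing_junctions:
            raise IntegrityError("valid outcome cannot list missing junctions")
        if self.status == INVALID and not self.missing_junctions:
            raise IntegrityError("invalid outcome must list missing junctions")


@dataclass(frozen=True)
class ValidationConfig:
    min_unique: int = 1
    keep_mono_exon: bool = True


def junctions_of(transcript: TranscriptModel) -> SJChain:
    """The ordered intron chain of a transcript; empty for mono-exon."""
    return tuple(
        SpliceJunction(transcript.chrom, transcript.strand, a.end, b.start)
        for a, b in zip(transcript.exons, transcript.exons[1:])
    )


def chain_key(transcript: TranscriptModel) -> Tuple:
    """Hashable identity of a transcript's intron chain."""
    return (
        transcript.chrom,
        transcript.strand,
        tuple((j.start, j.end) for j in junctions_of(transcript)),
    )


def classify_junction_motif(
    sj: SpliceJunction, genome: GenomeAccessor
) -> JunctionMotif:
    """Donor/acceptor dinucleotides in transcription orientation.

    Canonical pairs are GT-AG, GC-AG and AT-AC; anything else is
    non-canonical.
    """
    left = genome.fetch(sj.chrom, sj.start, sj.start + 2)
    right = genome.fetch(sj.chrom, sj.end - 2, sj.end)
    if sj.strand == "-":
        return JunctionMotif(
            donor=reverse_complement(right), acceptor=reverse_complement(left)
        )
    return JunctionMotif(donor=left, acceptor=right)


def validate_chain(
    chain: Sequence[SpliceJunction],
    table: SJTable,
    min_unique: int = 1,
    isoform_id: str = "",
) -> ValidationOutcome:
    """Check that every junction of the chain has exact short-read support.

    A junction is supported when the table holds a record at the same
    (chrom, start, end) whose strand equals the chain's (or is '.'), with
    unique_reads >= min_unique.
    """
    if not chain:
        return ValidationOutcome(isoform_id, MONO_EXON)
    missing: List[SpliceJunction] = []
    supports: List[int] = []
    for sj in chain:
        rec = table.lookup(sj.chrom, sj.strand, sj.start, sj.end)
        if rec is None or rec.unique_reads < min_unique:
            missing.append(sj)
        else:
            supports.append(rec.unique_reads)
    if missing:
        return ValidationOutcome(
            isoform_id,
            INVALID,
            tuple(missing),
            min(supports) if supports else None,
        )
    return ValidationOutcome(isoform_id, VALID, (), min(supports))


def filter_isoforms(
    isoforms: Sequence[TranscriptModel],
    table: SJTable,
    config: ValidationConfig = ValidationConfig(),
) -> Tuple[List[TranscriptModel], List[ValidationOutcome]]:
    """Keep isoforms whose complete junction chain is short-read supported.

    Returns (retained isoforms in input order, one outcome per input).
    Mono-exon isoforms carry no chain to validate; by default they are
    retained and flagged rather than silently filtered.
    """
    retained: List[TranscriptModel] = []
    report: List[ValidationOutcome] = []
    for iso in isoforms:
        outcome = validate_chain(
            junctions_of(iso), table, config.min_unique, iso.transcript_id
        )
        report.append(outcome)
        if outcome.status == VALID or (
            outcome.status == MONO_EXON and config.keep_mono_exon
        ):
            retained.append(iso)
    return retained, report
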