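"""Readers/writers for the external formats the toolkit touches.

All in-memory coordinates are 0-based half-open. GTF (1-based inclusive)
and STAR ``SJ.out.tab`` (1-based inclusive intron bounds) are converted at
the parse/write boundary; no other module performs +/-1 arithmetic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from Bio import SeqIO

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """A line of an input file could not be interpreted."""


class IntegrityError(ValueError):
    """Parsed records violate a structural invariant (e.g. mixed strands)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntegrityError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise IntegrityError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise IntegrityError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded exon chain: the toolkit's universal currency.

    Exons are sorted ascending, non-overlapping, separated by at least one
    base (introns have positive length), and all share chrom/strand.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise IntegrityError(
                f"{self.transcript_id}: transcript strand must be + or -"
            )
        if not self.exons:
            raise IntegrityError(f"{self.transcript_id}: needs >= 1 exon")
        object.__setattr__(self, "exons", tuple(self.exons))
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise IntegrityError(
                    f"{self.transcript_id}: exon chrom {ex.chrom} != {self.chrom}"
                )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise IntegrityError(
                    f"{self.transcript_id}: exons must be sorted with "
                    f"positive-length introns ({a.end} !< {b.start})"
                )

    @classmethod
    def from_coords(
        cls,
        transcript_id: str,
        gene_id: str,
        chrom: str,
        strand: str,
        exons: Iterable[Tuple[int, int]],
    ) -> "TranscriptModel":
        ivs = tuple(
            GenomicInterval(chrom, s, e, strand) for s, e in sorted(exons)
        )
        return cls(transcript_id, gene_id, chrom, strand, ivs)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_coords(self) -> Tuple[Tuple[int, int], ...]:
        return tuple((e.start, e.end) for e in self.exons)

    @property
    def length(self) -> int:
        """Spliced (mature transcript) length in nucleotides."""
        return sum(len(e) for e in self.exons)

    def with_ids(self, transcript_id=None, gene_id=None) -> "TranscriptModel":
        return replace(
            self,
            transcript_id=transcript_id or self.transcript_id,
            gene_id=gene_id or self.gene_id,
        )


@dataclass
class AnnotationSet:
    """Reference annotation: gene_id -> transcripts."""

    genes: Dict[str, List[TranscriptModel]]
    provenance: Optional[str] = None

    def __post_init__(self) -> None:
        seen: set = set()
        for gid, txs in self.genes.items():
            for t in txs:
                if t.gene_id != gid:
                    raise IntegrityError(
                        f"transcript {t.transcript_id} filed under {gid} "
                        f"but carries gene_id {t.gene_id}"
                    )
                if t.transcript_id in seen:
                    raise IntegrityError(
                        f"duplicate transcript_id {t.transcript_id}"
                    )
                seen.add(t.transcript_id)

    def transcripts(self) -> Iterator[TranscriptModel]:
        for txs in self.genes.values():
            yield from txs

    @property
    def n_transcripts(self) -> int:
        return sum(len(v) for v in self.genes.values())


@dataclass(frozen=True)
class SJRecord:
    """One short-read splice junction (intron) with its read support."""

    junction: GenomicInterval
    motif_code: int = 0
    annotated_flag: int = 0
    unique_reads: int = 0
    multi_reads: int = 0
    max_overhang: int = 0

    def __post_init__(self) -> None:
        if self.unique_reads < 0 or self.multi_reads < 0:
            raise IntegrityError("read counts must be >= 0")


class SJTable:
    """Exact-coordinate lookup of short-read junction evidence.

    Records with strand '.' (STAR strand code 0) are retrievable from
    either strand; discarding them would bias validation against one
    strand's genes.
    """

    def __init__(self, records: Iterable[SJRecord] = ()) -> None:
        self._by_key: Dict[Tuple[str, str, int, int], SJRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SJRecord) -> None:
        j = rec.junction
        key = (j.chrom, j.strand, j.start, j.end)
        old = self._by_key.get(key)
        if old is not None:
            # duplicate rows: keep the better-supported one, deterministically
            logger.warning("duplicate SJ record at %s; keeping max support", key)
            if rec.unique_reads <= old.unique_reads:
                return
        self._by_key[key] = rec

    def lookup(
        self, chrom: str, strand: str, start: int, end: int
    ) -> Optional[SJRecord]:
        """Exact-coordinate lookup; strand '.' records match any strand."""
        rec = self._by_key.get((chrom, strand, start, end))
        if rec is None and strand != ".":
            rec = self._by_key.get((chrom, ".", start, end))
        return rec

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[SJRecord]:
        return iter(
            self._by_key[k] for k in sorted(self._by_key)
        )


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str) -> AnnotationSet:
    """Read exon features from a GTF2.2 file into an :class:`AnnotationSet`.

    Only ``exon`` features are used; ``gene_id`` and ``transcript_id``
    attributes are mandatory, all other attributes are ignored. GTF's
    1-based inclusive coordinates become 0-based half-open.
    """
    exons: Dict[str, List[GenomicInterval]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "exon":
                continue
            chrom, strand = fields[0], fields[6]
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinates") from exc
            attrs = dict(_ATTR_RE.findall(fields[8]))
            if "transcript_id" not in attrs:
                raise ParseError(
                    f"{path}:{lineno}: exon line lacks transcript_id attribute"
                )
            if "gene_id" not in attrs:
                raise ParseError(
                    f"{path}:{lineno}: exon line lacks gene_id attribute"
                )
            tid, gid = attrs["transcript_id"], attrs["gene_id"]
            prev = meta.get(tid)
            if prev is None:
                meta[tid] = (gid, chrom, strand)
            elif prev[1] != chrom or prev[2] != strand:
                raise IntegrityError(
                    f"{path}: transcript {tid} has exons on mixed "
                    "chromosomes/strands"
                )
            exons.setdefault(tid, []).append(
                GenomicInterval(chrom, start1 - 1, end1, strand)
            )
    genes: Dict[str, List[TranscriptModel]] = {}
    for tid in sorted(exons):
        gid, chrom, strand = meta[tid]
        tx = TranscriptModel(
            tid, gid, chrom, strand, tuple(sorted(exons[tid]))
        )
        genes.setdefault(gid, []).append(tx)
    return AnnotationSet(genes=genes, provenance=str(path))


def write_gtf(annotation: AnnotationSet, path: str) -> None:
    """Write one exon line per exon; byte-deterministic given the set."""
    txs = sorted(
        annotation.transcripts(),
        key=lambda t: (t.chrom, t.start, t.transcript_id),
    )
    with open(path, "w") as fh:
        fh.write("##gff-version 2.2\n")
        for t in txs:
            for ex in t.exons:
                fh.write(
                    f"{t.chrom}\tsjkit\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{t.strand}\t.\t"
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";\n'
                )


# ---------------------------------------------------------------------------
# STAR SJ.out.tab

_STAR_STRAND = {"0": ".", "1": "+", "2": "-"}


def read_star_sj(path: str) -> SJTable:
    """Read a STAR ``SJ.out.tab`` (9 columns) into an :class:`SJTable`.

    Columns 2/3 are the 1-based first and last intron bases; internally
    the intron becomes the half-open interval [col2-1, col3).
    """
    table = SJTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            try:
                start = int(f[1]) - 1
                end = int(f[2])
                motif = int(f[4])
                annotated = int(f[5])
                uniq = int(f[6])
                multi = int(f[7])
                overhang = int(f[8])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field") from exc
            strand = _STAR_STRAND.get(f[3])
            if strand is None:
                raise ParseError(f"{path}:{lineno}: bad strand code {f[3]}")
            table.add(
                SJRecord(
                    GenomicInterval(f[0], start, end, strand),
                    motif_code=motif,
                    annotated_flag=annotated,
                    unique_reads=uniq,
                    multi_reads=multi,
                    max_overhang=overhang,
                )
            )
    return table


def write_star_sj(table: SJTable, path: str) -> None:
    inv = {".": "0", "+": "1", "-": "2"}
    with open(path, "w") as fh:
        for rec in table:
            j = rec.junction
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        j.chrom,
                        j.start + 1,
                        j.end,
                        inv[j.strand],
                        rec.motif_code,
                        rec.annotated_flag,
                        rec.unique_reads,
                        rec.multi_reads,
                        rec.max_overhang,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED12

def _split_name(name: str) -> Tuple[str, str]:
    # BED12 has no gene column; allow "gene|transcript" encoded names
    if "|" in name:
        gid, tid = name.split("|", 1)
        return gid, tid
    return name, name


def read_isoform_alignments(path: str, format: str = "BED12") -> List[TranscriptModel]:
    """Read long-read isoform models as exon chains (BED12 or GTF).

    Records with undefined strand are skipped with a warning: a transcript
    model without orientation cannot be validated or classified.
    """
    fmt = format.upper()
    if fmt == "GTF":
        return sorted(
            read_gtf(path).transcripts(),
            key=lambda t: (t.chrom, t.start, t.transcript_id),
        )
    if fmt != "BED12":
        raise ValueError(f"unsupported isoform format {format!r}")
    out: List[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, name, strand = f[0], f[3], f[5]
            if strand not in ("+", "-"):
                logger.warning(
                    "%s:%d: record %s has undefined strand; skipped",
                    path, lineno, name,
                )
                continue
            try:
                chrom_start = int(f[1])
                block_count = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad numeric field") from exc
            if len(sizes) != block_count or len(starts) != block_count:
                raise ParseError(
                    f"{path}:{lineno}: blockCount={block_count} inconsistent "
                    f"with block lists"
                )
            exons = [
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            gid, tid = _split_name(name)
            out.append(
                TranscriptModel.from_coords(tid, gid, chrom, strand, exons)
            )
    return out


def write_bed12(isoforms: Iterable[TranscriptModel], path: str) -> None:
    txs = sorted(isoforms, key=lambda t: (t.chrom, t.start, t.transcript_id))
    with open(path, "w") as fh:
        for t in txs:
            sizes = ",".join(str(len(e)) for e in t.exons)
            starts = ",".join(str(e.start - t.start) for e in t.exons)
            name = (
                t.transcript_id
                if t.gene_id == t.transcript_id
                else f"{t.gene_id}|{t.transcript_id}"
            )
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        t.chrom, t.start, t.end, name, 0, t.strand,
                        t.start, t.end, 0, t.n_exons, sizes, starts,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeAccessor:
    """Random access into genome sequences, always uppercase, 0-based half-open."""

    def __init__(self, sequences: Dict[str, str]) -> None:
        self._seqs = {name: s.upper() for name, s in sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise LookupError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"query [{start}, {end}) out of range for {chrom} "
                f"(length {len(seq)})"
            )
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}


def read_genome_fasta(path: str) -> GenomeAccessor:
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seqs:
            raise IntegrityError(f"duplicate FASTA record name {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return GenomeAccessor(seqs)


def write_genome_fasta(sequences: Dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            s = sequences[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
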