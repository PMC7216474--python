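"""Local alternative-splicing events and condition comparison.

Events are generated pairwise over the transcripts of a gene and
deduplicated by their defining coordinates (variant-pair semantics, no
splicing graph). Seven types are recognised:

SE  exon skipping               A5/A3  alternative 5'/3' splice site
MX  mutually exclusive exons    RI     intron retention
AF/AL alternative first/last exon

Genomic patterns are matched first and mirrored by strand at emission
time: e.g. the shared-genomic-end / variant-genomic-start junction pair is
an A5 on '+' and an A3 on '-'.

Boundary conventions (shared by the brute-force test oracle):

* A5/A3 — the outer junction's variant boundary must fall STRICTLY inside
  the partner's flanking exon; the boundary-touching case is the
  alternative-first/last-exon pattern.
* RI — the retaining exon extends strictly beyond both intron boundaries.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

from .formats import IntegrityError, TranscriptModel
from .junctions import junctions_of

EVENT_TYPES = ("SE", "A5", "A3", "MX", "RI", "AF", "AL")


@dataclass(frozen=True)
class ASEvent:
    gene_id: str
    event_type: str
    chrom: str
    strand: str
    coordinates: Tuple[int, ...]
    inclusion_isoforms: Tuple[str, ...]
    exclusion_isoforms: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if not self.inclusion_isoforms or not self.exclusion_isoforms:
            raise ValueError("event needs witnesses on both sides")

    @property
    def key(self) -> Tuple:
        return (self.gene_id, self.event_type, self.coordinates)


EventKey = Tuple[str, str, Tuple[int, ...]]


def _tx_arrays(t: TranscriptModel):
    exons = t.exon_coords
    juncs = tuple((a[1], b[0]) for a, b in zip(exons, exons[1:]))
    return exons, juncs


def _pair_events(ta: TranscriptModel, tb: TranscriptModel) -> List[Tuple]:
    """All events between an (ordered-irrelevant) transcript pair.

    Returns tuples (event_type, coordinates, inclusion_id, exclusion_id).
    """
    out: List[Tuple] = []
    strand = ta.strand
    for x, y in ((ta, tb), (tb, ta)):
        ex_x, j_x = _tx_arrays(x)
        ex_y, j_y = _tx_arrays(y)
        jset_y = set(j_y)

        # SE: x shows the internal exon, y skips it with one junction
        for i in range(len(j_x) - 1):
            e1, s2 = j_x[i]
            e2, s3 = j_x[i + 1]
            if (e1, s3) in jset_y:
                out.append(
                    ("SE", (e1, s2, e2, s3), x.transcript_id, y.transcript_id)
                )

        # RI: y's single exon strictly covers one of x's introns
        for e1, s2 in j_x:
            for xs, xe in ex_y:
                if xs < e1 and xe > s2:
                    out.append(
                        (
                            "RI",
                            (xs, e1, s2, xe),
                            y.transcript_id,
                            x.transcript_id,
                        )
                    )

        # MX: shared outer boundaries, non-overlapping internal exons
        for i in range(len(j_x) - 1):
            a1, b1 = j_x[i]
            a2, b2 = j_x[i + 1]
            for k in range(len(j_y) - 1):
                c1, d1 = j_y[k]
                c2, d2 = j_y[k + 1]
                if a1 != c1 or b2 != d2:
                    continue
                exon_x = (b1, a2)
                exon_y = (d1, c2)
                if exon_x == exon_y:
                    continue
                if exon_x[1] <= exon_y[0] or exon_y[1] <= exon_x[0]:
                    first, second = sorted((exon_x, exon_y))
                    coords = (a1, *first, *second, b2)
                    incl, excl = (
                        (x.transcript_id, y.transcript_id)
                        if exon_x <= exon_y
                        else (y.transcript_id, x.transcript_id)
                    )
                    out.append(("MX", coords, incl, excl))

    # A5/A3: scan unordered junction pairs once
    ex_a, j_a = _tx_arrays(ta)
    ex_b, j_b = _tx_arrays(tb)
    for sa, ea in j_a:
        for sb, eb in j_b:
            if ea == eb and sa != sb:
                # shared genomic end; inner = larger start (shorter intron)
                (s_out, t_out), (s_in, t_in) = sorted(
                    [(sa, ta), (sb, tb)], key=lambda p: p[0]
                )
                flank = next(
                    (
                        (fs, fe)
                        for fs, fe in t_in.exon_coords
                        if fe == s_in
                    ),
                    None,
                )
                if flank is not None and flank[0] < s_out:
                    etype = "A5" if strand == "+" else "A3"
                    out.append(
                        (
                            etype,
                            (s_out, ea, s_in, ea),
                            t_in.transcript_id,
                            t_out.transcript_id,
                        )
                    )
            elif sa == sb and ea != eb:
                # shared genomic start; inner = smaller end
                (e_in, t_in), (e_out, t_out) = sorted(
                    [(ea, ta), (eb, tb)], key=lambda p: p[0]
                )
                flank = next(
                    (
                        (fs, fe)
                        for fs, fe in t_in.exon_coords
                        if fs == e_in
                    ),
                    None,
                )
                if flank is not None and flank[1] > e_out:
                    etype = "A3" if strand == "+" else "A5"
                    out.append(
                        (
                            etype,
                            (sa, e_in, sa, e_out),
                            t_in.transcript_id,
                            t_out.transcript_id,
                        )
                    )

    # AF/AL: non-overlapping terminal exons splicing to a shared boundary
    if len(ta.exons) >= 2 and len(tb.exons) >= 2:
        # genomic-left pattern: first exons, first junctions share their end
        fa, fb = ta.exon_coords[0], tb.exon_coords[0]
        ja0, jb0 = j_a[0], j_b[0]
        if (
            ja0[1] == jb0[1]
            and ja0[0] != jb0[0]
            and (fa[1] <= fb[0] or fb[1] <= fa[0])
        ):
            first, second = sorted((fa, fb))
            etype = "AF" if strand == "+" else "AL"
            incl, excl = (
                (ta.transcript_id, tb.transcript_id)
                if fa <= fb
                else (tb.transcript_id, ta.transcript_id)
            )
            out.append(
                ("%s" % etype, (*first, *second, ja0[1]), incl, excl)
            )
        # genomic-right pattern: last exons, last junctions share their start
        la, lb = ta.exon_coords[-1], tb.exon_coords[-1]
        jan, jbn = j_a[-1], j_b[-1]
        if (
            jan[0] == jbn[0]
            and jan[1] != jbn[1]
            and (la[1] <= lb[0] or lb[1] <= la[0])
        ):
            first, second = sorted((la, lb))
            etype = "AL" if strand == "+" else "AF"
            incl, excl = (
                (ta.transcript_id, tb.transcript_id)
                if la <= lb
                else (tb.transcript_id, ta.transcript_id)
            )
            out.append(
                ("%s" % etype, (jan[0], *first, *second), incl, excl)
            )
    return out


def enumerate_events(
    transcripts_of_gene: Sequence[TranscriptModel],
) -> List[ASEvent]:
    """All local AS events among the transcripts of one gene.

    Events are deduplicated by (gene, type, coordinates); witness lists
    accumulate over all transcript pairs exhibiting the same event.
    """
    if not transcripts_of_gene:
        return []
    strands = {t.strand for t in transcripts_of_gene}
    chroms = {t.chrom for t in transcripts_of_gene}
    genes = {t.gene_id for t in transcripts_of_gene}
    if len(strands) > 1 or len(chroms) > 1 or len(genes) > 1:
        raise IntegrityError(
            "event enumeration requires one gene on one chrom/strand, got "
            f"genes={sorted(genes)} chroms={sorted(chroms)} strands={sorted(strands)}"
        )
    gene = transcripts_of_gene[0].gene_id
    chrom = transcripts_of_gene[0].chrom
    strand = transcripts_of_gene[0].strand

    found: Dict[Tuple[str, Tuple[int, ...]], Tuple[Set[str], Set[str]]] = {}
    txs = sorted(transcripts_of_gene, key=lambda t: t.transcript_id)
    for i in range(len(txs)):
        for k in range(i + 1, len(txs)):
            for etype, coords, incl, excl in _pair_events(txs[i], txs[k]):
                inc_set, exc_set = found.setdefault(
                    (etype, coords), (set(), set())
                )
                inc_set.add(incl)
                exc_set.add(excl)
    events = [
        ASEvent(
            gene,
            etype,
            chrom,
            strand,
            coords,
            tuple(sorted(inc)),
            tuple(sorted(exc)),
        )
        for (etype, coords), (inc, exc) in found.items()
    ]
    events.sort(key=lambda e: (e.event_type, e.coordinates))
    return events


@dataclass
class EventCatalog:
    """Deduplicated events of one condition, with per-type counts."""

    events: Tuple[ASEvent, ...]
    label: str = ""

    @property
    def counts(self) -> "OrderedDict[str, int]":
        c: "OrderedDict[str, int]" = OrderedDict((t, 0) for t in EVENT_TYPES)
        for e in self.events:
            c[e.event_type] += 1
        return c

    @property
    def keys(self) -> FrozenSet[EventKey]:
        return frozenset(e.key for e in self.events)

    def __len__(self) -> int:
        return len(self.events)


def build_catalog(
    isoforms: Sequence[TranscriptModel], label: str = ""
) -> EventCatalog:
    """Enumerate events gene by gene over an isoform set."""
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for iso in isoforms:
        by_gene.setdefault(iso.gene_id, []).append(iso)
    events: List[ASEvent] = []
    for gid in sorted(by_gene):
        events.extend(enumerate_events(by_gene[gid]))
    events.sort(key=lambda e: e.key)
    return EventCatalog(tuple(events), label)


@dataclass(frozen=True)
class ConditionComparison:
    """Events present only in condition B, lifted to gene level.

    ``asg_b`` are the condition-specific AS genes; they are partitioned by
    membership in a differential-expression gene set into genes whose AS
    change is accompanied by an abundance change (``asg_b_deg``) and genes
    where it is not (``asg_b_non_deg``).
    """

    events_only_in_b: Tuple[ASEvent, ...]
    asg_b: FrozenSet[str]
    asg_b_deg: FrozenSet[str]
    asg_b_non_deg: FrozenSet[str]


def compare_conditions(
    catalog_a: EventCatalog,
    catalog_b: EventCatalog,
    deg_genes: Iterable[str] = (),
) -> ConditionComparison:
    deg = frozenset(deg_genes)
    only_b = tuple(
        e for e in catalog_b.events if e.key not in catalog_a.keys
    )
    asg = frozenset(e.gene_id for e in only_b)
    return ConditionComparison(
        events_only_in_b=only_b,
        asg_b=asg,
        asg_b_deg=asg & deg,
        asg_b_non_deg=asg - deg,
    )
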