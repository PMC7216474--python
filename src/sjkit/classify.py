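"""Structural classification of isoforms against a reference annotation.

Categories follow the SQANTI-style vocabulary: FSM (full splice match),
ISM (incomplete splice match: a contiguous sub-chain of a reference
transcript), NIC (novel in catalog: every donor and acceptor is annotated
but the combination is new), NNC (novel not in catalog: at least one novel
splice site), plus the locus-level categories Genic_Genomic, Genic_Intron,
Antisense, Fusion and Intergenic.

Decision order (same-strand evidence dominates, chain evidence dominates
locus evidence):

1. FSM — chain equals a reference transcript's chain
2. ISM — chain is a strict contiguous sub-chain of one
3. Fusion — exonic overlap with >= 2 same-strand genes whose spans do not
   overlap each other (checked before NIC/NNC so a read-through spanning
   two genes is not mislabelled as novel-combination)
4. NIC — all query splice sites annotated on the same strand
5. NNC — overlaps a same-strand gene span with >= 1 novel splice site
6. Genic_Intron — entirely within one gene's intronic sequence
7. Genic_Genomic — overlaps a same-strand gene mixing exonic and
   intronic/flanking sequence
8. Antisense — overlaps gene spans only on the opposite strand
9. Intergenic

Mono-exon queries have no chain: FSM requires coincidence with a mono-exon
reference transcript (ends within a configurable tolerance), ISM requires
containment within a single reference exon; otherwise steps 6-9 apply.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from intervaltree import IntervalTree

from .formats import AnnotationSet, TranscriptModel
from .junctions import junctions_of

CATEGORIES = (
    "FSM",
    "ISM",
    "NIC",
    "NNC",
    "Genic_Genomic",
    "Genic_Intron",
    "Antisense",
    "Fusion",
    "Intergenic",
)

Chain = Tuple[Tuple[int, int], ...]


@dataclass(frozen=True)
class StructuralCall:
    isoform_id: str
    category: str
    associated_genes: Tuple[str, ...] = ()
    matched_reference_transcript: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category in ("FSM", "ISM") and not self.matched_reference_transcript:
            raise ValueError(f"{self.category} call requires a matched reference")
        if self.category == "Intergenic" and self.associated_genes:
            raise ValueError("Intergenic call cannot carry associated genes")


@dataclass
class _GeneInfo:
    gene_id: str
    chrom: str
    strand: str
    span: Tuple[int, int]
    exon_union: List[Tuple[int, int]]    # merged, sorted
    intron_union: List[Tuple[int, int]]  # complement of exon_union in span


def _merge(intervals: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersects(a: List[Tuple[int, int]], b: List[Tuple[int, int]]) -> bool:
    i = j = 0
    while i < len(a) and j < len(b):
        if a[i][1] <= b[j][0]:
            i += 1
        elif b[j][1] <= a[i][0]:
            j += 1
        else:
            return True
    return False


def _contained(a: List[Tuple[int, int]], b: List[Tuple[int, int]]) -> bool:
    """Every interval of `a` fully covered by a single interval of `b`."""
    return all(any(s >= bs and e <= be for bs, be in b) for s, e in a)


@dataclass
class RefIndex:
    """Precomputed reference lookups for classification."""

    chains: Dict[Tuple[str, str], Dict[Chain, str]]          # chain -> tid
    transcripts: Dict[Tuple[str, str], List[Tuple[Chain, str, str]]]
    starts: Dict[Tuple[str, str], Set[int]]                  # junction starts
    ends: Dict[Tuple[str, str], Set[int]]                    # junction ends
    genes: Dict[str, _GeneInfo]
    span_tree: Dict[str, IntervalTree]                       # per chrom
    mono_refs: Dict[Tuple[str, str], List[Tuple[int, int, str, str]]]
    exon_list: Dict[Tuple[str, str], List[Tuple[int, int, str]]]

    def genes_overlapping(self, chrom: str, start: int, end: int):
        tree = self.span_tree.get(chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(start, end), key=lambda iv: iv.data)
        return [self.genes[iv.data] for iv in hits]


def build_reference_index(annotation: AnnotationSet) -> RefIndex:
    chains: Dict[Tuple[str, str], Dict[Chain, str]] = {}
    transcripts: Dict[Tuple[str, str], List[Tuple[Chain, str, str]]] = {}
    starts: Dict[Tuple[str, str], Set[int]] = {}
    ends: Dict[Tuple[str, str], Set[int]] = {}
    genes: Dict[str, _GeneInfo] = {}
    span_tree: Dict[str, IntervalTree] = {}
    mono_refs: Dict[Tuple[str, str], List[Tuple[int, int, str, str]]] = {}
    exon_list: Dict[Tuple[str, str], List[Tuple[int, int, str]]] = {}

    for gid in sorted(annotation.genes):
        txs = annotation.genes[gid]
        if not txs:
            continue
        chrom, strand = txs[0].chrom, txs[0].strand
        all_exons: List[Tuple[int, int]] = []
        for t in sorted(txs, key=lambda t: t.transcript_id):
            key = (t.chrom, t.strand)
            chain = tuple((j.start, j.end) for j in junctions_of(t))
            all_exons.extend(t.exon_coords)
            for s, e in t.exon_coords:
                exon_list.setdefault(key, []).append((s, e, gid))
            if chain:
                chains.setdefault(key, {}).setdefault(chain, t.transcript_id)
                transcripts.setdefault(key, []).append(
                    (chain, t.transcript_id, gid)
                )
                for s, e in chain:
                    starts.setdefault(key, set()).add(s)
                    ends.setdefault(key, set()).add(e)
            else:
                mono_refs.setdefault(key, []).append(
                    (t.start, t.end, t.transcript_id, gid)
                )
        span = (min(s for s, _ in all_exons), max(e for _, e in all_exons))
        exon_union = _merge(all_exons)
        intron_union = [
            (a[1], b[0]) for a, b in zip(exon_union, exon_union[1:])
        ]
        genes[gid] = _GeneInfo(gid, chrom, strand, span, exon_union, intron_union)
        span_tree.setdefault(chrom, IntervalTree()).addi(span[0], span[1], gid)

    for key in exon_list:
        exon_list[key].sort()
    return RefIndex(
        chains, transcripts, starts, ends, genes, span_tree, mono_refs, exon_list
    )


def _contiguous_subchain(q: Chain, r: Chain) -> bool:
    m, n = len(q), len(r)
    if m >= n:
        return False
    return any(r[i : i + m] == q for i in range(n - m + 1))


def classify_isoform(
    query: TranscriptModel, index: RefIndex, mono_exon_tol: int = 50
) -> StructuralCall:
    """Assign exactly one structural category to `query`."""
    key = (query.chrom, query.strand)
    chain: Chain = tuple((j.start, j.end) for j in junctions_of(query))
    qid = query.transcript_id
    q_exons = list(query.exon_coords)

    overlapping = index.genes_overlapping(query.chrom, query.start, query.end)
    same = [g for g in overlapping if g.strand == query.strand]
    anti = [g for g in overlapping if g.strand != query.strand]

    if chain:
        tid = index.chains.get(key, {}).get(chain)
        if tid is not None:
            gid = next(
                g for c, t, g in index.transcripts[key] if t == tid
            )
            return StructuralCall(qid, "FSM", (gid,), tid)
        ism = [
            (t, g)
            for c, t, g in index.transcripts.get(key, [])
            if _contiguous_subchain(chain, c)
        ]
        if ism:
            tid, gid = min(ism)
            return StructuralCall(qid, "ISM", (gid,), tid)
    else:
        # mono-exon chain relations
        for s, e, tid, gid in sorted(index.mono_refs.get(key, [])):
            if abs(query.start - s) <= mono_exon_tol and abs(
                query.end - e
            ) <= mono_exon_tol:
                return StructuralCall(qid, "FSM", (gid,), tid)
        for s, e, gid in index.exon_list.get(key, []):
            if s <= query.start and query.end <= e:
                tid = _tid_for_exon(index, key, s, e, gid)
                return StructuralCall(qid, "ISM", (gid,), tid)

    # Fusion: exonic overlap with >= 2 same-strand genes with disjoint spans
    exon_hit = [
        g for g in same if _intersects(q_exons, g.exon_union)
    ]
    if len(exon_hit) >= 2:
        disjoint = all(
            a.span[1] <= b.span[0] or b.span[1] <= a.span[0]
            for i, a in enumerate(exon_hit)
            for b in exon_hit[i + 1 :]
        )
        if disjoint:
            return StructuralCall(
                qid, "Fusion", tuple(sorted(g.gene_id for g in exon_hit))
            )

    if chain:
        s_ann = index.starts.get(key, set())
        e_ann = index.ends.get(key, set())
        if all(s in s_ann and e in e_ann for s, e in chain):
            gids = tuple(sorted(g.gene_id for g in same)) or tuple(
                sorted(g.gene_id for g in exon_hit)
            )
            return StructuralCall(qid, "NIC", gids)
        if same:
            return StructuralCall(
                qid, "NNC", tuple(sorted(g.gene_id for g in same))
            )

    for g in same:
        if _contained(q_exons, g.intron_union):
            return StructuralCall(qid, "Genic_Intron", (g.gene_id,))
    if same:
        return StructuralCall(
            qid, "Genic_Genomic", tuple(sorted(g.gene_id for g in same))
        )
    if anti:
        return StructuralCall(
            qid, "Antisense", tuple(sorted(g.gene_id for g in anti))
        )
    return StructuralCall(qid, "Intergenic")


def _tid_for_exon(
    index: RefIndex, key: Tuple[str, str], s: int, e: int, gid: str
) -> str:
    for chain, tid, g in index.transcripts.get(key, []):
        if g == gid:
            return tid
    for ms, me, tid, g in index.mono_refs.get(key, []):
        if g == gid:
            return tid
    raise RuntimeError(f"no reference transcript recorded for gene {gid}")


def classify_all(
    queries: Sequence[TranscriptModel], index: RefIndex, mono_exon_tol: int = 50
) -> List[StructuralCall]:
    return [classify_isoform(q, index, mono_exon_tol) for q in queries]


def summarize_categories(calls: Sequence[StructuralCall]) -> "OrderedDict[str, int]":
    counts: "OrderedDict[str, int]" = OrderedDict((c, 0) for c in CATEGORIES)
    for call in calls:
        counts[call.category] += 1
    return counts
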