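"""Collapse validated isoforms into non-redundant clusters.

Multi-exon isoforms are redundant when they share chromosome, strand and
the complete splice-junction chain (their transcribed ends may differ).
Mono-exon isoforms, having no chain, are clustered by single-linkage
genomic overlap on the same strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from .formats import TranscriptModel
from .junctions import chain_key


@dataclass(frozen=True)
class CollapseConfig:
    # Merging 5'-truncated chains into longer parents would erase the ISM
    # category downstream; off by default.
    merge_5prime_truncated: bool = False


@dataclass(frozen=True)
class IsoformCluster:
    representative: TranscriptModel
    members: Tuple[str, ...]
    chain_key: Tuple

    def __post_init__(self) -> None:
        if self.representative.transcript_id not in self.members:
            raise ValueError("representative must be a member")


def _pick_representative(models: List[TranscriptModel]) -> TranscriptModel:
    # longest genomic span wins; ties broken by lexicographically smallest id
    return min(models, key=lambda t: (-(t.end - t.start), t.transcript_id))


def _is_truncation(short: Tuple, full: Tuple) -> bool:
    """True if chain `short` is a strict contiguous sub-chain of `full`."""
    if len(short) >= len(full) or not short:
        return False
    n, m = len(full), len(short)
    return any(full[i : i + m] == tuple(short) for i in range(n - m + 1))


def collapse_isoforms(
    isoforms: Sequence[TranscriptModel],
    config: CollapseConfig = CollapseConfig(),
) -> List[IsoformCluster]:
    """Group isoforms into non-redundant clusters.

    Guarantees: every input lands in exactly one cluster; clusters,
    members and representatives are independent of input order.
    """
    multi: Dict[Tuple, List[TranscriptModel]] = {}
    mono: Dict[Tuple[str, str], List[TranscriptModel]] = {}
    for iso in isoforms:
        if iso.n_exons == 1:
            mono.setdefault((iso.chrom, iso.strand), []).append(iso)
        else:
            multi.setdefault(chain_key(iso), []).append(iso)

    if config.merge_5prime_truncated:
        multi = _merge_truncated(multi)

    clusters: List[IsoformCluster] = []
    for key, models in multi.items():
        rep = _pick_representative(models)
        clusters.append(
            IsoformCluster(
                representative=rep,
                members=tuple(sorted(t.transcript_id for t in models)),
                chain_key=key,
            )
        )

    # mono-exon: single-linkage any-overlap sweep on each (chrom, strand)
    for (chrom, strand), models in mono.items():
        models = sorted(models, key=lambda t: (t.start, t.end, t.transcript_id))
        group: List[TranscriptModel] = []
        group_end = -1
        batches: List[List[TranscriptModel]] = []
        for t in models:
            if group and t.start >= group_end:
                batches.append(group)
                group = []
                group_end = -1
            group.append(t)
            group_end = max(group_end, t.end)
        if group:
            batches.append(group)
        for batch in batches:
            rep = _pick_representative(batch)
            key = (
                "mono",
                chrom,
                strand,
                min(t.start for t in batch),
                max(t.end for t in batch),
            )
            clusters.append(
                IsoformCluster(
                    representative=rep,
                    members=tuple(sorted(t.transcript_id for t in batch)),
                    chain_key=key,
                )
            )

    clusters.sort(
        key=lambda c: (
            c.representative.chrom,
            c.representative.start,
            c.representative.transcript_id,
        )
    )
    return clusters


def _merge_truncated(
    multi: Dict[Tuple, List[TranscriptModel]]
) -> Dict[Tuple, List[TranscriptModel]]:
    """Fold clusters whose chain is a contiguous sub-chain of a longer one."""
    keys = sorted(multi, key=lambda k: (-len(k[2]), k))
    merged: Dict[Tuple, List[TranscriptModel]] = {}
    for key in keys:
        chrom, strand, chain = key
        target = None
        for cand in sorted(merged, key=lambda k: (-len(k[2]), k)):
            if cand[0] == chrom and cand[1] == strand and _is_truncation(
                chain, cand[2]
            ):
                target = cand
                break
        if target is None:
            merged[key] = list(multi[key])
        else:
            merged[target].extend(multi[key])
    return merged
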