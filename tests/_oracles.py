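"""Independent brute-force oracles used to cross-check the library.

These deliberately re-derive the definitions by the most literal route
available (base-set arithmetic, exhaustive nested loops, full spans
enumeration, permutation tests) and share no code with the implementation
they check.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.stats import rankdata

STOPS = ("TAA", "TAG", "TGA")


def _chain(tx) -> Tuple[Tuple[int, int], ...]:
    ex = tx.exon_coords
    return tuple((a[1], b[0]) for a, b in zip(ex, ex[1:]))


# ---------------------------------------------------------------------------
# structural classification by direct set comparison


def brute_force_classify(query, annotation, mono_tol: int = 50) -> str:
    refs = [t for t in annotation.transcripts()]
    same = [
        t for t in refs if t.chrom == query.chrom and t.strand == query.strand
    ]
    anti = [
        t for t in refs if t.chrom == query.chrom and t.strand != query.strand
    ]
    qchain = _chain(query)
    q_bases: Set[int] = set()
    for s, e in query.exon_coords:
        q_bases |= set(range(s, e))

    def gene_tables(txs):
        genes: Dict[str, Dict] = {}
        for t in txs:
            g = genes.setdefault(
                t.gene_id, {"exon_bases": set(), "lo": None, "hi": None}
            )
            for s, e in t.exon_coords:
                g["exon_bases"] |= set(range(s, e))
        for g in genes.values():
            g["lo"], g["hi"] = min(g["exon_bases"]), max(g["exon_bases"]) + 1
            g["intron_bases"] = set(range(g["lo"], g["hi"])) - g["exon_bases"]
        return genes

    same_genes = gene_tables(same)
    anti_genes = gene_tables(anti)

    # 1/2: chain relations
    if qchain:
        for t in same:
            if _chain(t) == qchain:
                return "FSM"
        for t in same:
            rc = _chain(t)
            m = len(qchain)
            if m < len(rc) and any(
                rc[i : i + m] == qchain for i in range(len(rc) - m + 1)
            ):
                return "ISM"
    else:
        for t in same:
            if len(t.exons) == 1 and (
                abs(t.start - query.start) <= mono_tol
                and abs(t.end - query.end) <= mono_tol
            ):
                return "FSM"
        if any(
            s <= query.start and query.end <= e
            for t in same
            for s, e in t.exon_coords
        ):
            return "ISM"
    # Fusion
    hit = [
        gid
        for gid, g in same_genes.items()
        if q_bases & g["exon_bases"]
    ]
    if len(hit) >= 2:
        spans = [(same_genes[g]["lo"], same_genes[g]["hi"]) for g in hit]
        if all(
            a[1] <= b[0] or b[1] <= a[0]
            for i, a in enumerate(spans)
            for b in spans[i + 1 :]
        ):
            return "Fusion"
    if qchain:
        starts = {j[0] for t in same for j in _chain(t)}
        ends = {j[1] for t in same for j in _chain(t)}
        if all(s in starts and e in ends for s, e in qchain):
            return "NIC"
        if any(
            g["lo"] < query.end and query.start < g["hi"]
            for g in same_genes.values()
        ):
            return "NNC"
    for g in same_genes.values():
        if q_bases <= g["intron_bases"]:
            return "Genic_Intron"
    if any(
        g["lo"] < query.end and query.start < g["hi"]
        for g in same_genes.values()
    ):
        return "Genic_Genomic"
    if any(
        g["lo"] < query.end and query.start < g["hi"]
        for g in anti_genes.values()
    ):
        return "Antisense"
    return "Intergenic"


# ---------------------------------------------------------------------------
# AS events by exhaustive nested loops


def brute_force_events(transcripts) -> Set[Tuple[str, Tuple[int, ...]]]:
    """Set of (event_type, coordinates) over all transcript pairs."""
    strand = transcripts[0].strand
    found: Set[Tuple[str, Tuple[int, ...]]] = set()
    n = len(transcripts)
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            tx, ty = transcripts[a], transcripts[b]
            ex_x, jx = tx.exon_coords, _chain(tx)
            ex_y, jy = ty.exon_coords, _chain(ty)

            # SE: two junctions of x flanking one of x's exons; y skips
            for j1 in jx:
                for j2 in jx:
                    if (j1[1], j2[0]) in ex_x and (j1[0], j2[1]) in jy:
                        found.add(("SE", (j1[0], j1[1], j2[0], j2[1])))
            # RI: y exon strictly covers an intron of x
            for a1, b1 in jx:
                for s, e in ex_y:
                    if s < a1 and e > b1:
                        found.add(("RI", (s, a1, b1, e)))
            # A5/A3: junction pairs sharing one boundary
            for s1, e1 in jx:
                for s2, e2 in jy:
                    if e1 == e2 and s1 != s2:
                        s_out, s_in = min(s1, s2), max(s1, s2)
                        inner_tx = tx if s_in == s1 else ty
                        if any(
                            fe == s_in and fs < s_out
                            for fs, fe in inner_tx.exon_coords
                        ):
                            t = "A5" if strand == "+" else "A3"
                            found.add((t, (s_out, e1, s_in, e1)))
                    if s1 == s2 and e1 != e2:
                        e_in, e_out = min(e1, e2), max(e1, e2)
                        inner_tx = tx if e_in == e1 else ty
                        if any(
                            fs == e_in and fe > e_out
                            for fs, fe in inner_tx.exon_coords
                        ):
                            t = "A3" if strand == "+" else "A5"
                            found.add((t, (s1, e_in, s1, e_out)))
            # MX: shared outer boundaries, disjoint internal exons
            for j1 in jx:
                for j2 in jx:
                    if (j1[1], j2[0]) not in ex_x:
                        continue
                    for k1 in jy:
                        for k2 in jy:
                            if (k1[1], k2[0]) not in ex_y:
                                continue
                            if j1[0] != k1[0] or j2[1] != k2[1]:
                                continue
                            e_x = (j1[1], j2[0])
                            e_y = (k1[1], k2[0])
                            if e_x == e_y:
                                continue
                            if e_x[1] <= e_y[0] or e_y[1] <= e_x[0]:
                                lo, hi = sorted((e_x, e_y))
                                found.add(
                                    ("MX", (j1[0], *lo, *hi, j2[1]))
                                )
            # AF/AL: distinct non-overlapping terminal exons, shared anchor
            if len(ex_x) >= 2 and len(ex_y) >= 2:
                fx, fy = ex_x[0], ex_y[0]
                jx0 = next(j for j in jx if j[0] == fx[1])
                jy0 = next(j for j in jy if j[0] == fy[1])
                if (
                    jx0[1] == jy0[1]
                    and jx0[0] != jy0[0]
                    and (fx[1] <= fy[0] or fy[1] <= fx[0])
                ):
                    lo, hi = sorted((fx, fy))
                    t = "AF" if strand == "+" else "AL"
                    found.add((t, (*lo, *hi, jx0[1])))
                lx, ly = ex_x[-1], ex_y[-1]
                jxn = next(j for j in jx if j[1] == lx[0])
                jyn = next(j for j in jy if j[1] == ly[0])
                if (
                    jxn[0] == jyn[0]
                    and jxn[1] != jyn[1]
                    and (lx[1] <= ly[0] or ly[1] <= lx[0])
                ):
                    lo, hi = sorted((lx, ly))
                    t = "AL" if strand == "+" else "AF"
                    found.add((t, (jxn[0], *lo, *hi)))
    return found


# ---------------------------------------------------------------------------
# longest ORF by exhaustive span enumeration


def brute_force_longest_orf(seq: str) -> Optional[Tuple[int, int, int]]:
    """(aa_length, cds_start, cds_end) of the best ATG..stop span."""
    best = None
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(seq):
            if seq[j : j + 3] in STOPS:
                aa = (j - i) // 3
                cand = (-aa, i)
                if best is None or cand < best[0]:
                    best = (cand, (aa, i, j + 3))
                break
            j += 3
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# permutation Mann-Whitney


def permutation_mwu_p(
    a: Sequence[float], b: Sequence[float], n_perm: int = 10000, seed: int = 0
) -> float:
    """Two-sided permutation p-value for the rank-sum statistic."""
    rng = np.random.default_rng(seed)
    x = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    n1 = len(a)
    ranks = rankdata(x)
    expected = n1 * (len(x) + 1) / 2.0
    obs = abs(ranks[:n1].sum() - expected)
    idx = np.arange(len(x))
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(idx)
        stat = abs(ranks[idx[:n1]].sum() - expected)
        if stat >= obs - 1e-9:
            hits += 1
    return (hits + 1) / (n_perm + 1)
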