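"""Seeded generator of toy genomes, annotations, isoform sets and
short-read junction tables with complete ground truth.

The generator emulates the input structure of a two-condition hybrid
sequencing study ("untreated" vs "treated"): a reference annotation of one
full-chain transcript per gene, long-read query isoforms consisting of the
reference transcripts plus perturbed novel isoforms, and per-condition
short-read junction tables containing every true junction (minus optional
dropouts) plus spurious decoys that never coincide with a true junction.
The treated condition receives extra event-producing perturbations on top
of the untreated isoform set, so condition-specific events exist by
construction.

A single RNG stream seeded from ``SimConfig.seed`` is consumed in a fixed,
documented order: (1) gene layout, (2) per-gene novel-op choices and
parameters, (3) genome bases, (4) reference intron motifs, (5) expression
values, (6) differential-expression statistics, (7) per-condition junction
dropout uniforms, (8) spurious junction sampling. Dropout uniforms are
drawn whether or not dropout is enabled, so datasets generated from the
same seed with different dropout rates share coupled randomness.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .classify import build_reference_index, classify_isoform
from .events import ASEvent, EventCatalog, build_catalog
from .formats import (
    AnnotationSet,
    GenomeAccessor,
    GenomicInterval,
    SJRecord,
    SJTable,
    TranscriptModel,
    write_bed12,
    write_genome_fasta,
    write_gtf,
    write_star_sj,
)
from .junctions import junctions_of, validate_chain
from .orf_expr import DEGRecord

UNTREATED = "untreated"
TREATED = "treated"
CONDITIONS = (UNTREATED, TREATED)

OPS = (
    "skip_exon",
    "retain_intron",
    "shift_donor",
    "shift_acceptor",
    "novel_exon",
    "truncate_5prime",
    "antisense",
    "intergenic",
)
#: ops guaranteed to add a local AS event against the reference isoform
EVENT_OPS = ("skip_exon", "retain_intron", "shift_donor", "shift_acceptor", "novel_exon")

_CANONICAL_MOTIFS = (("GT", "AG"), ("GC", "AG"), ("AT", "AC"))
_CANONICAL_WEIGHTS = (0.85, 0.10, 0.05)

_OP_CATEGORY = {
    "skip_exon": "NIC",
    "retain_intron": "NIC",
    "shift_donor": "NNC",
    "shift_acceptor": "NNC",
    "novel_exon": "NNC",
    "truncate_5prime": "ISM",
    "antisense": "Antisense",
    "intergenic": "Intergenic",
}
_OP_EVENT = {
    "skip_exon": "SE",
    "retain_intron": "RI",
    "shift_donor": "A5",
    "shift_acceptor": "A3",
    "novel_exon": "SE",
    "truncate_5prime": None,
    "antisense": None,
    "intergenic": None,
}


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 20
    exons_per_gene: Tuple[int, int] = (4, 7)
    exon_len: Tuple[int, int] = (80, 300)
    intron_len: Tuple[int, int] = (60, 400)
    #: condition-A isoforms per gene, reference included
    isoforms_per_gene: Tuple[int, int] = (2, 3)
    #: extra event-producing novels added in the treated condition
    extra_b_per_gene: Tuple[int, int] = (1, 1)
    novel_ops_mix: Tuple[Tuple[str, float], ...] = (
        ("skip_exon", 0.20),
        ("retain_intron", 0.20),
        ("shift_donor", 0.125),
        ("shift_acceptor", 0.125),
        ("novel_exon", 0.10),
        ("truncate_5prime", 0.10),
        ("antisense", 0.075),
        ("intergenic", 0.075),
    )
    junction_dropout: float = 0.0
    spurious_sj_rate: int = 0
    noncanonical_fraction: float = 0.0
    spacer: int = 1000
    flank: int = 500
    chrom: str = "chrS"
    shift_nt: int = 6

    def __post_init__(self) -> None:
        if not (0.0 <= self.junction_dropout <= 1.0):
            raise ValueError("junction_dropout must lie in [0, 1]")
        if not (0.0 <= self.noncanonical_fraction <= 1.0):
            raise ValueError("noncanonical_fraction must lie in [0, 1]")
        if self.spurious_sj_rate < 0:
            raise ValueError("spurious_sj_rate must be >= 0")
        for lo, hi in (
            self.exons_per_gene,
            self.exon_len,
            self.intron_len,
            self.isoforms_per_gene,
        ):
            if lo < 1 or hi < lo:
                raise ValueError("ranges must be positive with lo <= hi")
        weights = dict(self.novel_ops_mix)
        if set(weights) - set(OPS):
            raise ValueError(f"unknown ops in mix: {set(weights) - set(OPS)}")
        total = sum(weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"novel_ops_mix weights must sum to 1, got {total}")


@dataclass(frozen=True)
class IsoformTruth:
    isoform_id: str
    gene_id: str
    op: str  # "reference" or a novel-op name
    category: str
    expected_event: Optional[str]
    in_conditions: Tuple[str, ...]
    n_junctions: int
    #: expected validation status per condition the isoform appears in
    status: Tuple[Tuple[str, str], ...]


@dataclass
class GroundTruth:
    isoforms: Dict[str, IsoformTruth]
    #: full-set event catalogs per condition (noise-free definition)
    catalogs: Dict[str, EventCatalog]
    #: reference intron (start, end) -> (donor, acceptor, canonical)
    junction_motifs: Dict[Tuple[int, int], Tuple[str, str, bool]]
    #: per condition, true junctions removed from the SJ table
    dropped: Dict[str, FrozenSet[Tuple[int, int]]]

    def valid_ids(self, condition: str) -> Set[str]:
        """Isoforms of `condition` expected to survive chain validation
        (mono-exon isoforms counted as retained under the default config)."""
        out = set()
        for t in self.isoforms.values():
            st = dict(t.status).get(condition)
            if st in ("valid", "mono_exon"):
                out.add(t.isoform_id)
        return out


@dataclass
class SimulatedDataset:
    config: SimConfig
    chrom: str
    sequence: str
    annotation: AnnotationSet
    isoforms: Dict[str, List[TranscriptModel]]
    sj_tables: Dict[str, SJTable]
    expression: pd.DataFrame
    deg_records: List[DEGRecord]
    truth: GroundTruth

    @property
    def genome(self) -> GenomeAccessor:
        return GenomeAccessor({self.chrom: self.sequence})

    def write(self, outdir: str) -> Dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fa"),
            "annotation": os.path.join(outdir, "annotation.gtf"),
            "expression": os.path.join(outdir, "expression.tsv"),
            "deg": os.path.join(outdir, "deg.tsv"),
            "truth": os.path.join(outdir, "truth.tsv"),
            "truth_events": os.path.join(outdir, "truth_events.tsv"),
            "truth_junctions": os.path.join(outdir, "truth_junctions.tsv"),
        }
        write_genome_fasta({self.chrom: self.sequence}, paths["genome"])
        write_gtf(self.annotation, paths["annotation"])
        for cond in CONDITIONS:
            paths[f"isoforms_{cond}"] = os.path.join(outdir, f"isoforms_{cond}.bed")
            paths[f"sj_{cond}"] = os.path.join(outdir, f"sj_{cond}.tab")
            write_bed12(self.isoforms[cond], paths[f"isoforms_{cond}"])
            write_star_sj(self.sj_tables[cond], paths[f"sj_{cond}"])
        self.expression.to_csv(paths["expression"], sep="\t", index=False)
        pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.deg_records],
                "log2fc": [r.log2fc for r in self.deg_records],
                "p_value": [r.p_value for r in self.deg_records],
            }
        ).to_csv(paths["deg"], sep="\t", index=False)
        rows = []
        for t in sorted(self.truth.isoforms.values(), key=lambda t: t.isoform_id):
            rows.append(
                {
                    "isoform_id": t.isoform_id,
                    "gene_id": t.gene_id,
                    "op": t.op,
                    "category": t.category,
                    "expected_event": t.expected_event or "",
                    "conditions": ",".join(t.in_conditions),
                    "n_junctions": t.n_junctions,
                    "status": ";".join(f"{c}={s}" for c, s in t.status),
                }
            )
        pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
        ev_rows = [
            {
                "condition": cond,
                "gene_id": e.gene_id,
                "event_type": e.event_type,
                "coordinates": ",".join(map(str, e.coordinates)),
            }
            for cond in CONDITIONS
            for e in self.truth.catalogs[cond].events
        ]
        pd.DataFrame(
            ev_rows, columns=["condition", "gene_id", "event_type", "coordinates"]
        ).to_csv(paths["truth_events"], sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "start": s,
                    "end": e,
                    "donor": d,
                    "acceptor": a,
                    "canonical": int(c),
                }
                for (s, e), (d, a, c) in sorted(
                    self.truth.junction_motifs.items()
                )
            ]
        ).to_csv(paths["truth_junctions"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# perturbation ops


def _model(
    base: TranscriptModel,
    exons: Sequence[Tuple[int, int]],
    op: str,
    strand: Optional[str] = None,
    own_gene: bool = False,
) -> TranscriptModel:
    tid = f"{base.transcript_id}.{op}"
    gid = tid if own_gene else base.gene_id
    return TranscriptModel.from_coords(
        tid, gid, base.chrom, strand or base.strand, exons
    )


def perturb_isoform(
    base: TranscriptModel,
    op: str,
    rng: np.random.Generator,
    shift_nt: int = 6,
) -> Tuple[TranscriptModel, str, Optional[str]]:
    """Apply one novel-isoform operation to `base`.

    Returns (perturbed model, expected structural category, expected AS
    event type against the reference or None). Raises ``ValueError`` when
    the op is not applicable to the base structure.
    """
    exons = list(base.exon_coords)
    n = len(exons)
    strand = base.strand

    if op == "skip_exon":
        if n < 3:
            raise ValueError("skip_exon needs >= 3 exons")
        i = int(rng.integers(1, n - 1))
        new = exons[:i] + exons[i + 1 :]
    elif op == "retain_intron":
        if n < 4:
            raise ValueError("retain_intron needs an internal intron (>= 4 exons)")
        i = int(rng.integers(1, n - 2))
        new = exons[:i] + [(exons[i][0], exons[i + 1][1])] + exons[i + 2 :]
    elif op in ("shift_donor", "shift_acceptor"):
        cands = [
            j
            for j in range(n - 1)
            if exons[j + 1][0] - exons[j][1] >= shift_nt + 10
        ]
        if not cands:
            raise ValueError(f"{op}: no intron long enough to shift")
        j = cands[int(rng.integers(0, len(cands)))]
        grow_left_exon = (op == "shift_donor") == (strand == "+")
        if grow_left_exon:
            # intron start moves right: exon j extends into the intron
            exons[j] = (exons[j][0], exons[j][1] + shift_nt)
        else:
            # intron end moves left: exon j+1 extends into the intron
            exons[j + 1] = (exons[j + 1][0] - shift_nt, exons[j + 1][1])
        new = exons
    elif op == "novel_exon":
        cands = [
            j for j in range(n - 1) if exons[j + 1][0] - exons[j][1] >= 50
        ]
        if not cands:
            raise ValueError("novel_exon: no intron long enough")
        j = cands[int(rng.integers(0, len(cands)))]
        s_i, e_i = exons[j][1], exons[j + 1][0]
        third = (e_i - s_i) // 3
        new = exons[: j + 1] + [(s_i + third, e_i - third)] + exons[j + 1 :]
    elif op == "truncate_5prime":
        if n < 3:
            raise ValueError("truncate_5prime needs >= 3 exons")
        new = exons[1:] if strand == "+" else exons[:-1]
    elif op == "antisense":
        anti = "-" if strand == "+" else "+"
        m = _model(base, [(base.start + 5, base.end - 5)], op, anti, own_gene=True)
        return m, "Antisense", None
    elif op == "intergenic":
        offset = 120 + int(rng.integers(0, 5)) * 60
        st = base.end + offset
        s2 = "+" if rng.integers(0, 2) == 0 else "-"
        m = _model(
            base, [(st, st + 100), (st + 220, st + 320)], op, s2, own_gene=True
        )
        return m, "Intergenic", None
    else:
        raise ValueError(f"unknown op {op!r}")

    return _model(base, new, op), _OP_CATEGORY[op], _OP_EVENT[op]


def _applicable(op: str, base: TranscriptModel, shift_nt: int) -> bool:
    exons = base.exon_coords
    n = len(exons)
    introns = [exons[j + 1][0] - exons[j][1] for j in range(n - 1)]
    if op == "skip_exon" or op == "truncate_5prime":
        return n >= 3
    if op == "retain_intron":
        return n >= 4
    if op in ("shift_donor", "shift_acceptor"):
        return any(l >= shift_nt + 10 for l in introns)
    if op == "novel_exon":
        return any(l >= 50 for l in introns)
    return True  # antisense / intergenic


# ---------------------------------------------------------------------------
# dataset generation


def _draw_op(
    rng: np.random.Generator,
    mix: Sequence[Tuple[str, float]],
) -> str:
    names = [m[0] for m in mix]
    weights = np.asarray([m[1] for m in mix], dtype=float)
    weights = weights / weights.sum()
    return names[int(rng.choice(len(names), p=weights))]


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate a complete two-condition toy dataset with ground truth.

    Deterministic: the same config yields byte-identical files from
    :meth:`SimulatedDataset.write`.
    """
    rng = np.random.default_rng(config.seed)
    chrom = config.chrom

    # (1) gene layout -------------------------------------------------------
    cursor = config.flank
    refs: List[TranscriptModel] = []
    for g in range(config.n_genes):
        gid = f"g{g + 1:04d}"
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        ex_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, n_ex)
        in_lens = rng.integers(
            config.intron_len[0], config.intron_len[1] + 1, max(n_ex - 1, 0)
        )
        exons: List[Tuple[int, int]] = []
        pos = cursor
        for i in range(n_ex):
            exons.append((pos, pos + int(ex_lens[i])))
            pos += int(ex_lens[i])
            if i < n_ex - 1:
                pos += int(in_lens[i])
        refs.append(TranscriptModel.from_coords(f"{gid}.t1", gid, chrom, strand, exons))
        cursor = pos + config.spacer
    total_len = cursor + config.flank

    annotation = AnnotationSet(
        genes={t.gene_id: [t] for t in refs}, provenance="simulated"
    )

    # (2) novel ops ---------------------------------------------------------
    mix = list(config.novel_ops_mix)
    b_mix = [m for m in mix if m[0] in EVENT_OPS]
    iso_a: List[TranscriptModel] = []
    iso_b_extra: List[TranscriptModel] = []
    truth_meta: Dict[str, Tuple[str, str, str, Optional[str]]] = {}

    def _add_novels(
        base: TranscriptModel,
        count: int,
        pool: Sequence[Tuple[str, float]],
        tag: str,
        used: Set[Tuple],
        sink: List[TranscriptModel],
    ) -> None:
        made = 0
        attempts = 0
        while made < count and attempts < 25 * max(count, 1):
            attempts += 1
            op = _draw_op(rng, pool)
            if not _applicable(op, base, config.shift_nt):
                continue
            model, category, event = perturb_isoform(base, op, rng, config.shift_nt)
            sig = (model.strand, model.exon_coords)
            if sig in used:
                continue
            used.add(sig)
            made += 1
            tid = f"{base.gene_id}.{tag}{made}.{op}"
            gid = tid if op in ("antisense", "intergenic") else base.gene_id
            model = model.with_ids(transcript_id=tid, gene_id=gid)
            sink.append(model)
            truth_meta[tid] = (gid, op, category, event)

    for ref in refs:
        used: Set[Tuple] = {(ref.strand, ref.exon_coords)}
        n_a = int(
            rng.integers(config.isoforms_per_gene[0], config.isoforms_per_gene[1] + 1)
        )
        _add_novels(ref, max(n_a - 1, 0), mix, "nA", used, iso_a)
        n_b = int(
            rng.integers(config.extra_b_per_gene[0], config.extra_b_per_gene[1] + 1)
        )
        _add_novels(ref, n_b, b_mix, "nB", used, iso_b_extra)
        truth_meta[ref.transcript_id] = (ref.gene_id, "reference", "FSM", None)

    isoforms = {
        UNTREATED: sorted(refs + iso_a, key=lambda t: t.transcript_id),
        TREATED: sorted(refs + iso_a + iso_b_extra, key=lambda t: t.transcript_id),
    }

    # (3) genome bases ------------------------------------------------------
    bases = rng.integers(0, 4, total_len)
    seq = np.array(list("ACGT"), dtype="U1")[bases]

    # (4) reference intron motifs ------------------------------------------
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def _rc(s: str) -> str:
        return "".join(comp[c] for c in reversed(s))

    motifs: Dict[Tuple[int, int], Tuple[str, str, bool]] = {}
    alphabet = "ACGT"
    for ref in refs:
        for sj in junctions_of(ref):
            if rng.random() < config.noncanonical_fraction:
                while True:
                    donor = "".join(
                        alphabet[int(i)] for i in rng.integers(0, 4, 2)
                    )
                    acceptor = "".join(
                        alphabet[int(i)] for i in rng.integers(0, 4, 2)
                    )
                    if (donor, acceptor) not in _CANONICAL_MOTIFS:
                        break
                canonical = False
            else:
                donor, acceptor = _CANONICAL_MOTIFS[
                    int(rng.choice(3, p=_CANONICAL_WEIGHTS))
                ]
                canonical = True
            motifs[(sj.start, sj.end)] = (donor, acceptor, canonical)
            if ref.strand == "+":
                seq[sj.start : sj.start + 2] = list(donor)
                seq[sj.end - 2 : sj.end] = list(acceptor)
            else:
                seq[sj.start : sj.start + 2] = list(_rc(acceptor))
                seq[sj.end - 2 : sj.end] = list(_rc(donor))
    sequence = "".join(seq)

    # (5) expression --------------------------------------------------------
    all_iso = sorted(
        {t.transcript_id: t for c in CONDITIONS for t in isoforms[c]}.values(),
        key=lambda t: t.transcript_id,
    )
    in_a = {t.transcript_id for t in isoforms[UNTREATED]}
    in_b = {t.transcript_id for t in isoforms[TREATED]}
    expr_rows = []
    for t in all_iso:
        tpm_u = float(np.round(rng.lognormal(1.0, 1.0), 3))
        tpm_t = float(np.round(rng.lognormal(1.0, 1.0), 3))
        expr_rows.append(
            {
                "isoform_id": t.transcript_id,
                "gene_id": t.gene_id,
                "tpm_untreated": tpm_u if t.transcript_id in in_a else 0.0,
                "tpm_treated": tpm_t if t.transcript_id in in_b else 0.0,
            }
        )
    expression = pd.DataFrame(expr_rows)

    # (6) differential expression ------------------------------------------
    deg_records = [
        DEGRecord(
            ref.gene_id,
            float(rng.normal(0.0, 1.5)),
            float(rng.uniform(0.0, 1.0)),
        )
        for ref in refs
    ]

    # (7) per-condition SJ tables with coupled dropout ----------------------
    sj_tables: Dict[str, SJTable] = {}
    dropped: Dict[str, FrozenSet[Tuple[int, int]]] = {}
    true_coords: Set[Tuple[int, int]] = set()
    for cond in CONDITIONS:
        juncs = sorted(
            {
                (sj.start, sj.end, sj.strand)
                for t in isoforms[cond]
                for sj in junctions_of(t)
            }
        )
        table = SJTable()
        cond_dropped: Set[Tuple[int, int]] = set()
        for start, end, strand in juncs:
            true_coords.add((start, end))
            u = rng.random()
            support = int(rng.integers(5, 51))
            if u < config.junction_dropout:
                cond_dropped.add((start, end))
                continue
            table.add(
                SJRecord(
                    GenomicInterval(chrom, start, end, strand),
                    unique_reads=support,
                    max_overhang=30,
                )
            )
        sj_tables[cond] = table
        dropped[cond] = frozenset(cond_dropped)

    # (8) spurious decoys ---------------------------------------------------
    for cond in CONDITIONS:
        added = 0
        while added < config.spurious_sj_rate:
            start = int(rng.integers(0, total_len - 600))
            end = start + int(rng.integers(60, 500))
            if (start, end) in true_coords:
                continue
            strand = (".", "+", "-")[int(rng.integers(0, 3))]
            if sj_tables[cond].lookup(chrom, strand, start, end) is not None:
                continue
            sj_tables[cond].add(
                SJRecord(
                    GenomicInterval(chrom, start, end, strand),
                    unique_reads=int(rng.integers(1, 21)),
                    max_overhang=20,
                )
            )
            added += 1

    # ground truth ----------------------------------------------------------
    iso_truth: Dict[str, IsoformTruth] = {}
    for t in all_iso:
        gid, op, category, event = truth_meta[t.transcript_id]
        conds = tuple(
            c for c in CONDITIONS if t.transcript_id in (in_a if c == UNTREATED else in_b)
        )
        status = tuple(
            (
                c,
                validate_chain(
                    junctions_of(t), sj_tables[c], 1, t.transcript_id
                ).status,
            )
            for c in conds
        )
        iso_truth[t.transcript_id] = IsoformTruth(
            isoform_id=t.transcript_id,
            gene_id=gid,
            op=op,
            category=category,
            expected_event=event,
            in_conditions=conds,
            n_junctions=t.n_exons - 1,
            status=status,
        )

    catalogs = {
        cond: build_catalog(isoforms[cond], label=cond) for cond in CONDITIONS
    }
    truth = GroundTruth(
        isoforms=iso_truth,
        catalogs=catalogs,
        junction_motifs=motifs,
        dropped=dropped,
    )
    return SimulatedDataset(
        config=config,
        chrom=chrom,
        sequence=sequence,
        annotation=annotation,
        isoforms=isoforms,
        sj_tables=sj_tables,
        expression=expression,
        deg_records=deg_records,
        truth=truth,
    )
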