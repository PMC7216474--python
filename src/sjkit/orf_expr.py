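"""ORF finding on spliced transcripts, expression support and summaries.

The ORF finder is a deliberate longest-ORF heuristic on the sense strand
(spliced transcripts are already oriented, so a 6-frame scan would only
hallucinate antisense ORFs). Expression support and differential-expression
filtering implement threshold contracts over tables produced by upstream
quantifiers; the statistics themselves (TPM, fold-change p-values) are
consumed, not computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .formats import GenomeAccessor, TranscriptModel, reverse_complement

STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class ORFCall:
    transcript_id: str
    aa_length: int            # codons translated, stop excluded
    cds_start_tx: int         # transcript coordinates, nucleotides, half-open
    cds_end_tx: int

    def __post_init__(self) -> None:
        if self.aa_length < 0:
            raise ValueError("aa_length must be >= 0")
        if self.cds_end_tx - self.cds_start_tx != 3 * (self.aa_length + 1):
            raise ValueError("CDS span must cover the peptide plus its stop")


@dataclass(frozen=True)
class ExpressionRecord:
    isoform_id: str
    gene_id: str
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError("tpm must be non-negative")


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    log2fc: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def transcript_sequence(iso: TranscriptModel, genome: GenomeAccessor) -> str:
    """Spliced transcript sequence, 5'->3' (reverse-complemented on '-')."""
    s = "".join(genome.fetch(iso.chrom, e.start, e.end) for e in iso.exons)
    return reverse_complement(s) if iso.strand == "-" else s


def find_longest_orf(seq: str, transcript_id: str = "") -> Optional[ORFCall]:
    """Longest ATG..stop ORF over the three sense frames.

    Ties are broken by the smallest start position. Returns None when no
    ATG has an in-frame stop downstream.
    """
    best: Optional[Tuple[int, int]] = None  # (-aa, start) minimised
    best_call: Optional[ORFCall] = None
    n = len(seq)
    for frame in range(3):
        next_stop: Dict[int, int] = {}
        stop_pos = None
        # walk codons right-to-left recording the nearest downstream stop
        positions = range(frame, n - 2, 3)
        for pos in reversed(positions):
            if seq[pos : pos + 3] in STOPS:
                stop_pos = pos
            next_stop[pos] = stop_pos
        for pos in positions:
            if seq[pos : pos + 3] == "ATG":
                stop = next_stop[pos]
                if stop is None:
                    continue
                aa = (stop - pos) // 3
                rank = (-aa, pos)
                if best is None or rank < best:
                    best = rank
                    best_call = ORFCall(transcript_id, aa, pos, stop + 3)
    return best_call


def support_flags(
    records: Sequence[ExpressionRecord],
    tpm_threshold: float = 1.0,
    dominance_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-isoform expression-support and dominance flags.

    ``supported`` means tpm strictly above ``tpm_threshold``; ``dominant``
    means the isoform contributes strictly more than ``dominance_threshold``
    of its gene's summed TPM (false when the gene total is zero).
    """
    if tpm_threshold <= 0 or dominance_threshold <= 0:
        raise ValueError("thresholds must be positive")
    df = pd.DataFrame(
        {
            "isoform_id": [r.isoform_id for r in records],
            "gene_id": [r.gene_id for r in records],
            "tpm": [r.tpm for r in records],
        }
    )
    if df.empty:
        df["gene_total"] = pd.Series(dtype=float)
        df["supported"] = pd.Series(dtype=bool)
        df["dominant"] = pd.Series(dtype=bool)
        return df
    df["gene_total"] = df.groupby("gene_id")["tpm"].transform("sum")
    df["supported"] = df["tpm"] > tpm_threshold
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(df["gene_total"] > 0, df["tpm"] / df["gene_total"], 0.0)
    df["dominant"] = frac > dominance_threshold
    return df


def deg_filter(
    records: Sequence[DEGRecord], lfc: float = 1.0, alpha: float = 0.05
) -> Set[str]:
    """Genes passing |log2FC| >= lfc and p <= alpha (both inclusive)."""
    return {
        r.gene_id
        for r in records
        if abs(r.log2fc) >= lfc and r.p_value <= alpha
    }


def length_summaries(
    groups: Mapping[str, Sequence[float]]
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Quartile summaries per group and pairwise Mann-Whitney U p-values.

    Quantiles use linear interpolation; the two-sided U test uses the
    normal approximation with tie correction.
    """
    for name, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"group {name!r} is empty")
    names = list(groups)
    summary = pd.DataFrame(
        {
            "group": names,
            "n": [len(groups[g]) for g in names],
            "q25": [float(np.percentile(groups[g], 25)) for g in names],
            "median": [float(np.percentile(groups[g], 50)) for g in names],
            "q75": [float(np.percentile(groups[g], 75)) for g in names],
        }
    ).set_index("group")
    pvals = pd.DataFrame(1.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = stats.mannwhitneyu(
                groups[a], groups[b], alternative="two-sided", method="asymptotic"
            )
            pvals.loc[a, b] = pvals.loc[b, a] = float(res.pvalue)
    return summary, pvals


# ---------------------------------------------------------------------------
# table readers (headered TSV)

def read_expression_table(path: str) -> pd.DataFrame:
    """Expression TSV: isoform_id, gene_id, one tpm_* column per condition."""
    df = pd.read_csv(path, sep="\t")
    required = {"isoform_id", "gene_id"}
    if not required <= set(df.columns):
        raise ValueError(f"expression table needs columns {sorted(required)}")
    return df


def expression_records(
    df: pd.DataFrame, tpm_column: str
) -> List[ExpressionRecord]:
    return [
        ExpressionRecord(r.isoform_id, r.gene_id, float(getattr(r, tpm_column)))
        for r in df.itertuples(index=False)
    ]


def read_deg_table(path: str) -> List[DEGRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "p_value"}
    if not required <= set(df.columns):
        raise ValueError(f"DEG table needs columns {sorted(required)}")
    return [
        DEGRecord(r.gene_id, float(r.log2fc), float(r.p_value))
        for r in df.itertuples(index=False)
    ]
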