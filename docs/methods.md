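# Methods

## Coordinate model

Every type in `sjkit` stores 0-based half-open genomic intervals. GTF
(1-based inclusive) and STAR `SJ.out.tab` (1-based first/last intron base)
are converted at the parser/writer boundary; no other module performs ±1
arithmetic, so `intron length == end − start` holds everywhere. A splice
junction is the intron interval itself: `start` is the first intronic
base, `end` is one past the last. The minimum representable intron is 4 bp
(room for the donor and acceptor dinucleotides).

## Chain validation

An isoform model is accepted when **every** junction of its chain has a
short-read record at *exactly* the same coordinates. There is deliberately
no fuzz window: a tolerance of even a few nucleotides would silently admit
wobbly junctions, which is precisely the error mode the validation exists
to remove. Matching is strand-aware, with one exception: STAR emits strand
code 0 ("undefined") for some junctions, and those records answer queries
from either strand — discarding them would bias validation against genes
on one strand.

Parameters:

- `min_unique` (default 1 read) — minimum uniquely-mapped read count for a
  junction record to count as support. 1 is the weakest non-trivial
  contract; raising it can only shrink the retained set (validation is
  monotone in this threshold).
- `keep_mono_exon` (default true) — mono-exon isoforms carry no chain and
  therefore no evidence either way; they are retained and flagged rather
  than silently filtered.

## Junction motifs

Donor and acceptor dinucleotides are read in transcription orientation:
on `+`, donor = genome[start, start+2) and acceptor = genome[end−2, end);
on `−` both are reverse-complemented and swapped. Canonical pairs are
GT-AG, GC-AG and AT-AC; everything else is non-canonical.

## Collapse

Multi-exon isoforms are redundant iff they share (chrom, strand, complete
junction chain); transcribed ends are ignored, so 3′/5′ end variation of
the same splice structure collapses to one isoform. Mono-exon isoforms are
clustered by single-linkage any-overlap on the same strand — the simplest
deterministic rule. The representative is the member with the longest
genomic span, ties broken by lexicographically smallest identifier.
5′-truncated chains are **not** merged into their longer parents by
default (`merge_5prime_truncated=False`): merging would erase the ISM
category downstream; the flag enables the alternative behaviour.

## Structural classification

Decision order (first match wins):

1. **FSM** — query chain equals a same-strand reference transcript chain.
2. **ISM** — query chain is a *strict contiguous* sub-chain of one. A
   gapped subset implies skipping and is not ISM.
   Mono-exon queries: FSM requires coincidence with a mono-exon reference
   transcript, both ends within `mono_exon_tol` (default 50 bp — exact end
   matching is unrealistic for long reads; the tolerance is explicit
   config, not hidden); ISM requires containment in a single reference
   exon.
3. **Fusion** — exonic overlap with ≥ 2 same-strand genes whose spans do
   not overlap each other (the span-disjointness condition prevents
   nested or overlapping gene annotations from producing spurious
   fusions). Checked before NIC/NNC so a read-through over two genes is
   not mislabelled as a novel combination.
4. **NIC** — multi-exon, every junction's donor *and* acceptor present in
   the same-strand annotated site sets. Site sets are global per
   (chrom, strand), not restricted to the overlapping gene, which avoids
   ambiguity at overlapping loci.
5. **NNC** — multi-exon, overlapping a same-strand gene span, with ≥ 1
   novel donor or acceptor.
6. **Genic_Intron** — every query exon inside a single same-strand gene's
   intronic union.
7. **Genic_Genomic** — remaining same-strand gene-span overlap (mixes
   exonic and intronic/flanking sequence).
8. **Antisense** — overlaps gene spans only on the opposite strand;
   evaluated after all same-strand relations fail because same-strand
   evidence dominates.
9. **Intergenic** — no gene-span overlap at all.

The classifier is exhaustive and exclusive by construction; the test suite
checks it against an independent brute-force implementation that evaluates
the definitions by base-set arithmetic over an exhaustively enumerated
locus (all junction subsets, ±6 nt single-site shifts, both strands, plus
a mono-exon panel).

## AS events

Events are generated from transcript pairs and deduplicated by their
coordinate tuple within (gene, type) — variant-pair semantics, not a
splicing graph. Genomic patterns are matched first and mirrored by strand
on emission (e.g. a shared-genomic-end/variant-genomic-start junction pair
is A5 on `+` and A3 on `−`), which keeps the matcher free of duplicated
strand logic.

- **SE** — T_a has consecutive junctions (e1,s2),(e2,s3) flanking exon
  (s2,e2); T_b has junction (e1,s3). Coordinates (e1,s2,e2,s3).
- **RI** — T_a has junction (e1,s2); T_b has a single exon extending
  *strictly* beyond both intron boundaries (exon.start < e1,
  exon.end > s2). Boundary-touching cases are terminal-exon patterns, not
  retention. Coordinates (exon_start,e1,s2,exon_end).
- **A5/A3** — two junctions share one boundary and differ at the other;
  the outer junction's variant boundary must fall *strictly inside* the
  partner's flanking exon (the non-strict case is the AF/AL pattern and
  would otherwise be double-counted).
- **MX** — consecutive junction pairs sharing both outer boundaries with
  non-overlapping internal exons.
- **AF/AL** — non-overlapping terminal exons each splicing to the same
  anchor boundary.

Inclusion witnesses are the isoforms carrying the extra sequence (the
exon for SE, the retained intron for RI, the longer exon for A5/A3, the
genomic-left exon for MX/AF/AL); witness lists accumulate over all pairs
showing the same event.

The two-condition comparison is presence-based: an event is
condition-specific when its (gene, type, coordinates) key appears in one
catalog only. Genes are then lifted from the specific events and
partitioned by the DEG set. No ΔPSI or read-count quantification is
attempted — event presence in the isoform catalogs is the comparison.

## ORFs, expression, summaries

The ORF finder scans the three sense frames of the spliced, oriented
transcript for ATG…first-in-frame-stop spans and returns the longest
(ties: smallest start). It is a deliberate heuristic stand-in for a
coding-potential model; the visible contract downstream is the length
filter (default > 100 aa, strict, counting amino acids excluding the
stop). Six-frame scanning is avoided because spliced transcripts have a
defined sense and antisense ORFs would be artifacts.

Expression support uses strict inequalities as printed in the thresholds
it implements: supported ⇔ TPM > 1; dominant ⇔ isoform TPM > 50% of its
gene's summed TPM (false when the gene total is zero — with the default
threshold at most one isoform per gene can be dominant). The DEG filter is
inclusive on both bounds: |log2FC| ≥ 1 and p ≤ 0.05. Quantile summaries
use linear interpolation (the common default, stated here for
reproducibility); the Mann-Whitney U test is two-sided with the normal
approximation and tie correction, cross-checked in the tests against a
rank-based permutation oracle.

## Synthetic data generator

`simulate_dataset` emulates a two-condition hybrid study: non-overlapping
multi-exon genes on one chromosome (fixed 1 kb spacers, one annotated
full-chain transcript per gene), query isoforms consisting of the
reference transcripts plus perturbed novels, per-condition STAR-style SJ
tables containing every true junction (optionally thinned by coupled
dropout) plus spurious decoys sampled disjoint from true coordinates, an
expression table with arbitrary positive TPMs, and a per-gene
differential-expression table. The treated condition receives extra
perturbations drawn from the event-producing operations only (exon skip,
intron retention, donor/acceptor shift, novel exon), so condition-specific
events exist by construction.

Default conditions: 20 genes, 4–7 exons of 80–300 bp, introns 60–400 bp,
2–3 untreated isoforms per gene (reference included), one extra treated
novel per gene, boundary shifts of 6 nt, dropout 0, no decoys, all introns
canonical (85% GT-AG / 10% GC-AG / 5% AT-AC). Intron retention is applied
only to internal introns (a retained terminal intron would leave a
contiguous sub-chain, i.e. an ISM, not a NIC). A single RNG stream is
consumed in documented order, and dropout uniforms are drawn even when
dropout is 0, so datasets from the same seed with different dropout rates
are coupled: raising dropout can only remove junctions.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: read-level errors and coverage gradients
(junction support counts are arbitrary), soft-clipped or mis-aligned exon
boundaries, overlapping or nested genes, multi-chromosome genomes,
realistic expression structure, and junction decoys that collide with
true junctions (decoys are sampled disjoint so expected validation
outcomes stay exactly computable).

## Pipeline

Stage order is validation → collapse → classification → events →
comparison; a flag (`collapse_before_validation`) flips the first two for
sensitivity analysis. All randomness is confined to the simulator; the
pipeline is deterministic, and the JSON manifest echoes the
analysis-relevant configuration (output directory and log level are
excluded so identical inputs yield byte-identical manifests).

## Problem sizes

The test suite and `scripts/acceptance.py` run at desk scale, chosen so
each property is exercised well clear of edge effects: 50-gene
two-condition datasets (~300 isoforms) for validation and end-to-end
checks, 500 random toy genes for the event oracle, ~250 queries for the
exhaustive classification oracle, 1000 planted introns for motif
recovery, and n = 500 per group with a 15% median shift (lognormal
σ = 0.8) for the distribution-shift check — a spread at which the
asymptotic p-value (~10⁻³) is resolvable by a 10,000-permutation oracle.

## Known limitations

- Validation is exact-coordinate by design; junctions supported with
  ±1–2 nt wobble in the short reads count as unsupported.
- Fusion detection requires span-disjoint partner genes and exonic
  overlap; read-throughs across overlapping gene annotations fall into
  NIC/NNC/Genic categories instead.
- The longest-ORF heuristic has no coding-potential model behind it;
  short upstream ORFs and non-ATG starts are invisible.
- Event comparison is qualitative (presence/absence); biological
  significance of condition-specific events still needs quantitative
  follow-up.
- BAM input is out of scope; alignments must arrive as BED12 or GTF exon
  chains.
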