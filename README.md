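# sjkit

**Splice-junction chain validation and quality control for hybrid
long-read / short-read transcriptomics.**

Long-read sequencing (PacBio Iso-Seq and similar) reads whole transcript
isoforms but at modest depth and with noisy splice boundaries; short-read
RNA-seq cannot phase distant exons but detects splice junctions with high
coverage and base-level precision. `sjkit` implements the hybrid workflow
that combines the two: a long-read isoform model is trusted only if **every
intron in its splice-junction (SJ) chain is matched exactly, at genomic
coordinates, by a short-read junction** — partial matches are rejected.
Validated models are collapsed into non-redundant isoforms, classified
structurally against a reference annotation, and mined for local
alternative-splicing (AS) events, including a two-condition comparison
that finds genes with condition-specific AS.

The toolkit is aimed at people doing isoform-level QC of long-read
transcriptomes (plant or otherwise) who have a genome, a GTF annotation,
long-read alignments (BED12/GTF exon chains) and STAR `SJ.out.tab` files.

## What it computes

- **Chain validation** — for each isoform with exon chain
  $e_1, \dots, e_n$ and intron chain $j_i = [\mathrm{end}(e_i),
  \mathrm{start}(e_{i+1}))$, the isoform is *valid* iff every $j_i$ has a
  short-read record at identical coordinates (same strand, or STAR's
  undefined strand) with `unique_reads >= min_unique` (default 1).
  Mono-exon isoforms have no chain; they are retained and flagged.
- **Junction motifs** — donor/acceptor dinucleotides in transcription
  orientation; canonical = GT-AG, GC-AG or AT-AC, all else non-canonical.
- **Collapse** — isoforms with identical (chrom, strand, full SJ chain)
  merge into one cluster; the representative is the longest-spanning
  member. Mono-exon isoforms cluster by same-strand overlap.
- **Structural categories** — FSM, ISM, NIC, NNC, Genic_Genomic,
  Genic_Intron, Antisense, Fusion, Intergenic (SQANTI-style; see
  `docs/methods.md` for the exact decision order).
- **AS events** — SE, A5, A3, MX, RI, AF, AL, generated pairwise over each
  gene's isoforms and deduplicated by coordinates; two catalogs are
  compared by event presence to yield condition-specific AS genes,
  partitioned by a DEG list (|log2FC| ≥ 1 and p ≤ 0.05, inclusive).
- **ORFs and expression support** — longest sense-strand ORF per
  transcript (ATG to first in-frame stop, 3 frames); novel-isoform support
  (TPM > 1, strict) and gene-level dominance (> 50% of gene TPM, strict);
  quartile summaries with two-sided Mann-Whitney U tests.

A seeded simulator (`sjkit simulate`) generates toy genomes, annotations,
isoform sets and SJ tables with complete ground truth, so the entire
workflow is testable offline.

## Worked example

Simulate a 6-gene two-condition dataset and run the stages:

```bash
sjkit simulate --seed 11 --n-genes 6 --spurious-sj-rate 20 --outdir demo
sjkit validate --isoforms demo/isoforms_treated.bed --sj demo/sj_treated.tab \
               --out-prefix demo/val
# retained 20/20 isoforms
sjkit classify --isoforms demo/isoforms_treated.bed \
               --annotation demo/annotation.gtf --out-prefix demo/cls
# FSM 6 / ISM 1 / NIC 8 / NNC 5
sjkit events --isoforms demo/isoforms_untreated.bed --out demo/ev_a.tsv
# SE:3 A5:0 A3:0 MX:0 RI:4 AF:0 AL:0
sjkit events --isoforms demo/isoforms_treated.bed --out demo/ev_b.tsv
# SE:8 A5:1 A3:0 MX:0 RI:6 AF:0 AL:0
sjkit compare --catalog-a demo/ev_a.tsv --catalog-b demo/ev_b.tsv \
              --deg-list demo/deg.tsv --out-prefix demo/cmp
# {"n_asg_b": 6, "n_asg_b_deg": 0, "n_asg_b_non_deg": 6, "n_events_only_in_b": 8}
```

Reading the output: all 20 treated-condition isoform models validate
because the simulated SJ tables contain every true junction (the 20 decoy
junctions never touch a real chain). Six models are exact reference
matches (FSM), the rest are planted novel isoforms — exon skips and
retained introns (NIC, annotated sites in new combinations), shifted
donors/acceptors and novel exons (NNC, novel sites). The treated condition
carries 8 AS events absent from the untreated catalog, spread over 6
genes; none of those genes passes the DEG threshold, so all 6 are
condition-specific AS genes without an abundance change.

`demo/val.validation.tsv` holds the per-isoform report:

```
isoform_id            status  n_junctions  n_missing  min_support
g0001.nA1.novel_exon  valid   4            0          16
g0001.nB1.skip_exon   valid   2            0          13
g0001.t1              valid   3            0          13
```

The full pipeline (`sjkit run --config cfg.json`) chains
validate → collapse → classify → events → compare and writes a
deterministic `manifest.json` with every stage count.

## Layout

```
src/sjkit/formats.py     GTF / BED12 / STAR SJ.out.tab / FASTA IO, core types
src/sjkit/junctions.py   SJ chains, motif classification, chain validation
src/sjkit/collapse.py    non-redundant isoform collapse
src/sjkit/classify.py    structural categories vs reference annotation
src/sjkit/events.py      local AS events and condition comparison
src/sjkit/orf_expr.py    ORFs, expression support, DEG filter, summaries
src/sjkit/simulate.py    seeded synthetic datasets with ground truth
src/sjkit/pipeline.py    end-to-end orchestration and manifest
src/sjkit/cli.py         `sjkit` command-line interface
```
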