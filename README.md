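# tagdge

Tag-based digital gene expression (DGE) analysis: from raw 21-nt
restriction-anchored tag reads (NlaIII `CATG` + 17 nt) to differential
expression and term enrichment.

The package implements the full analysis chain used in classic DGE tag
profiling of two libraries without replicates:

- **simulate** — synthetic reference transcriptomes (every gene carries a
  tag site), ground-truth expression with planted log2 fold changes, raw
  tag libraries with substitution noise / adaptor artifacts / low-quality
  reads, gene→term annotation tables with optional planted enrichment,
  and qPCR Ct tables.
- **tags** — raw-read cleaning (adaptor removal, Phred threshold,
  ambiguous bases) into distinct-tag count tables with raw/clean totals.
- **mapping** — exact-match tag index over every `CATG`+17 window of each
  gene and its reverse complement (sense-only mode available); tags are
  classified unambiguous / ambiguous / unmapped, and only unambiguous
  tags contribute to gene counts.
- **diffexpr** — TPM normalization (tags per million clean tags), the
  exact two-library conditional count test (two-sided: twice the smaller
  tail, capped at 1, evaluated in log space), Benjamini–Hochberg FDR,
  DEG calls at FDR < 0.001 and |log2 ratio| ≥ 1, fold-change binning and
  Pearson correlation of log2(TPM+1).
- **enrichment** — upper-tail hypergeometric over-representation of DEG
  sets against flat term→gene annotations, background = annotated genes.
- **qpcr** — 2^−ΔΔCt relative quantification and direction-of-change
  concordance with DGE calls.
- **pipeline** — end-to-end orchestration for a two-species × two-host
  design with deterministic report bundles (library-statistics table,
  DEG tables/summaries, enrichment tables, manifest) and a verification
  pass that re-derives every report number from the serialized
  intermediates.

## CLI

```sh
tagdge simulate --config sim.yaml --out data/         # synthetic dataset
tagdge clean    --fastq data/reads_A.fastq --out-prefix work/A
tagdge index    --reference data/reference.fasta --out work/index.tsv
tagdge map      --tags work/A.tags.tsv --index work/index.tsv \
                --reference-size 500 --out-prefix work/A
tagdge diffexp  --counts-a work/A.gene_counts.tsv --counts-b work/B.gene_counts.tsv \
                --clean-total-a 99000 --clean-total-b 98000 --out-prefix work/B_vs_A
tagdge enrich   --degs work/B_vs_A.degs.tsv --annotation data/annotation.tsv \
                --category pathway --out work/enrichment.tsv
tagdge qpcr     --ct data/qpcr_ct.tsv --degs work/B_vs_A.degs.tsv --out work/qpcr.tsv
tagdge report   --config run.yaml                     # full pipeline
tagdge verify   --run-dir run_output/                 # re-derive report numbers
```

A `report` run configuration names references (FASTA), libraries (FASTQ
or pre-counted tag TSV, each tied to a reference), within-reference
comparisons, optional annotation TSVs, and thresholds; see
`tests/test_pipeline.py` for a complete example.

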