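# sexmeth

Factorial analysis of sex-biased DNA methylation from WGBS-style per-CpG
count tables. The pipeline compares five genotype/phenotype groups (XX.F,
XY.F, XY.M, XO.F, XXPaf.F) across four baseline-vs-other contrasts and:

- calls differentially methylated CpG sites with a 500 bp smoothed,
  dispersion-aware Wald test (`sexmeth.dmc`);
- calls regions by two independent strategies — a scan over runs of
  significant CpGs with length/CpG/difference constraints, and fixed 300 bp
  tiles with an overdispersion-corrected chi-square — and unions them with
  scan priority (`sexmeth.dmr`);
- intersects the four comparisons (UpSet-style exclusive subset counts) and
  classifies sites/regions into sex-phenotype-, X-dosage-, and
  Y-chromosome-dependent classes (`sexmeth.classify`);
- annotates regions against CpG-island geography (island/shore/shelf/
  inter-CGI), genic features, and chromatin states, and tests repeat
  family/subfamily enrichment with a distance-matched permutation null
  (`sexmeth.annotate`);
- assigns regions to proximal genes (genic footprint + 5 kb upstream),
  tests DEG enrichment (hypergeometric) and the directional
  methylation-expression association (continuity-corrected chi-square), and
  runs mouse-human ortholog overlap tests (`sexmeth.integrate`);
- generates fully synthetic cohorts with planted effect regions, coupled
  expression effects, and annotation tracks so that every stage is testable
  without external data (`sexmeth.simulate`).

## Command line

```sh
# synthetic cohort
sexmeth simulate --out sim/ --seed 1

# one comparison, site level
sexmeth dmc --design XX.F_vs_XY.M \
    --sample XX.F_1:XX.F:sim/XX.F_1.cpg.tsv ... --out dmc.tsv

# region level (scan | tiles | union)
sexmeth dmr --mode union --design XX.F_vs_XY.M \
    --dmc-table dmc.tsv.all.tsv --sample ... --out dmr.bed

# cross-species overlap
sexmeth xspecies --orthologs map.tsv --mouse-genes mouse.txt \
    --human-genes human.txt --chrom-class X

# full pipeline from one YAML config (see tests/test_cli.py for the schema)
sexmeth run --config cfg.yaml
```

`sexmeth run` requires every stage threshold to be stated explicitly in the
config (`sexmeth.cli.REFERENCE_THRESHOLDS` holds the reference defaults:
window 500 bp, p < 1e-5, |difference| > 0.20, region constraints
{50 bp, 3 CpG, 100 bp merge}, tiles {300 bp, q < 0.05}, depth [10, 500],
1000 permutations, 5 kb proximal cutoff, DEG {|lfc| > 1.5, padj < 0.05}),
and writes a machine-readable `manifest.json`; identical config + seed
gives identical outputs.

## Data formats

- CpG report: TSV `chrom  pos  meth_count  total_count` (1-based positions,
  optional header, gzip-transparent).
- Tracks: BED3/BED6 (+label) with 0-based half-open coordinates; repeats as
  5-column BED (chrom, start, end, family, subfamily); gene models as BED12
  or minimal GTF.
- DEG tables: TSV `gene_id  log2fc  padj  chrom`. Ortholog map: TSV
  `mouse_gene  human_gene  chrom_class` with class in {autosomal, X}.
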