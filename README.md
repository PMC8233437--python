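# zwdosage

Analysis pipeline for chromosome-resolved dosage-compensation studies in
WZ/ZZ (female-heterogametic) systems, from contig-level genome data to
expression statistics:

- **Synthetic data** (`zwdosage.simulate`) — ZW genomes with a fused Z
  (ancestral Z + former autosome), 1-to-1 ortholog maps with a
  configurable transposition rate, sex-structured DNA coverage tables,
  and negative-binomial RNA-seq counts with per-segment per-sex dosage
  factors, planted sex-biased genes and lncRNA level/specificity
  differences — all with emitted ground truth.
- **Genome assignment** (`zwdosage.assignment`) — ortholog-plurality
  contig anchoring, fusion detection along scaffolds, read-weighted
  coverage normalization, sample QC (low coverage, heterogeneity),
  sex-mislabel detection from Z-coverage profiles, male:female coverage
  linkage classification (autosomal / Z-linked / W-candidate), and the
  alignment-span chimeric-scaffold rule.
- **Expression** (`zwdosage.expression`) — exon-collapsing with
  structural-RNA masking, TMM normalization factors, CPM / log2CPM /
  FPKM, the ≥1 CPM in ≥2 samples expressed-gene filter, the tau
  specificity index, and a minimal Welch/BH sex-bias classifier for
  synthetic data.
- **Dosage statistics** (`zwdosage.dosage`) — Z:A median expression
  ratios and female:male equalization with rank tests under Bonferroni,
  the generalized (general-association) Cochran–Mantel–Haenszel test
  over expression-threshold strata, adjusted standardized residuals,
  the continuity-corrected two-proportion chi-square test, and a
  probability-mass two-sided Fisher exact test.
- **lncRNA** (`zwdosage.lncrna`) — structural acceptance rules
  (mature length > 200 nt, ≥ 1 splice junction, sense-overlap
  rejection) and positional classification (intergenic / antisense /
  intronic) with repeat-overlap flagging, plus lncRNA-vs-coding
  proportion contrasts.

## CLI

```sh
zwdosage simulate --seed 1 --out-dir fixtures/        # synthetic tables + truth
zwdosage anchor   --orthologs fixtures/orthologs.tsv --contigs fixtures/contigs.fai --out assign.tsv
zwdosage sexassign --coverage fixtures/coverage.tsv --samples fixtures/dna_samples.tsv \
                   --contigs fixtures/contigs.fai --out-dir sex/
zwdosage chimera  --aln spans.paf --contigs fixtures/contigs.fai --out chimera.tsv
zwdosage expr     --counts fixtures/counts.tsv --gene-meta fixtures/gene_meta.tsv \
                  --samples fixtures/rna_samples.tsv --out-dir expr/
zwdosage dosage   --fpkm expr/fpkm.tsv --segments segments.tsv \
                  --samples fixtures/rna_samples.tsv --out-dir dosage/
zwdosage sexbias  --bias bias.tsv --segments segments.tsv --fpkm expr/fpkm.tsv --out-dir sexbias/
zwdosage lncrna   --candidates cand.gff3 --coding genes.gff3 --repeats repeats.bed --out lnc.tsv
```

Simulation parameters can be supplied as YAML (`--config sim.yaml`);
keys mirror `zwdosage.simulate.SimulationConfig`. All randomness flows
from the single `seed`.

## Conventions

Internal coordinates are 0-based half-open; GFF3 (1-based closed) and
BED conversions happen only at the I/O boundary. Accepted formats: GFF3
(annotation), BED (repeats), PAF or 6-column TSV (alignment spans),
FAI-style TSV (contig lengths), TSV (counts, coverage, samples,
orthologs), YAML/JSON (config).
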