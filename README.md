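# ampdesign

Design toolkit for highly multiplexed amplicon genotyping assays around
CRISPR knockout screens and natural-variation (eco-tilling) screens.

Characterising mutations in tens to hundreds of candidate genes — whether
induced by Cas9 or present as natural alleles in a germplasm collection —
is cheapest with multiplex PCR amplicon sequencing (HiPlex): one reaction
amplifies all target regions, short reads resolve the haplotypes.  Getting
there requires a design step that is tedious and error-prone by hand,
especially inside gene families where paralogous sequence causes
cross-amplification and off-target guides.  `ampdesign` automates it:

* **Target extraction** — pull candidate genes (optionally with flanks)
  out of a genome FASTA + GFF3, reverse-complement minus-strand genes so
  every CDS is on the + strand, and remap all features to per-gene
  coordinates.
* **gRNA filtering** — consume guide tables from upstream designers
  (FlashFry- or CRISPOR-style) and remove guides with Pol III terminator
  poly-T runs (≥ 4 T), restriction sites in the simulated cloning construct
  (promoter + spacer + scaffold, both strands), cut sites outside a chosen
  CDS window or feature type, or specificity scores below a threshold.
* **Amplicon design** — enumerate up to 150 candidate primer pairs per
  gene in a configured size range (nearest-neighbour Tm scoring, primers
  spaced ≥ 5 bp, no Ns, homopolymer-containing products ≥ 10 nt removed),
  then screen every primer for mispriming against the *entire* reference
  set: ≤ 1 binding site per primer (mismatch budget with an exact 3'
  anchor) and no convergent site pair yielding an unintended product.
* **Ranking and selection** — group guides to amplicons (≥ 15 bp between
  primer and protospacer), rank amplicons by (i) guide count, (ii) guide
  overlap, (iii) mean specificity, (iv) mean efficiency score, and select
  a per-gene maximum of top-ranking non-overlapping amplicons.  Without
  guides (NatVar mode) an exact weighted-interval-scheduling DP selects
  non-overlapping amplicons maximising reference coverage, and a
  mask-and-rerun loop builds complementary tiled assays.
* **Outputs** — primer/gRNA TSVs with per-gene dropout reasons, design
  GFF3, border GFF3 + sites BED for downstream haplotyping tools, summary
  tables and debug GFFs.
* **Pooled screening** — expected haplotype frequency in pools (one
  heterozygous diploid in a pool of 10 plants = 1/20 alleles = 5%), 1D/2D
  pool layouts (100 plants → 2 × 10 = 20 pools, a 5-fold PCR reduction)
  and carrier localisation from positive X/Y pool coordinates.

A deterministic synthetic-data generator (`ampdesign.fixtures`) builds
genomes and gene families with exact pairwise identity, so the whole
pipeline is testable without downloads.

## Worked example

Build a synthetic four-gene family (800 bp genes, 70% pairwise identity),
extract the genes from the generated genome, and design a HiPlex assay
(120–150 bp amplicons, ≤ 2 amplicons/gene, ≤ 2 guides/amplicon):

```sh
cat > family.json <<'EOF'
[{"n_genes": 4, "gene_length": 800, "pairwise_identity": 0.7,
  "seed": 11, "family_id": "mapk"}]
EOF
ampdesign fixtures --families family.json --out-prefix demo --seed 11
# -> 4 genes, 40 guides -> demo.*

printf 'mapk_g%d\tmapk\n' 1 2 3 4 > genes.txt
ampdesign targets --genome demo.genome.fasta --gff demo.genome.gff3 \
    --genes genes.txt --out-prefix targets
# -> extracted 4 genes -> targets.fasta/.gff3

ampdesign design --fasta targets.fasta --gff targets.gff3 \
    --guides demo.guides.tsv --preset hiplex --summary --out-dir design
# -> designed 4/4 genes -> design
```

`design/primers.tsv` (1-based inclusive coordinates; the two amplicons per
gene are disjoint and their primers bind nowhere else in the family):

```
gene_id  amplicon_id     primer_id   sequence                  start end  product_size
mapk_g1  mapk_g1_amp35   mapk_g1_F1  TCATGGGCCGCGTTCCTCTA      396   415  150
mapk_g1  mapk_g1_amp35   mapk_g1_R1  CGGGTGCACTTACCACGAGA      526   545  150
mapk_g1  mapk_g1_amp118  mapk_g1_F2  GCAATCGAATGCCAAATCAGAAGT  46    69   148
...
```

`design/guides.tsv` lists the selected guides per amplicon with cut sites
(3 bp 5' of the PAM) and the scores they arrived with; the summary reports
per-family retention — the percentage of genes with at least one amplicon
covering at least two gRNAs:

```
family_id  retention_pct
mapk       100.0
```

Genes that cannot be designed are kept in the TSVs with the first failing
stage (no gRNAs supplied / none passed the filters / no specific amplicons
/ no gRNA–amplicon overlap).  For a pooled natural-variation screen:

```sh
ampdesign pooling --plants 100 --pool-size 10 --dim 2 --out layout.tsv
# -> 20 pools for 100 plants (5.0-fold fewer PCRs) -> layout.tsv
```

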