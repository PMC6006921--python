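# techromatin

Transposable elements (TEs) make up roughly half of the human genome, and a
substantial minority of TE families are not passive passengers: their copies
concentrate in chromatin that a given tissue marks as *active* (promoters,
transcribed gene bodies, enhancers) or as *repressed* (Polycomb H3K27me3,
heterochromatin H3K9me3). `techromatin` is a tested, reusable implementation
of the analysis pipeline behind that kind of study, for genomicists who want
to run it — or stress-test it — without multi-gigabyte downloads: every stage
can be exercised end to end on synthetic data with planted, parameterised
structure and a ground-truth manifest.

The pipeline:

1. **Region extraction** — chromHMM-style dense segmentations (BED4, one
   per tissue) are split into *active* states (`TssA`, `TssAFlnk`, `TxFlnk`,
   `Tx`, `TxWk`, `EnhG`, `Enh`, `TssBiv`, `EnhBiv`) and *repressed* states
   (`Het` → H3K9me3; `ReprPC`, `ReprPCWk` → H3K27me3), merged per tissue.
2. **Permutation enrichment** — for each TE family (or age class) the
   observed number of copies overlapping a region set is compared with its
   distribution over *N* positional shuffles of the catalog (each copy
   re-placed uniformly on its own chromosome, length preserved). The
   two-tailed empirical p-value uses the add-one rule,

       p = min(1, 2 · min(#{exp ≥ obs} + 1, #{exp ≤ obs} + 1) / (N + 1)),

   the odds ratio is OR = obs / mean(exp), and Benjamini–Hochberg FDR is
   applied across the families of each (tissue, activity) run; FDR < 5% is
   the significance criterion.
3. **Composition** — genomic typology of the enriched copies (promoter =
   TSS ± 1 kb, gene body split intron/exon, intergenic; Fisher exact tests
   vs background), TE-class proportion tests (exact binomial against
   catalog-wide class fractions), and the partition of repressed fragments
   between H3K27me3 and H3K9me3, overall and restricted to TE-containing
   fragments.
4. **Tissue specificity** — per family, Z-scores across tissues from the
   enrichment odds ratios: z_t = (OR_t − mean(OR)) / sd(OR).
5. **Expression link** — each TE copy in active or repressed chromatin is
   assigned to the gene with the nearest TSS; genes fall into four
   categories (1 = TE partners only in active chromatin, 2 = mixed,
   3 = repressed only, 4 = no TE). Cross-tissue expression variance,
   normalised by mean TPM (an index of dispersion), is compared across
   categories by Wilcoxon rank-sum tests and by
   `lm(normalized_variance ~ CATEGORY + gene_length + gene_density)`,
   and designated gene sets are tested for focal-tissue expression shifts
   against the mean of the other tissues.

The synthetic generator (`techromatin.synthetic_data`) plants all of these
effects — family-level insertion biases into chosen (tissue, activity)
targets via rejection sampling, dispersion inflation on category-1 genes,
and focal-tissue expression shifts — and records them in `truth.json`.

## Worked example

The numbered drivers under `analysis/` run the pipeline on the default
planted dataset (2 × 5 Mb genome, 4 tissues, 30 families, ~8,000 copies):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_extract_regions.py
python analysis/03_enrichment.py --seed 1 --n-reps 2000
python analysis/04_composition.py
python analysis/05_tissue_specificity.py
```

The enrichment step recovers all five planted families, each in its target
tissue and activity class:

```
240 family tests, 7 at FDR < 5%:
tissue  activity      key  obs_count  exp_mean  odds_ratio  q_value direction
    t1    active F01_SINE        174   62.5600    2.781330 0.014993  enriched
    t1    active F05_LINE         13   46.9825    0.276699 0.014993  depleted
    t1    active  F28_LTR         35   53.6460    0.652425 0.039980  depleted
    t1 repressed  F03_LTR        160   58.0245    2.757456 0.029985  enriched
    t2    active  F02_DNA        140   49.2910    2.840275 0.029985  enriched
    t2 repressed  F04_SVA        122   41.3490    2.950495 0.029985  enriched
    t4    active F12_SINE         37   20.0295    1.847275 0.029985  enriched
```

`F01_SINE` was planted at bias 3 into t1's active chromatin: it overlaps
174 copies where ~63 are expected under uniform placement (OR ≈ 2.8), and
the depleted family (bias 1/3) shows the mirror image. The two extra calls
(`F28_LTR`, `F12_SINE`, both unplanted and at borderline q) are the false
discoveries an FDR-controlled procedure permits at this scale. The
composition step reports that 82.8% of TE-containing repressed fragments
carry H3K27me3, and the Z-score step identifies the planted tissue as the
most specific one for each enriched family
(`F01_SINE: most tissue-specific in t1 (z = 1.49)`).

The expression-variance and shift analyses need many genes spread over a
larger, sparser genome (100 Mb, 2,000 genes, 8 tissues), so they run on the
dedicated expression study:

```sh
python analysis/01_simulate.py --seed 1 --study expression --out-dir results/data_expression
python analysis/02_extract_regions.py --data-dir results/data_expression --out-dir results/regions_expression
python analysis/06_expression_link.py --data-dir results/data_expression \
    --regions-dir results/regions_expression --out-dir results/expression
```

```
gene categories: {'no_te': 1131, 'active_only': 317, 'mixed': 301, 'repressed_only': 251}
  active_any_vs_rest: medians 1.346 vs 0.967, rank-sum p = 8.53e-23
  active_only_vs_mixed: medians 1.990 vs 0.923, rank-sum p = 7.01e-34
  OLS TE-active (cat 1) coefficient: 1.378 (se 0.432, p = 0.00145)
  shift test in t1: direction up, p = 4.4e-17 over 100 genes
```

Genes whose TEs sit in active chromatin carry higher normalised expression
variance (the planted ×2 dispersion corresponds to a coefficient of 1.0 on
this scale; 1.38 ± 0.43 here), and the 100-gene set with a planted 3× shift
in tissue t1 is detected with direction "up".

## Layout

```
src/techromatin/        library: io_formats, chromatin_regions, enrichment,
                        composition, tissue_specificity, synthetic_data, pipeline
analysis/               numbered narrative drivers (01_simulate ... 06_expression_link)
scripts/acceptance.py   end-to-end recomputation of the headline quantities
tests/                  pytest suite incl. oracle-based and planted-recovery checks
docs/methods.md         models, parameters, numerical choices, limitations
```
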