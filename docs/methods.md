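# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `techromatin`. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED convention); the
RepeatMasker `.out` reader converts its 1-based inclusive coordinates on
input. Strand is stored but ignored by every overlap computation — none of
the analyses conditions on strand. Gene models are read from BED12 rather
than GTF because BED12 carries exactly the fields used (TSS, exon blocks,
gene span); a GTF reader is out of scope. Readers validate against a bound
chromosome-sizes table, reject overlapping segmentation records, and can
optionally coalesce abutting same-state records (off by default, since
dense segmentations are usually already maximal).

## Chromatin activity classes

The 15 chromHMM coreMarks mnemonics partition into *active*
(TssA, TssAFlnk, TxFlnk, Tx, TxWk, EnhG, Enh, TssBiv, EnhBiv), *repressed*
(Het, ReprPC, ReprPCWk) and *neither* (ZNF/Rpts, BivFlnk, Quies, plus any
unknown label). The bivalent states are counted as active by convention
here, even though they also carry H3K27me3; the mapping is a configurable
`StateMap`, so other conventions or chromHMM models can be supplied as
YAML. Two views of each region set are kept deliberately:

* a **merged** union per tissue and activity class, used for overlap
  counting, so one TE copy spanning two abutting active states counts once;
* the labelled **fragments**, used for the repressive-mark analyses, so
  each repressed fragment has exactly one mark (Het → H3K9me3,
  ReprPC/ReprPCWk → H3K27me3).

## Permutation enrichment

For a group g (family, class or age class), the statistic is the number of
distinct copies overlapping the merged region set by ≥ 1 bp (overlapped bp
are reported alongside but not tested; copy counts are the tested quantity).
The null is generated by re-placing every copy of the catalog uniformly on
its own chromosome with its length preserved (`positional` mode, the
default); shuffled copies may overlap each other, and an optional excluded-
regions BED is honoured by rejection sampling. A second mode
(`label_permutation`) keeps positions fixed and permutes the (family,
class, age) labels; it answers a subtly different question — whether a
label is special *given* the overall TE placement — and is exposed because
the flag semantics of the original tooling admit that reading. Reports name
the mode; neither claims to bit-match the original tool. Both preserve the
per-chromosome multiset of copy lengths and per-family copy numbers.

The empirical two-tailed p-value uses the add-one rule with inclusive tie
handling: `p = min(1, 2·min(#{exp ≥ obs}+1, #{exp ≤ obs}+1)/(N+1))`, so
p ∈ [2/(N+1), 1] and the test is exact-level at finite N. The odds ratio is
obs / mean(exp); when mean(exp) = 0 the OR is undefined (NaN) and such
entries are excluded from Z-score computation. Direction is the sign of
obs − mean(exp). Expected-count spread is the sample sd (ddof = 1).

Benjamini–Hochberg step-up q-values (monotonicity enforced) are computed
across the groups of one (tissue, activity) run; no cross-tissue joint
correction is applied, matching the per-tissue "enriched in at least one
tissue" reading. Note a discreteness interaction worth knowing: with N
replicates the smallest attainable p is 2/(N+1), so a *single* true signal
among m groups can only clear FDR α if 2/(N+1) ≤ α/m. The analysis drivers
default to N = 1000; the acceptance script uses N = 2000 so that one
discovery among 30 families clears 5%.

Reproducibility: one master seed; each replicate draws from an independent
substream spawned from the master generator, and the catalog is canonically
sorted before substreams are assigned, so results are bit-identical across
runs and independent of input row order.

## Age classes

Age classes are lineage labels attached per family (e.g. Vertebrata,
Mammalia, Eutheria, Primates, Hominidae). Besides per-class tests, a
two-level summary groups classes into *ancient* vs *young* using a
configurable lineage ordering split at Eutheria; Eutheria itself is counted
as ancient (the split point is inclusive on the old side), and labels
absent from the ordering are grouped under "unknown".

## Composition analyses

Typology: promoter = any overlap with a TSS ± 1000 bp window (both flanks
inclusive); else gene body = any overlap with a gene span; else intergenic.
Promoter takes precedence. Gene attribution is by nearest TSS (ties to the
lexicographically smallest gene id); the intron/exon sub-typology uses the
exons of the assigned gene only, so attribution stays single-gene and
deterministic. The typology unit is the TE copy.

The "proportion test" of class composition is a two-sided exact binomial
test of k enriched families of class c among n enriched families against
p0 = the class's share of all annotated families; the normal-approximation
p is reported alongside for comparison. The class-by-mark association tests
count TE copies overlapping repressed fragments; a copy touching fragments
of both marks counts once per mark (the duplication rate is logged), and
each class gets a two-sided Fisher exact test of its H3K9me3/H3K27me3 split
against all other classes.

## Tissue-specificity Z-scores

Per family row of the OR matrix (families × tissues), using finite entries
only: z = (OR − mean)/sd with the sample sd. Rows with fewer than 3 finite
entries or zero spread are reported all-NA rather than ±∞. Rows are
location/scale invariant by construction.

## Expression link

Normalised variance is the sample variance (ddof = 1) of a gene's
per-tissue mean TPMs divided by its grand mean — an index of dispersion.
The alternative reading var/mean² (CV²) is available behind a flag; the
index-of-dispersion form is the default because it makes a multiplicative
dispersion change an additive effect on the response. Genes with grand mean
0 are excluded. Gene density is the union (not the sum) of all exon blocks
within ±100 kb of the gene span, clipped to the chromosome.

Rank-sum tests use the Mann–Whitney U with exact enumeration for small
untied samples and the tie- and continuity-corrected normal approximation
otherwise. The OLS reference level is category 4 (no TE), so category
coefficients read directly as effects of TE association; gene length enters
in raw bp by default (log10 behind a flag).

The focal-tissue shift test compares, over a gene set, the vector of TPMs
in the focal tissue against the vector of per-gene means over all other
tissues, by an unpaired two-sided rank-sum test. Because both vectors are
computed on the same genes, they are positively dependent, which makes the
test *conservative* under the null (its p-values pile up near 1 rather than
being uniform); detections are therefore trustworthy, but the test spends
power. This is a property of the published test definition, kept as is.

## Synthetic data generator

The generator emulates the *structure* of the real inputs, not their
content: multi-tissue dense state tracks, a family/class/age-annotated TE
catalog, BED12 genes with evenly spaced fixed-size exons, and a gene ×
tissue mean-TPM matrix.

* **Segmentations.** Each chromosome is tiled end to end with segments
  whose states are drawn with probability ∝ frequency/mean-length (so the
  emitted *bp* fractions converge to the grammar frequencies) and whose
  lengths are geometric with per-state means. Tissues are independent. The
  default grammar has ~10% active bp, ~15% repressed bp and ~75% quiescent.
* **TE planting.** A family targeted at (tissue T, activity A, bias b) is
  placed by rejection sampling against T's realised regions so that the
  per-copy probability of overlapping A is b times the uniform-placement
  probability (b < 1 plants depletion); the planted quantity is therefore
  directly comparable to the enrichment module's odds ratio. b times the
  uniform overlap probability must be ≤ 1, else the generator raises.
  Realised and background overlap rates go into the truth manifest.
* **Expression.** Each gene has a log-normal baseline mean
  (ln TPM ~ N(3.7, 0.7), i.e. robustly expressed genes around ~40 TPM) and
  per-tissue TPMs drawn Gamma with scale θ (the dispersion), so var/mean = θ
  exactly in expectation. Category-1 genes get θ multiplied by the variance
  inflation factor, making the planted OLS effect θ·(v − 1) on the response
  scale. A designated gene set gets TPM multiplied by the shift fold in the
  focal tissue only. The baseline level matters quantitatively: the
  var̂/mean̂ estimator has the exact expectation θ·Tb/(Tb + θ) for a gene
  with baseline b over T tissues (derived from Gamma/Dirichlet moments), a
  downward ratio bias ≈ θ²/(Tb); at the chosen baseline this is ~1% and
  negligible, while lowly expressed baselines would visibly shrink planted
  effects.

Study conditions are named config factories: the **default** study
(2 × 5 Mb, 4 tissues, 30 families of 100–500 copies, 300 genes) carries the
enrichment narrative; the **null** study (50 unplanted families) calibrates
the permutation test; the **expression** study (4 × 25 Mb, 8 tissues,
15 × 300 copies, 2,000 genes, ~2% active + ~2% repressed bp) carries the
variance and shift analyses. The sparse chromatin of the expression study
is deliberate: with eight independent tissue tracks at dense coverage,
nearly every gene's TE partners touch both activity classes somewhere and
the "mixed" category swallows the catalog; at ~2%+2% coverage all four
categories hold ≥ ~250 genes. Real tissues are strongly correlated, which
would achieve the same end; independent-but-sparse is the simpler model.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: TE sequence content and fragmentation of old
copies, correlated chromatin state across tissues, realistic chromHMM
transition structure, gene clustering and overlapping transcripts, assembly
gaps, and the heavy left tail of lowly expressed genes. Conclusions about
calibration and power transfer to real data only in so far as those
features do not interact with the statistic under test.

## Problem sizes used by the automated checks

The test suite and acceptance script run at desk scale on one CPU: overlap
kernels are verified exactly against brute-force oracles on up to
2,000 × 2,000 random instances; calibration uses 50 families × 200
replicates; planted-recovery and Z-score checks use 20 seeds at the default
study size with 200–1,000 replicates; the expression analyses use 20 seeds
of the expression study. The whole suite runs in a few minutes; the
acceptance script in about 1–2.

## Known limitations

* The positional shuffle is an unconditioned uniform null: no GC, gap or
  chromatin-state matching. Excluded-region support exists but synthetic
  genomes contain no gaps.
* Interrupted TE copies are not reassembled; every annotation row is one
  copy.
* The per-(tissue, activity) FDR scope means cross-tissue multiplicity is
  uncorrected, as in the published criterion ("enriched in at least one
  tissue").
* The shift test's conservativeness under the null (see above) is inherited
  from its definition.
* With N permutation replicates, p-values are discrete multiples of
  2/(N+1); FDR behaviour near the floor should be interpreted with the
  discreteness in mind.
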