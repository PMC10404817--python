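# Methods notes

This note records the model assumptions, parameter choices, numerical
conventions and known limitations of `brainreg`, in the spirit of a
methods supplement. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Differential expression engine

The published analyses this pipeline generalizes use DESeq2's
negative-binomial GLM. Re-implementing DESeq2's dispersion shrinkage is
out of scope here; `brainreg` instead owns a deterministic engine with the
same *decision rule*: per gene, y = log2(count/size factor + 1), a
two-sided test of the brain/nonbrain term (Welch's t when no covariate is
flagged; an OLS fit y ~ group + covariates otherwise), BH adjustment, and
calls at FDR < 0.05 with |log2FC| ≥ 1.5. This is a deliberate, documented
substitution: the selection logic downstream consumes only the calls, and
the engine is exactly reproducible and unit-testable. Consequences: no
shrinkage means slightly less power at very low counts — irrelevant at the
planted effect sizes the generator defaults to, and conservative on real
data.

Conventions worth pinning:

- log2FC is the difference of group means of y (pseudocount 1 on
  normalized counts, so zero counts are bounded), not the model
  coefficient; with balanced covariates the two coincide.
- Covariates enter the design only when the screen flags them (numeric:
  two-sided Mann–Whitney U; sex: Fisher exact on the 2×2 table; flag at
  p < 0.05). A constant covariate gets p = 1 and is never flagged. A
  covariate collinear with the group indicator is dropped with a warning.
  The choice of test per covariate type is this package's decision — the
  upstream convention only says covariates "significantly different
  between groups" enter the design.
- All retention thresholds are strict as worded: reads > 12 M, rate >
  0.70, expressed in > 20% of samples; the fold-change gate is inclusive
  (≥ 1.5). Boundary cases are tested explicitly.
- Median-of-ratios size factors exclude genes with any zero count (their
  geometric mean is zero); the exclusion count is logged. Scaling one
  sample by c rescales the geometric-mean reference, so factor *ratios*
  between samples — the quantity normalization uses — are equivariant,
  not individual factors.

## Selection tree

- "Highest expression among organs" is summarized as the **median of
  median-of-ratios-normalized counts per organ** (mean selectable). The
  upstream description does not fix the summary statistic; the median is
  robust to single outlier samples.
- Organ summaries are computed on the QC-filtered but *not*
  low-expression-filtered study, so every universe gene retains an organ
  profile even if it was dropped from one species' DE stage.
- Ties in the organ argmax fail the filter: "the highest" is read as a
  unique maximum; this is conservative and deterministic.
- The alternative branch (nonprimate brain-*down* ∩ outgroup organ
  filter) is reported as `experimental_subset`. A significant brain-down
  call and a nonbrain top organ are logically aligned but estimated from
  different statistics, so containment in the final set is enforced (with
  a logged count of any violators) rather than assumed.
- Brain vs nonbrain organ labels come from sample metadata, never from
  tissue names.

## Cross-species peak classification

- A conversion through the block map fails when < 95% of bases land in
  blocks (mirroring common liftover defaults) or when the mapped blocks
  disagree on target chromosome or orientation.
- Failed conversion counts as **absent** — the "failed to convert ⇒
  specifically activated" rule — applied in the focal ±2 Mb gene scan
  exactly as stated and generalized symmetrically in the genome-wide
  classifier (absent = unmappable OR mapped-without-overlap).
- Presence across replicate samples defaults to `all_samples` (the
  strictest reading of "present in N samples"); `any_sample` and a
  fractional rule are selectable because the replicate-consensus
  convention is not fixed upstream. Overlap is ≥ 1 bp, unstranded.
- Classification is single-direction (reference → comparator); no
  reciprocal-mapping check is applied.
- Conservation profiles score each alignment column as coverage ×
  similarity, with similarity measured against the designated reference
  row (which counts as matching itself); columns gapped in the reference
  are skipped. Matching is case-insensitive; `-` and `.` are gaps.

## Element-to-gene linkage

- Distance is edge-to-edge to the gene **body** (0 when overlapping), not
  to the TSS: the common annotator default for "nearest gene within
  500 kb". Both `nearest` (ties broken by lexicographically smaller
  gene_id) and `all_within` modes exist because lineage-level counts can
  be read either way; the default is `nearest`.
- Promoter windows are TSS −2000/+1000 bp, strand-aware, clipped at 0. On
  the minus strand the window is the exact genomic mirror.
- Loop assignment reports both routes — direct promoter overlap and
  loop-distal (element on the anchor opposite a promoter-overlapping
  anchor) — and both may fire for one element.

## Overlap statistics

One-sided (enrichment) hypergeometric tail by default, identical to the
one-sided Fisher exact test; two-sided selectable. The universe must be
passed explicitly (by convention the one-to-one ortholog universe) and is
never inferred from set unions. Odds ratios are sample estimates with a
0.5 continuity correction when a cell is zero. Region-vs-region overlap
(e.g. conserved elements vs peaks) is reported as counts and intersection
ratio without a test. BH adjustment spans all cells of a tested matrix.

## Single-cell DEGs

Cluster assignments and cross-species integration are inputs, not
computed here. Label transfer takes, per cluster, the reference species'
cell type with the largest percentage (ties: lexicographically smaller,
flagged). The Wilcoxon rank-sum test uses midranks with the normal
approximation and continuity correction (count data are tie-heavy);
constant genes get p = 1 by convention. Adjustment is Bonferroni within
each (cluster, species-pair) stratum by default — BH selectable — since
the upstream convention says only "adjusted P". Per-stratum control
bounds the chance of any false call per cluster at α, not across all
clusters jointly; the test suite asserts the per-stratum guarantee.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

- **Counts**: negative binomial, var = μ + φμ² (φ = `dispersion`,
  default 0.1 for bulk, 0.5 for single cell). Baseline gene means are
  log-normal (median 150, σ_log 0.8); per-tissue log-normal factors
  (σ 0.15) are shared across species so orthologs agree apart from the
  planted effect; per-sample depth factors (σ_log 0.2) exercise size
  factors.
- **Planted brain bias**: brain-tissue means × `fold_effect` (default 8)
  in the two primates and ÷ `fold_effect` in the nonprimate and outgroup —
  exactly the expression signature the tree detects. Defaults (2000
  genes, 20 planted, 10 samples/tissue, 1 brain + 3 nonbrain organs per
  species, four species: reference primate, comparator primate,
  nonprimate, mouse-like outgroup) are the regime in which recovery is
  provably clean; smaller n or fold weakens it.
- **Covariates** (age, sex, RIN) are balanced by default;
  `confounded_covariates=True` shifts brain-sample ages to exercise the
  screen.
- **Toy assembly**: one chromosome per species, identical (identity)
  coordinates, genes on a regular 10 kb grid with alternating strand.
  Peaks live in a dedicated downstream region on non-overlapping slots;
  planted class labels (shared / primate-specific / human-specific) are
  realized per species either as mapped-but-no-peak or as an unmappable
  map gap (gaps also fill a peak-free filler region up to
  `unmappable_fraction` of the assembly). Enhancer peaks sit in
  promoter-free intergenic zones and are wired by loops to target genes;
  the first loops target the planted single-cell DEG genes so that known
  fractions (defaults 4/20 human-specific, 9/20 primate-specific) of
  DEGs carry elements of each class. RECNE-like elements are placed
  immediately outside their gene so the nearest-gene truth is
  unambiguous.
- **Fetal zones**: planted genes get FPKM in (2, 10) in every human-like
  sample and (0, 0.5) in mouse-like samples; all other genes stay below
  the log2(FPKM+1) = 1 activity threshold in human. Three planted
  fetal-pass genes by default.
- **Seeds**: one master seed; each generator draws from
  `default_rng([stream_label, seed])` with fixed labels, so adding a
  generator never perturbs the others and identical config+seed gives
  byte-identical serialized output.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: mapping/quantification artifacts, GC and length
biases, batch structure, correlated genes, phylogenetic signal in
sequence, incomplete ortholog tables, noisy peak boundaries beyond small
jitter, or cluster-assignment errors upstream of the single-cell stage.

## Problem sizes and determinism

The shipped test and acceptance configurations use 150–2000 genes, 5–10
samples per tissue, up to 10,000 peaks and a few hundred cells — sizes at
which every stage's behavior (recovery, null calibration, classification)
is already asymptotically stable while the full suite runs in about a
minute. The pipeline manifest echoes the complete configuration and the
sha256 of every stage output with paths relative to the output directory,
so identical config+seed re-runs are byte-identical wherever they are
written.

## Known limitations

- The DE engine is not DESeq2; exact p-values differ even though the
  decision rule matches (see above).
- Peak classification trusts the block map; no reciprocal-best check.
- The hypergeometric test assumes exchangeability within the declared
  universe; a biased universe biases enrichment.
- `link_elements_to_genes` is annotation-naive (no synteny awareness).
- Wilcoxon p-values in the single-cell stage are asymptotic; for very
  small clusters (< 3 cells per species) the stratum is skipped rather
  than tested exactly.
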