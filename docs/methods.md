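# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the design decisions behind `trilayer`, in the
order the pipeline applies them.

## Annotation and exonic regions

The annotation is a gene → transcript → exon hierarchy read from
Ensembl-dialect GTF. Coordinates are 1-based closed intervals, so a region
spanning positions `start..end` has length `end − start + 1`, and "shorter
than 100 bp" means length < 100 — a region of exactly 100 bp is kept.

Exonic regions are derived per gene: every distinct exon start/end cuts
the gene's exon union into segments on which the covering transcript set
is constant; each covered segment becomes one region with id
`gene_id:index` (1-based, left to right). Two deliberate conventions:

- **No merging across boundaries.** Adjacent segments with identical
  member sets stay separate, so the region grid mirrors the exon
  structure (two identical transcripts yield regions identical to their
  exon set, not one fused block).
- **Per-gene flattening, strand ignored.** Regions are computed
  independently per gene; a genomic interval overlapped by two genes can
  appear in regions of both. This keeps the region → gene mapping (needed
  for DEE-G sets) unambiguous. Counting-bin tools that flatten whole
  chromosomes may merge overlapping genes differently; results are
  comparable only up to that difference. Strand plays no role anywhere
  downstream, so flattening ignores it.

## Quantification

Naïve FPKM omits effective-length correction:
`FPKM_i = n_i / (n_T × l_i)` (n_T in millions of mapped reads, l_i in
kbp). Totals per sample come from a sidecar TSV, since the package never
sees alignments. The same formula inverted,
`count = round(FPKM × l_kbp × n_T,millions)`, converts FPKM matrices into
pseudo-counts for the NB engine; the round trip is exact on integer
counts. Gene FPKM sums the gene's transcripts; region FPKM sums the
region's member transcripts. Gene length (used only for the FPKM-route
pseudo-counts) is the exon-union length, i.e. the sum of the gene's
region lengths.

Quality filters, applied in order; each feature is removed for at most
one reason:

1. genes whose id appears more than once in the gene expression matrix
   (conflicting upstream records) are dropped;
2. genes with any transcript marked *absent* — a missing value, written
   as the literal `NA`, deliberately distinct from an observed 0 — are
   dropped with all their transcripts;
3. in replicate-discovery mode only, genes/transcripts must have non-zero
   FPKM in both tissues of at least `ceil(n_patients/2 + 0.5)` paired
   patients (39 of 77), so that no training half can end up with a
   near-constant feature. The prevalence filter is applied to genes and
   transcripts, not to exonic regions, whose counts are derived
   quantities.

## The NB testing engine

One engine serves genes, transcripts and exonic regions. The reference
analyses this design emulates used three separate tools at the three
levels, all built on the same distributional family; re-implementing each
tool's internals (in particular the exon-usage interaction GLM of
dedicated exon tools) is out of scope, so exon-level testing here is
differential expression of region counts, not relative-usage testing.
Model for count K in sample s: NB with mean μ·s_s and variance
μ·s_s + α(μ·s_s)².

- **Size factors**: median-of-ratios over features with all-positive
  counts, rescaled to geometric mean 1. Matches DESeq2's estimator
  exactly (cross-checked against pydeseq2 in the test suite).
- **Dispersions**: per feature, the within-group variance of normalized
  counts pooled across the two groups gives
  α̂ = max(0, (s² − μ̄)/μ̄²); a hyperbolic trend α(μ) = a₀ + a₁/μ is fitted
  across features by a Gamma-family GLM (identity link, coefficients
  clipped at 0; ordinary least squares as fallback on degenerate fits).
  The final dispersion is max(per-feature, trend) — deliberately
  conservative, which is what keeps the family-wise error controlled on
  cohorts of tens of patients at the cost of a little power.
- **Wald test**: group means μ_t, μ_n of normalized counts; the reported
  and tested log fold change is log((μ_t + 0.5)/(μ_n + 0.5)) — the 0.5
  pseudocount keeps zero-mean groups finite and makes identical groups
  give exactly z = 0, p = 1. The standard error is the delta method on
  the shifted log scale with Var(μ̂_g) = (Σ_s μ_g/s_s + n_g·α·μ_g²)/n_g²;
  p-values are two-sided normal. Features with zero counts everywhere are
  flagged degenerate (p = 1, lfc = 0). p-values are floored at 1e-300
  before multiplication by the family size (Bonferroni; the family is the
  set of features tested at one level on one sample subset). Significance
  is `p_bonferroni ≤ cutoff`.
- **Pairing**: the test is unpaired two-group, matching the classic
  count-based tools this follows; patient pairing is respected only in
  data splitting (both tissues of a patient always fall on the same side
  of a split).

Overlap between gene sets (e.g. DEGs vs gene-mapped DEEs) uses the
upper-tail hypergeometric probability P(X ≥ overlap); the universe is
always passed explicitly by the caller, since no single default (all
annotated genes vs all tested genes) is right for every question.

## Selection and classification

- **Splits**: patients are permuted and halved, training taking ⌈n/2⌉
  (77 → 39 + 38). With stratification, patients are grouped by the joint
  value of gender/smoking/stage; each stratum is halved and the odd
  patient goes to the currently smaller side, so strata differ by ≤1
  between subsets and the overall imbalance never exceeds 1.
- **Discovery**: the NB test runs once per replicate training half; the
  three cutoffs are applied to the same results, and only features
  significant in *all* replicates survive. An empty intersection is a
  legitimate outcome (warned, not raised) — at stringent cutoffs a level
  can yield no shared features.
- **Ranking**: each candidate is scored by a *single-feature* random
  forest per replicate (trained on the training half, accuracy on the
  validation half), averaged over the five replicates. A feature constant
  in a training half contributes chance accuracy 0.5. No aggregation rule
  or tie-break is canonical here, so the package fixes one: descending
  mean accuracy, ties broken by smaller mean discovery p, then
  lexicographic id.
- **Feature sets**: top ⌈fraction × n⌉ of the ranking, so a non-empty
  ranking always yields at least one feature even at the top-1% cut; the
  three fractions are nested by construction.
- **Systems**: one random forest per fresh random assignment (100 fresh
  draws by default, not reusing the five discovery splits), all sharing
  the feature set. Forest hyperparameters — 500 trees, √p features per
  split, unlimited depth — are conventional defaults, recorded in the run
  manifest. Voting is strictly more than n/2 for "tumor", so 50 of 100 is
  "normal". Any sample with complete feature values can be scored
  (validation-only samples included); a missing value is an error, never
  imputed.
- **SPI**: s_i = n_it/n, r_i = s_i for tumors and 1 − s_i for normals,
  SPI = mean r_i. All randomness fans out from one master seed through
  named, deterministic seed streams (< 2³¹), so a manifest reproduces a
  run byte for byte.

## The synthetic cohort generator

The generator emulates the structure of a paired tumor/normal cohort
study: each patient contributes one tumor and one normal sample; genes
carry 1–5 isoforms built from a shared exon pool (first transcript takes
the whole pool, others drop random exon subsets), so flattening yields
both shared and transcript-private regions; metadata carries
gender/smoking/stage strata.

Expected transcript expression is baseline × patient effect × tissue
effect, all multiplicative on the log scale. Defaults (the study
conditions for all tests): 40 patients, 500 genes (≈1450 transcripts),
log-normal baselines (median 100 counts, log-sd 1), NB dispersion
α = 0.2, per-patient log-normal effect (sd 0.3) shared between a
patient's two samples — this is what makes the data "paired" — and
log-normal library sizes (sd 0.3 around 20 M reads) so size-factor
estimation is actually exercised.

Planted events, pairwise disjoint by gene:

- `gene_de`: every isoform × fold in tumor.
- `transcript_switch`: two isoforms of one gene get baselines (b, f·b)
  and tumor multipliers (f, 1/f). The gene total is conserved *exactly*
  in expectation (b + f·b on both sides) while each isoform shifts by a
  full factor f — the cleanest construction in which the realized
  per-isoform fold equals the requested fold. Requires ≥2 isoforms.
- `exon_de`: the transcripts containing one target region (the most
  transcript-specific region of the gene) shift by the fold. Note the
  gene total then shifts partially, so exon events are *attenuated*, not
  absent, at gene level; only switches are exactly conserved.

Counts are NB draws around the expectation scaled by library size.
Exonic-region counts are derived from member-transcript counts scaled by
the length fraction l_region/l_transcript and rounded, so region naïve
FPKM equals the sum of member-transcript FPKM in expectation, and the
quantify-layer aggregation recovers the generator's region expression.
Transcript FPKM follows the naïve formula exactly.

Truth sets are derived from expectations, not labels: any feature whose
expected tumor/normal ratio differs from 1 (beyond 1e-9 on the log scale)
is a true DEG/DET/DEE, with the realized ratio recorded. A switch gene is
therefore *not* a true DEG, while all its shifted isoforms and their
private regions are true DETs/DEEs.

Two seed streams separate cohort *structure* (annotation, baselines,
event placement; `spec.seed`) from the *patients* (effects, library
sizes, counts, strata; `samples_seed`). A held-out validation batch is
the same spec with a new `samples_seed`: same population, new patients.
`simulate_null_counts` is a fast path producing gene-level null count
matrices with the same distributional structure but no annotation, used
where calibration simulations need hundreds of independent null cohorts.

What the generator does **not** emulate: read-level sampling (no
fragments, no positional bias), sequence content, correlated co-expression
modules, batch effects, and uncertainty of isoform deconvolution
(transcript counts are observed directly, whereas real isoform estimates
are correlated within genes). Passing tests therefore demonstrate the
pipeline's statistical machinery under its own model assumptions, not
performance on real cohorts.

## Problem sizes used in the test suite

Calibration uses one 2000-feature, 20-patient null cohort for p-value
uniformity (KS distance < 0.05) and 200 fast null cohorts of the same
shape for the family-wise error rate at Bonferroni 0.05. Recovery uses
the default 40-patient/500-gene cohort with 20 planted 4-fold gene
events: the five-replicate intersection must recover ≥90% of them, and
the 100-model system built on the intersection must reach median
validation accuracy ≥0.95 and SPI ≥0.95 on a held-out batch. Level
separation uses 20 planted switches under the same conditions: ≥80% of
events detected at transcript and exon level, <5% at gene level. The
whole suite runs in a few minutes on one CPU.

## Known limitations

- Exon-level testing is expression of region counts, not relative exon
  usage; a globally shifted gene lights up all its regions.
- The NB Wald normal approximation is anti-conservative for very small
  groups (<5 per group) at low counts; the conservative dispersion
  shrinkage compensates only partially there.
- The prevalence filter assumes paired metadata; cohorts of only
  unpaired samples are not supported for discovery (they can still be
  scored by a trained system).
- Model persistence uses joblib and is not portable across scikit-learn
  major versions; the manifest (features, seeds, config) is the durable
  record.
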