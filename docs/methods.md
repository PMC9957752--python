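# Methods

## The estimand: cell-type transcriptome fractions

A bulk RNA-seq library of a solid tissue is a mixture of the transcriptomes
of its constituent cell types.  Within any one library each transcript *t*
is a fraction of the total transcriptome *T*.  For a gene expressed
exclusively by cell type *c*, the ratio of its fraction in the whole-tissue
library to its fraction in a pure cell-type library,

    (t_L / T_L) / (t_C / T_C) = f_c ,

equals the fraction of the tissue transcriptome contributed by type *c*.
This is an identity, not an approximation, whenever (i) the marker really
is exclusive to *c* and (ii) the reference profile represents the in-tissue
expression state of *c*.  Averaging the ratio over a set of exclusive
markers gives the per-type estimate, with the standard deviation of the
per-marker ratios reported as a dispersion diagnostic.  Because numerator
and denominator are both within-library fractions, all library-size terms
cancel: the estimator is invariant to any linear rescaling (total or median
normalization) of either library, which is why the preprocessing pipeline
uses only linear operations.

Note the estimand is the *transcriptome* fraction, not the cell-number
fraction — cell types differ widely in transcripts per cell, so a 96%
transcriptome share does not mean 96% of cells.

### Hepatocytes by subtraction

Hepatocyte references prepared by collagenase isolation are unreliable:
isolation strongly induces reactive genes and the preparations retain
non-parenchymal cells (NPC).  The pipeline therefore never estimates the
hepatocyte fraction from hepatocyte markers.  Instead the NPC fraction is
the sum of the per-type estimates for all non-hepatocyte types, and the
hepatocyte fraction is `1 − NPC`, clipped to [0, 1] with a warning if the
NPC estimates are jointly inconsistent.  A direct estimate remains possible
(any cell type can be estimated from its own markers) and is used in
synthetic tests where the "hepatocyte" reference is exact.

### Apportionment of shared genes

Given the per-type fractions, the share of a multi-cell-type gene's total
tissue expression contributed by type *c* is

    contribution_c(g) = f_c · fraction_c(g) / fraction_L(g) .

Contributions plus the unattributed residual sum to exactly 1 per gene by
construction.  The residual absorbs whatever the supplied reference
profiles do not explain; when no hepatocyte profile exists the
`assign_hepatocyte` policy credits it to hepatocytes, which is the correct
reading in a hepatocyte-dominated tissue.  Contributions summing above
1.05 mark the row inconsistent (surfaced as a warning, never silently
renormalized — the model imposes no sum-to-one constraint across types, so
inconsistency is diagnostic information).

## Preprocessing

Order: biotype filtering → isoform collapsing → reads/kb conversion →
linear renormalization.

- **Extraneous biotypes** removed by default: `rRNA, Mt_rRNA, Mt_tRNA,
  miRNA, snoRNA, snRNA` (ribosomal, mitochondrial and small RNAs dominate
  libraries without carrying cell-type signal).  The set is configurable;
  an excluded biotype absent from the annotation warns rather than errors.
- **Isoform collapsing** keeps, per gene, the isoform with the largest raw
  count in that library; ties break to the lexicographically smallest
  transcript id so the choice is deterministic across runs.
- **Molecule counts (reads/kb)**: read counts divided by transcript length
  in kb, removing the length bias that makes longer transcripts attract
  more reads per molecule.  Non-positive lengths are fatal, naming the gene.
- **Renormalization**: `total` divides by the library sum (values become
  transcriptome fractions and sum to 1); `median` divides by the median of
  the *nonzero* genes — the median of a zero-inflated vector is frequently
  0 and useless as a scale factor.  Zero-count genes are retained at
  fraction 0 so gene universes stay aligned across libraries.

## Marker discovery and surrogate libraries

Gene *g* is a marker for type *c* iff `fraction_c(g) ≥ min_own_fraction`
(default 1e-5, roughly 10 reads/kb in a typical library) and, for every
other type, `fraction_c'(g) ≤ max_other_relative · fraction_c(g)` (default
0.05, i.e. at least 20-fold specificity).  No published numeric rule
exists for "uniquely expressed"; these defaults are explicit, configurable
stand-ins.  For `max_other_relative < 1` marker sets are provably disjoint
across types.  Fewer than `min_markers` (default 5, to stabilize the
averaged ratio) survivors raises an error naming the type.

Cell types without tissue-derived references (fibroblasts, macrophage
subtypes) are assigned a **surrogate library**: candidates are ranked by
Pearson correlation with the whole-tissue profile and the best is adopted.
The correlation is computed on `log2(1e6·fraction + 1)` — a
molecules-per-million log scale — because linear-scale Pearson is dominated
by a handful of very highly expressed genes, while `log2(x+1)` applied to
raw fractions (all ≪ 1) would be numerically linear and compress nothing.
A `log_scale=False` option preserves the plain linear reading.
Zero-variance candidates have undefined correlation and rank last with a
warning.

## Signature derivation, scoring and trend

- **Differential engine**: Welch's t-test per gene on `log2(CPM+1)` with
  Benjamini–Hochberg q-values; the fold change is the difference of group
  means on the same scale.  This engine exists to make the pipeline closed
  and testable on synthetic counts; for real sequencing data a
  negative-binomial model (DESeq2-class) is the appropriate external choice
  and is deliberately not reimplemented here.
- **Signature**: genes with `log2fc ≥ 1` and `q ≤ 0.05` (the conventional
  thresholds), ordered by ascending q then descending fold change,
  optionally truncated to a top-k.
- **Scoring**: the per-sample score is the mean over signature genes of the
  per-gene z-score of `log2(x+1)` expression across samples ("zmean").
  This is a fully specified, ssGSEA-like module score; a within-sample
  percentile-rank variant ("rank") is available for sensitivity analysis.
  Scoring assumes a pre-normalized matrix: a guard warns when sample totals
  differ by more than 10×.  The zmean score depends only on signature rows,
  so adding genes to a matrix cannot change it.
- **Cross-species transfer** uses a user-supplied 2-column orthology table;
  case-insensitive symbol matching is the documented fallback.
- **Trend test**: Spearman's rho between score and ordinal stage, p-value
  by permuting stage labels.  When n! ≤ 50 000 every permutation is
  enumerated and the p-value is exact; otherwise 10 000 seeded permutations
  with the (1 + extreme)/(1 + n_perm) estimator.  With tied stage labels
  |rho| < 1 by construction; strictly ordered scores attain the minimal rho
  achievable for the stage layout.  Constant scores report rho 0, p 1.

## Staging classifier

One quarter of the cohort (stratified by class, largest-remainder
allocation, deterministic per seed) trains a univariate logistic regression
of advanced-vs-mild status on one gene's `log2(x+1)` expression, fitted by
IRLS/Newton to a log-likelihood tolerance of 1e-10 within 100 iterations.
Perfect separation is detected (perfect classification with the likelihood
at its supremum) and flagged rather than silently diverging.  The remaining
three quarters are evaluated by ROC: the curve sweeps every distinct score
threshold, ties earn half credit, and the trapezoidal area equals the
Mann–Whitney statistic (wins + ½·ties)/(n₊·n₋).  Because the univariate
model is monotone in its input, the model AUC equals the raw-expression
AUC up to orientation; both are reported to keep that equivalence visible.

## Overlap and concordance statistics

Gene-set overlap uses the one-sided (enrichment) Fisher exact test — the
hypergeometric tail P(X ≥ shared) — with the sample odds ratio and no
continuity correction.  The declared gene universe dominates the p-value;
it defaults to the genes detected in both datasets and must be supplied
explicitly.  Global concordance is Pearson's r on `log2(x+1)`-transformed
matched genes (linear available), p from the t-distribution of r.

## The synthetic-data generators

The generators define the conditions under which every guarantee is
measured:

- **Reference panels**: per-type base expression log-normal with meanlog 2,
  sdlog 1 on the reads/kb scale (the heavy right tail typical of RNA-seq);
  exclusive marker blocks are exactly zero in all other types; shared genes
  are expressed in every type with independent levels; transcript lengths
  uniform on [0.5, 10] kb so the reads/kb conversion is exercised
  nontrivially.
- **Mixtures** are formed on the fraction scale (tissue fraction of g =
  Σ f_c·fraction_c(g)), converted back to expected read counts via length,
  and either returned exactly (`noise="none"`, real-valued) or
  Poisson-resampled (`noise="poisson"`, integer counts).  Expected molecule
  depth defaults to 1e6; the liver-like demonstration uses 1e7 because deep
  whole-tissue libraries carry tens of millions of reads and the rarest
  types (0.1–0.3% of the transcriptome) otherwise leave ~1 read per marker.
- **Two-condition matrices**: log-normal baseline Poisson means
  (meanlog 3, sdlog 1, so typical counts are tens), planted genes
  multiplied by 2^±effect in the reference group; effect 0 is the null
  configuration and plants nothing (a negative effect is an error).
- **Staged cohorts**: signature genes lose `stage_effect` log2 units of
  mean expression per stage with Gaussian log-scale noise; one designated
  single gene ("Smo") follows the same decline; background genes have no
  trend.

What the generators do **not** emulate — and hence what passing tests do
not establish about real data: negative-binomial overdispersion, batch and
isolation artifacts in reference libraries, imperfect marker exclusivity,
cross-platform normalization differences, UMI/doublet effects, and
cross-species expression divergence.  On real data the dominant error
sources are marker-set quality and reference representativeness, neither of
which the synthetic conditions stress.

## Numerical choices

- Fraction estimates are clipped to [0, 1]; the raw value and a clipped
  flag are preserved.  Per-marker ratios of 0 (marker silent in tissue) are
  valid — the cell type may be absent; a marker silent in its *own* type is
  an error.
- Averaging defaults to the unweighted mean (median available); whether a
  weighted average would be preferable is an open modeling question, and
  the unweighted mean is the simplest defensible reading.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); generators are bit-reproducible per seed
  and record the seed in their outputs.
- Dispersion is the sample standard deviation (ddof 1), 0 for a single
  marker.

## Problem sizes in the test suite

The shipped tests and the results script run on panels of 1 000–3 000 genes,
20 markers per type, 25–50 Monte-Carlo seeds and cohorts of ≤ 240 samples —
sizes at which every closed-form identity is exact and the stochastic
checks have comfortable margins, while the whole suite completes in well
under a minute of compute.

## Applying the pipeline to real reference libraries

The desk-scale guarantees above are measured on synthetic data.  Applying
the pipeline to deposited sequencing libraries (whole liver plus
cholangiocyte, sinusoidal endothelium, stellate, Kupffer, fibroblast,
monocyte/macrophage, neutrophil, B- and T-cell references) requires
multi-gigabyte downloads, alignment and gene-level quantification, which
are out of scope here.  The in-repo path picks up immediately downstream of
quantification: read the counts table and annotation
(`read_expression_table`), filter/collapse/convert each library
(`filter_extraneous`, `collapse_isoforms`, `to_molecule_counts`,
`renormalize`, `average_profiles` for replicate cell-type libraries),
select surrogate libraries for missing cell types
(`select_surrogate_library` against the whole-tissue profile), derive
marker sets (`find_cell_specific_genes`), estimate fractions and the
hepatocyte remainder (`estimate_cell_fraction`,
`estimate_npc_and_hepatocyte`), and apportion genes of interest
(`apportion_gene`).  Cohort-side analyses (`de_rank` → `derive_signature`
→ `score_samples` → `stage_trend`, and `classify_gene`) consume any
genes × samples table with stage labels.  Known limitation: one reference
library used in the original compilation (hepatic stellate cells) has no
listed public accession, so a fully independent reconstruction of that
panel is not possible from public identifiers alone.
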