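# hepatodecon

Marker-ratio deconvolution of bulk liver RNA-seq into **cell-type
transcriptome fractions**, with companion tools for gene-signature scoring
across staged cohorts and single-gene logistic/ROC disease staging.

## The problem

Bulk RNA-seq of a solid tissue averages over its cell types.  For liver —
where hepatocytes dominate but disease biology involves cholangiocytes,
stellate cells, sinusoidal endothelium and immune cells — two recurring
questions are: *what fraction of the tissue transcriptome does each cell
type contribute*, and *which cell type does a given gene's bulk signal
actually come from*?  The package answers both with a closed-form marker
estimator.  Within one library every transcript *t* is a fraction of the
total transcriptome *T*; for a gene exclusive to cell type *c*,

```
(t_L / T_L) / (t_C / T_C) = f_c
```

— the ratio of the gene's fraction in whole tissue to its fraction in the
pure cell-type library *is* that cell type's transcriptome fraction.
Averaging over a marker set gives the estimate; non-parenchymal (NPC)
fractions are summed and hepatocytes obtained as `1 − NPC` (isolated
hepatocyte references are distorted by isolation artifacts); and the
per-type fractions then apportion any shared gene's bulk expression as
`f_c · fraction_c(g) / fraction_L(g)`.

Downstream, the package derives an "active-state" gene signature from a
two-condition contrast (Welch t on log2 CPM, BH correction, |log2FC| ≥ 1 &
q < 0.05), scores independent cohorts by mean z-score, tests the score's
decline across ordinal fibrosis stages (permutation Spearman test, exact
for small cohorts), and stages disease from a single gene with a
one-quarter/three-quarter train/test split, an IRLS logistic fit and a
tie-aware trapezoidal ROC.  Fisher-exact overlap and Pearson concordance
statistics compare gene sets and whole transcriptomes across datasets.  A
synthetic-data module generates every input with known ground truth, so the
whole pipeline is testable end to end without downloads.

Intended users: computational biologists analyzing bulk liver (or other
dominant-cell-type tissue) RNA-seq who have pure or surrogate cell-type
reference libraries and want transparent, closed-form deconvolution rather
than regression-based signature matrices.

## Worked example

`examples/01_deconvolve_mixture.py` builds a six-cell-type reference panel,
simulates a deep (10⁷ molecules) Poisson-noised whole-liver library in
which hepatocytes contribute 96% of the transcriptome, and deconvolves it
with hepatocytes held out:

```
cell type        true %   estimated %
cholangiocyte      0.30     0.310   (sd over 20 markers: 9.25e-04)
stellate           1.00     1.043   (sd over 20 markers: 1.44e-03)
endothelium        1.60     1.743   (sd over 20 markers: 3.11e-03)
fibroblast         0.10     0.092   (sd over 20 markers: 6.16e-04)
kupffer            1.00     1.015   (sd over 20 markers: 9.34e-04)
NPC total          4.00     4.203
hepatocyte        96.00    95.797   (by subtraction)
```

Each estimated percentage is the average marker ratio for that cell type;
the hepatocyte row is one minus the NPC sum.  Without count noise the
recovery is exact to machine precision — a property the test suite asserts
at ≤ 1e-10.  The other examples cover shared-gene apportionment
(`02`), signature derivation/scoring/trend (`03` — scores decline from
+1.33 in healthy samples to −1.31 at the most advanced stage, Spearman
rho −0.97, permutation p 1e-4), single-gene staging (`04` — test-set AUC
0.94 on a cohort with a planted one-log2-unit decline), and
overlap/concordance statistics (`05`).

A thin CLI wraps the same functions
(`hepatodecon simulate|normalize|markers|deconvolve|signature|classify|overlap`);
every run writes a manifest with config, seeds and input hashes.

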