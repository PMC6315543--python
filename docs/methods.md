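# Methods

## The analysis

`pcafe` implements unsupervised feature extraction for case/control
expression studies, built around one idea: decompose the probes × samples
matrix and let the *sample-side* structure tell you which direction of
variation separates the classes, then rank probes by how strongly they load
on that direction.

Write the per-probe standardized matrix as a thin SVD, X = U D Vᵀ. We call
the columns of U·D the **PC scores** (attributed to probes) and the columns
of V the **PC loadings** (attributed to samples). The procedure is:

1. **Standardize** every probe row to mean 0, variance 1 (sample variance,
   ddof 1). Constant rows cannot be standardized and are dropped with a
   warning.
2. **Decompose** and scan the leading components (default 10, capped by
   rank). For each component, a two-sided Welch t-test compares its sample
   loadings between the classes; the component with the smallest p-value is
   the class-associated one. Labels enter the analysis *only* here — the
   per-probe ranking below never sees them, which is what makes the
   feature extraction "unsupervised". A user may also force a component
   index to reproduce a previous analysis exactly.
3. **Attribute p-values to probes.** On the chosen component(s), each
   probe's score is standardized across probes, z = u_i / sd(u), and
   P_i = P(χ²_df ≥ Σ z²) with df = number of components used (default one
   component, df = 1). Under the null that a probe carries no structure on
   that component, z is approximately standard normal and P_i is uniform;
   probes with outlying scores get small P.
4. **Select probes** whose Benjamini–Hochberg adjusted P is ≤ α
   (default 0.01).
5. **Second pass:** re-standardize and re-decompose the selected probes
   only, re-run the association scan on the reduced matrix, and fit **LDA**
   (empirical class priors; scikit-learn's implementation) on the winning
   loading. The confusion table is resubstitution by default — predictions
   on the same samples the discriminant was fitted on, which is how small-n
   microarray analyses of this kind are usually reported — with a
   stratified cross-validation mode available (`cv_folds`).
6. **Metrics.** Sensitivity, precision, F1 and accuracy for the case class
   (denominator-zero cases reported as NaN, never 0); ROC-AUC by the
   Mann–Whitney identity on the loading itself, signed so the case class
   has the larger mean (in one dimension the loading and the LDA posterior
   are monotone equivalents, so the AUC is the same; the loading is the
   more primitive quantity); Fisher's exact test on the confusion table
   with the **conditional-MLE odds ratio** (the maximizer of the noncentral
   hypergeometric likelihood with both margins fixed, via
   `scipy.stats.contingency.odds_ratio`). The CMLE is shrunk relative to
   the cross-product ratio ad/bc and is what R's `fisher.test` reports;
   e.g. the 57-sample table [[24,8],[3,22]] has cross-product ratio 22.0
   but CMLE 20.5.
7. **Enrichment.** Selected probes are mapped to gene symbols
   (many-to-one, deduplicated, unmapped probes counted) and tested for
   over-representation in GMT libraries: per term, a one-sided
   hypergeometric tail P(X ≥ k) with k the overlap, K the set size, n the
   query size and N the background; BH adjustment within each library.
   k = 0 is reported with p = 1. The coverage summary counts query genes in
   the union of significant sets — with miRNA target-set libraries this is
   "how many selected genes are targeted by at least one significant
   miRNA".

### Background universe for enrichment

The hypergeometric background defaults to N = 20,000 (approximately the
protein-coding genome) for bare gene lists. When a probe annotation is
supplied, the pipeline instead uses the annotation's symbol universe as an
explicit background: for array data the genes interrogated by the platform
are the coherent sampling frame, and using a larger N than the true
universe systematically inflates significance. Query symbols outside the
background are dropped with a warning.

### Dataset integration

Multiple series measured on a shared platform are merged by intersecting
probe sets (first matrix's order) and concatenating samples. No
cross-dataset renormalization or batch correction is applied; inputs are
assumed to be comparably normalized profiles. Whether the matrix should be
log-transformed upstream is data-dependent, so the model exposes a
`log2_transform` flag rather than guessing.

## The synthetic-data generator

`pcafe.synthetic` draws studies of the form X = Σ_k d_k u_k v_kᵀ + ε with
i.i.d. Gaussian noise ε and orthonormal factor matrices, emulating a merged
substantia-nigra case/control microarray design: 5000 probes, 35 controls +
25 cases, six latent factors, 255 spiked probes, a many-to-one probe→gene
map with ~0.95 symbols per probe (so 255 spiked probes collapse to roughly
244 symbols; spiking is done gene-by-gene, the way real differential
expression moves all probes of a gene together).

The class signal is deliberately planted on a **non-leading** factor (the
4th by default): in real merged series the top components are dominated by
non-biological variance (tissue composition, batch, degradation), and the
disease contrast appears further down the spectrum. The class shift
(`effect_size`, default 2.0 within-class SDs) is added to the signal
factor's sample values before the factors are orthonormalized, with the
signal column processed first so the planted direction survives intact.

Factor strengths: the five nuisance factors follow a geometric ladder
(`factor_strength` 400, `factor_decay` 0.75), while the sparse signal
factor has its own strength (`signal_strength` 900). The two cannot share
one ladder because per-probe standardization rescales every row by its own
SD: a spiked probe, whose variance is dominated by the signal factor, is
shrunk much more than a null probe, so the *effective* strength of the
signal factor after standardization is strongly compressed (it is bounded
by √(60 · n_spiked) regardless of the raw strength). The defaults are
calibrated so that the post-standardization component order is
d₁ > d₂ > d₃ > signal > d₅ > d₆ > noise — the signal lands on PC4 — and so
that spiked probes are signal-dominated enough for their standardized
scores to clear the BH threshold with margin. With weaker spikes the spiked
z-band straddles the step-up line and the selection becomes all-or-nothing
across seeds. Spiked probes draw score magnitudes from |N(8, 1)| with
random signs; null probes draw N(0, 0.05).

With these defaults (and α = 0.01), across 80 seeds the association scan
picked component 4 in every run, the median Jaccard overlap between
selected and spiked probes was 1.0 (minimum 0.93), and with effect_size = 0
the mean selected fraction was 0.006 ≤ α.

### What the generator does and does not emulate

It reproduces the *statistical geometry* the method assumes — low-rank
structure, a buried class factor, heavy-tailed probe scores on it, probe
redundancy per gene, gene sets enriched for the affected genes. It does not
emulate probe-level Affymetrix data, MAS5 normalization, batch effects
between merged series, correlated noise, non-Gaussian intensity
distributions, or realistic gene-set topology. Passing the recovery tests
therefore shows the pipeline is a correct implementation of the method
under its own assumptions; it does not show the method succeeds on any
particular real dataset, and the effect size and noise level were not fit
to any real study.

Dataset-scale figures from real analyses of this kind (a specific count of
selected probes or gene symbols, a specific AUC, specific enrichment
p-values against curated miRNA-target or disease-perturbation libraries)
depend on the original raw data and on library snapshots and background
sizes that are not recoverable; the package treats such numbers as
demonstrations, not as test targets. The synthetic recovery and
null-calibration experiments are the testable surface. (For the published
57-sample confusion table the implied metric suite itself *is* exactly
recomputable, and is: sensitivity 0.88, precision 0.73, F1 0.80, accuracy
0.81, CMLE odds ratio 20.5, two-sided Fisher p 2.6 × 10⁻⁶ — the exact
p-value, confirmed against R's `fisher.test`, differs slightly from the
commonly rounded 2.5 × 10⁻⁶.)

## Numerical choices

* SVD sign ambiguity: each loading column's largest-|entry| is made
  positive, scores flipped accordingly, so outputs are bit-reproducible.
* Welch (unequal-variance) t-test for the association scan; if both
  classes have zero variance on a component the p is 0 or 1 by mean
  (in)equality.
* χ² standardization uses the population SD (ddof 0) of the score column
  and no centering, per the z = u/sd convention; score columns of a
  standardized matrix have near-zero mean anyway.
* BH adjustment via `statsmodels.stats.multitest.multipletests(fdr_bh)`,
  validated in tests against a hand-written step-up oracle.
* Two-sided Fisher p uses the minimum-likelihood rule (sum of table
  probabilities ≤ observed, with the customary 1 + 1e-7 relative slack),
  matching R; validated against exhaustive enumeration.
* Degenerate inputs: constant probe rows are dropped before PCA (a
  constant row has no standardized representation); an all-constant
  matrix, a one-class label vector, a constant loading, and a
  zero-variance score column raise typed errors rather than propagating
  NaNs.
* Probe selection is a pure threshold on adjusted p — no tie-breaking is
  ever needed.

## Experiment sizes

The validation experiments (`pcafe.experiments`) default to 20 seeds for
recovery and null selection and 200 replicates for the enrichment null —
enough for the medians and means being asserted, and each run is a 5000×60
SVD, so the full suite stays fast.

## Known limitations

* The association scan formalizes "which loading separates the classes" as
  a per-component Welch t-test; other formalizations (rank tests,
  correlation with the indicator) are defensible and can pick different
  components when separation is weak. The `forced_component` escape hatch
  exists for exact reproduction of a prior analysis.
* With very weak signals BH selection on the χ² p-values is
  all-or-nothing across seeds (the spiked z-band crosses the step-up line
  as a block); the pipeline warns and completes with an empty selection
  rather than failing.
* The CMLE odds ratio is reported as 0 or +∞ for tables with a zero cell,
  per the conditional model's boundary behavior.
* Enrichment assumes symbols are comparable across query, annotation and
  library (all are uppercased at ingest); no ortholog mapping or alias
  resolution is attempted.
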