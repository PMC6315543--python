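# pcafe — PCA-based unsupervised feature extraction for expression biomarkers

`pcafe` finds class-discriminating probes in bulk case/control expression
matrices (microarray-style, probes × samples) the unsupervised way: instead
of testing each probe against the labels, it decomposes the whole matrix,
identifies the principal component whose **sample loadings** separate the
classes, and selects the probes whose **PC scores** are outliers on that
component. The selected genes are then validated by linear discriminant
analysis on the loading and by gene-set over-representation — including
miRNA target-set libraries, where the coverage summary answers "how many of
the selected genes are targeted by at least one significantly enriched
miRNA". It is aimed at transcriptomics analysts working with small-n
case/control designs (e.g. post-mortem brain cohorts) where supervised
per-gene testing overfits.

## The method

For the per-probe standardized matrix X (probes × samples), take the thin
SVD X = U D Vᵀ; columns of U·D are PC scores u (one per probe), columns of
V are PC loadings v (one per sample).

1. Scan the leading components with a two-sided Welch t-test of
   v<sub>ℓ</sub> between classes; the minimizing component ℓ\* is the
   class-associated one. Labels are used **only** for this choice.
2. For each probe i, standardize its score, z<sub>i</sub> =
   u<sub>ℓ\*i</sub> / sd(u<sub>ℓ\*</sub>), and attribute
   P<sub>i</sub> = P(χ²<sub>df</sub> ≥ Σ<sub>ℓ</sub> z²<sub>ℓi</sub>),
   df = number of components used (default 1).
3. Select probes with Benjamini–Hochberg adjusted P ≤ α (default 0.01).
4. Re-decompose the selected probes, find the class-associated loading of
   the reduced matrix, fit LDA on it (resubstitution by default) and report
   sensitivity, precision, F1, accuracy, Mann–Whitney ROC-AUC, Fisher's
   exact p and the conditional-MLE odds ratio.
5. Map selected probes to gene symbols and test them against GMT libraries
   with one-sided hypergeometric tests, BH-adjusted per library.

See `docs/methods.md` for assumptions, numerical conventions, the synthetic
data model and known limitations.

## Worked example

```python
from pcafe import PCAFeatureExtraction, SimulationConfig, generate_dataset
from pcafe.synthetic import generate_probe_annotation

config = SimulationConfig(seed=1)           # 5000 probes, 35 control + 25 case,
matrix, truth = generate_dataset(config)    # class signal planted on factor 4
annotation = generate_probe_annotation(config)

results = PCAFeatureExtraction(matrix, annotation).fit(alpha=0.01)
print(results.summary())
```

prints

```
PCA-based unsupervised feature extraction
=========================================================
samples: 60  (control: 35, case: 25)
probes: 5000

Pass 1: component-class association (Welch t, two-sided)
  PC1   p = 4.686e-01
  PC2   p = 2.329e-01
  PC3   p = 4.687e-02
  PC4   p = 9.295e-12 <- used
  PC5   p = 8.020e-01
  ...

selected probes (BH-adjusted p <= 0.01): 255
distinct gene symbols: 248

Pass 2: PCA on selected probes, LDA on PC1 loading
confusion (rows true, cols predicted; control, case):
    32    3
     3   22
sensitivity = 0.88   precision = 0.88
F1          = 0.88   accuracy  = 0.90
AUC         = 0.96
odds ratio (conditional MLE) = 67.5
Fisher exact p (two-sided)   = 2.93e-10
```

Reading it: the top three components (the strong non-biological variance
sources in the simulation) show no class association, while **PC4** — where
the generator planted the signal — separates the classes at p ≈ 10⁻¹¹.
Thresholding the BH-adjusted χ² probe p-values at 0.01 selects 255 probes
(here exactly the spiked set), which collapse to 248 gene symbols through
the many-to-one probe→gene map. On the re-decomposed 255-probe matrix the
class signal is the leading component, and LDA on that loading classifies
54 of 60 samples correctly (accuracy 0.90, AUC 0.96); the confusion table's
Fisher test (odds ratio 67.5, p ≈ 3 × 10⁻¹⁰) confirms the association is
far beyond chance.

The ground truth lets you score the run directly:

```python
jaccard = len(set(results.selected_probes) & truth.spiked_probe_ids) \
        / len(set(results.selected_probes) | truth.spiked_probe_ids)   # 1.0

from pcafe.synthetic import generate_genesets
library = generate_genesets(truth, annotation, n_sets=50,
                            enriched_fraction=0.2, seed=1)
records = results.enrich(library, background=annotation.all_symbols)
significant, covered, n = results.coverage(records, alpha=0.05)
```

## Command line

```bash
pcafe simulate -o data/ --seed 1                 # synthetic study + ground truth
pcafe run -c config.yaml                         # full pipeline from YAML config
pcafe enrich -q genes.txt -g library.gmt         # standalone over-representation
pcafe report -d out/                             # summarize a finished bundle
```

`pcafe run` consumes either file inputs (`expression`, `labels`,
`annotation`, `libraries`) or a `simulation` block, and writes a fixed-name
bundle (selection/association TSVs, classification JSON, enrichment TSVs,
a JSON manifest with per-stage counts, and `report.txt`).

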