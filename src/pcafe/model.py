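"""Model/Results interface for PCA-based unsupervised feature extraction.

:class:`PCAFeatureExtraction` is constructed from an expression matrix with
class labels; :meth:`~PCAFeatureExtraction.fit` runs the two-pass analysis

1. standardize probes, decompose, find the class-associated component,
   attribute chi-squared p-values to probes, BH-select probes;
2. re-decompose the selected probes, find the class-associated component
   of the reduced matrix, fit LDA on its sample loading and compute the
   confusion-table metric suite (sensitivity, precision, F1, accuracy,
   ROC-AUC, Fisher exact p, conditional-MLE odds ratio);

and returns a :class:`PCAFEResults` carrying every intermediate object,
with ``summary()``, enrichment and plotting attached.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from . import pca
from .classify import ClassificationReport, evaluate_classification
from .containers import ExpressionMatrix, GeneSetLibrary, ProbeAnnotation
from .enrich import (
    DEFAULT_BACKGROUND_N,
    EnrichmentRecord,
    enrich_genes,
    summarize_mirna_coverage,
)

__all__ = ["PCAFeatureExtraction", "PCAFEResults"]


class PCAFeatureExtraction:
    """PCA-based unsupervised feature extraction on a labelled matrix.

    Parameters
    ----------
    matrix
        probes x samples :class:`ExpressionMatrix` with class labels
        attached ("control" / "case").
    annotation
        Optional probe -> gene-symbol map; enables the gene-level outputs.
    log2_transform
        Apply ``log2(x + 1)`` before analysis, for matrices delivered on a
        linear intensity scale.

    Examples
    --------
    >>> from pcafe.synthetic import SimulationConfig, generate_dataset
    >>> matrix, truth = generate_dataset(SimulationConfig(seed=1))
    >>> results = PCAFeatureExtraction(matrix).fit()
    >>> results.association.selected_component
    4
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        annotation: ProbeAnnotation | None = None,
        log2_transform: bool = False,
    ) -> None:
        if matrix.labels is None:
            raise ValueError("matrix must carry class labels")
        if log2_transform:
            import numpy as np

            values = matrix.values
            if (values.to_numpy() < 0).any():
                raise ValueError("log2 transform requires non-negative values")
            matrix = ExpressionMatrix(np.log2(values + 1.0), matrix.labels)
        self.matrix = matrix
        self.annotation = annotation

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        labels: pd.Series,
        annotation: ProbeAnnotation | None = None,
        **kwargs,
    ) -> "PCAFeatureExtraction":
        """Build from a probes x samples DataFrame and a label Series."""
        return cls(ExpressionMatrix(values, labels), annotation, **kwargs)

    @classmethod
    def from_files(
        cls,
        expression_path,
        labels_path,
        annotation_path=None,
        **kwargs,
    ) -> "PCAFeatureExtraction":
        """Build from tab-delimited expression, label and annotation files."""
        from . import io as _io

        matrix = _io.read_expression_table(expression_path, labels_path)
        annotation = (
            _io.read_probe_annotation(annotation_path) if annotation_path else None
        )
        return cls(matrix, annotation, **kwargs)

    def fit(
        self,
        alpha: float = 0.01,
        forced_component: int | None = None,
        n_components_scan: int = 10,
        lda_priors: str = "empirical",
        cv_folds: int | None = None,
    ) -> "PCAFEResults":
        """Run both passes and return a results object.

        Parameters
        ----------
        alpha
            BH-adjusted p threshold for probe selection.
        forced_component
            Skip the first-pass association scan and use this 1-based
            component for probe attribution (the scan is still computed
            for audit).
        n_components_scan
            How many leading components the association scan examines
            (capped by the matrix rank).
        lda_priors
            "empirical" (class proportions) or "uniform".
        cv_folds
            If set, the confusion table uses stratified cross-validated
            predictions instead of resubstitution.
        """
        matrix = self.matrix
        labels = matrix.labels
        std = pca.standardize_probes(matrix)
        n_scan = min(n_components_scan, std.n_probes, std.n_samples)
        decomposition = pca.decompose(std, n_components=n_scan)
        association = pca.score_pc_class_association(decomposition, labels)
        component = (
            forced_component if forced_component is not None
            else association.selected_component
        )
        if not 1 <= component <= decomposition.n_components:
            raise ValueError(f"forced component {component} out of range")
        raw_p = pca.attribute_probe_pvalues(decomposition, [component])
        selection = pca.select_probes(raw_p, alpha, components_used=[component])

        symbols: list[str] | None = None
        if self.annotation is not None:
            symbols = pca.map_probes_to_genes(selection, self.annotation)

        second = None
        association2 = None
        classification = None
        if selection.n_selected >= 2:
            sub = pca.standardize_probes(matrix.subset_probes(selection.selected_probes))
            n_scan2 = min(n_components_scan, sub.n_probes, sub.n_samples)
            second = pca.decompose(sub, n_components=n_scan2)
            association2 = pca.score_pc_class_association(second, labels)
            classification = evaluate_classification(
                second.loading(association2.selected_component),
                labels,
                priors=lda_priors,
                cv_folds=cv_folds,
            )
        else:
            warnings.warn(
                f"only {selection.n_selected} probe(s) selected at "
                f"alpha={alpha}; skipping the classification pass",
                stacklevel=2,
            )
        return PCAFEResults(
            model=self,
            decomposition=decomposition,
            association=association,
            component_used=component,
            selection=selection,
            gene_symbols=symbols,
            second_decomposition=second,
            second_association=association2,
            classification=classification,
        )


@dataclass
class PCAFEResults:
    """Everything the two-pass analysis produced."""

    model: PCAFeatureExtraction
    decomposition: pca.PCADecomposition
    association: pca.PCAssociation
    component_used: int
    selection: pca.ProbeSelection
    gene_symbols: list[str] | None
    second_decomposition: pca.PCADecomposition | None
    second_association: pca.PCAssociation | None
    classification: ClassificationReport | None

    # -- convenience ---------------------------------------------------
    @property
    def selected_probes(self) -> list[str]:
        return self.selection.selected_probes

    @property
    def n_selected(self) -> int:
        return self.selection.n_selected

    def enrich(
        self,
        library: GeneSetLibrary,
        background_N: int = DEFAULT_BACKGROUND_N,
        background: set[str] | None = None,
    ) -> list[EnrichmentRecord]:
        """Over-representation of the selected gene symbols in ``library``."""
        if not self.gene_symbols:
            raise ValueError(
                "no gene symbols available (no annotation, or empty selection)"
            )
        return enrich_genes(self.gene_symbols, library, background_N, background)

    def coverage(
        self, records: list[EnrichmentRecord], alpha: float = 0.05
    ) -> tuple[list[EnrichmentRecord], set[str], int]:
        """Query coverage by the significant sets of an enrichment run."""
        return summarize_mirna_coverage(self.gene_symbols or [], records, alpha)

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        """Human-readable account of the fit."""
        m = self.model.matrix
        lines = [
            "PCA-based unsupervised feature extraction",
            "=" * 57,
            f"samples: {m.n_samples}  "
            f"(control: {int((m.labels == 'control').sum())}, "
            f"case: {int((m.labels == 'case').sum())})",
            f"probes: {m.n_probes}",
            "",
            "Pass 1: component-class association (Welch t, two-sided)",
        ]
        for comp, p in self.association.p_values.items():
            mark = " <- used" if comp == self.component_used else ""
            lines.append(f"  PC{comp:<3d} p = {p:.3e}{mark}")
        lines += [
            "",
            f"selected probes (BH-adjusted p <= {self.selection.alpha}): "
            f"{self.n_selected}",
        ]
        if self.gene_symbols is not None:
            lines.append(f"distinct gene symbols: {len(self.gene_symbols)}")
        if self.classification is not None and self.second_association is not None:
            c = self.classification
            lines += [
                "",
                "Pass 2: PCA on selected probes, LDA on "
                f"PC{self.second_association.selected_component} loading",
                "confusion (rows true, cols predicted; control, case):",
                f"  {c.confusion[0, 0]:4d} {c.confusion[0, 1]:4d}",
                f"  {c.confusion[1, 0]:4d} {c.confusion[1, 1]:4d}",
                f"sensitivity = {c.sensitivity:.2f}   precision = {c.precision:.2f}",
                f"F1          = {c.f1:.2f}   accuracy  = {c.accuracy:.2f}",
                f"AUC         = {c.auc:.2f}",
                f"odds ratio (conditional MLE) = {c.odds_ratio:.1f}",
                f"Fisher exact p (two-sided)   = {c.fisher_p:.2e}",
            ]
        else:
            lines += ["", "classification pass skipped (selection too small)"]
        return "\n".join(lines)

    # -- plots ----------------------------------------------------------
    def plot_roc(self, ax=None):
        """ROC curve of the classification loading (case = positive)."""
        if self.classification is None or self.second_association is None:
            raise ValueError("no classification pass to plot")
        import matplotlib.pyplot as plt
        from sklearn.metrics import roc_curve

        labels = self.model.matrix.labels
        loading = self.second_decomposition.loading(
            self.second_association.selected_component
        )
        y = (labels.reindex(loading.index) == "case").to_numpy()
        s = loading.to_numpy()
        if s[y].mean() < s[~y].mean():
            s = -s
        fpr, tpr, _ = roc_curve(y, s)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(fpr, tpr, label=f"AUC = {self.classification.auc:.2f}")
        ax.plot([0, 1], [0, 1], ls="--", color="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax

    def plot_loading(self, ax=None):
        """Strip plot of the classification loading by class."""
        if self.second_association is None:
            raise ValueError("no classification pass to plot")
        import matplotlib.pyplot as plt
        import numpy as np

        loading = self.second_decomposition.loading(
            self.second_association.selected_component
        )
        labels = self.model.matrix.labels.reindex(loading.index)
        if ax is None:
            _, ax = plt.subplots()
        rng = np.random.default_rng(0)
        for i, cls in enumerate(["control", "case"]):
            vals = loading[labels == cls]
            x = i + rng.uniform(-0.1, 0.1, size=len(vals))
            ax.scatter(x, vals, alpha=0.7, label=cls)
        ax.set_xticks([0, 1], ["control", "case"])
        comp = self.second_association.selected_component
        ax.set_ylabel(f"PC{comp} loading (selected probes)")
        ax.legend()
        return ax
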