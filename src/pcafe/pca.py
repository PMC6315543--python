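"""PCA-based unsupervised feature extraction.

The method decomposes a per-probe standardized expression matrix X
(probes x samples) by thin SVD, X = U D V'. In this convention the columns
of U (scaled by D) are *PC scores* attributed to probes, and the columns of
V are *PC loadings* attributed to samples. The component whose loadings
best separate the two sample classes is identified with a per-component
Welch t-test; probes are then ranked on that component by standardizing
their scores to z-values and converting the squared z to an upper-tail
chi-squared p-value (df = number of components used). Benjamini-Hochberg
adjustment and a threshold on the adjusted p give the selected probe set.

The selection is "unsupervised" in the sense that class labels enter only
in choosing the component, never in scoring individual probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, ProbeAnnotation

__all__ = [
    "PCADecomposition",
    "PCAssociation",
    "ProbeSelection",
    "standardize_probes",
    "decompose",
    "score_pc_class_association",
    "attribute_probe_pvalues",
    "adjust_bh",
    "select_probes",
    "map_probes_to_genes",
]


class DegenerateInputError(ValueError):
    """Raised when an input is too degenerate for the operation (e.g. all
    probes constant, zero-variance score column, one-class labels)."""


@dataclass
class PCADecomposition:
    """Thin SVD of a standardized expression matrix.

    Attributes
    ----------
    scores
        probes x components DataFrame ``U @ diag(d)``: PC score of probe i
        on component l.
    loadings
        samples x components DataFrame ``V``: PC loading of sample j on
        component l. Columns are orthonormal.
    singular_values
        Descending singular values for the retained components.
    variance_share
        Fraction of total variance carried by each retained component
        (denominator includes all components, so the shares sum to <= 1).
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    singular_values: np.ndarray
    variance_share: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def loading(self, component: int) -> pd.Series:
        """Sample loadings of a 1-based component index."""
        return self.loadings.iloc[:, component - 1]


@dataclass
class PCAssociation:
    """Per-component class-association p-values and the winning component."""

    p_values: pd.Series  # index: 1-based component, value: two-sided Welch p
    selected_component: int  # 1-based argmin

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"component": self.p_values.index, "p": self.p_values.values})
        df["selected"] = df["component"] == self.selected_component
        return df


@dataclass
class ProbeSelection:
    """Outcome of the chi-squared probe-selection step."""

    raw_p: pd.Series
    adjusted_p: pd.Series
    alpha: float
    components_used: list[int] = field(default_factory=list)

    @property
    def selected_probes(self) -> list[str]:
        mask = self.adjusted_p <= self.alpha
        return list(self.raw_p.index[mask])

    @property
    def n_selected(self) -> int:
        return int((self.adjusted_p <= self.alpha).sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.raw_p.index,
                "raw_p": self.raw_p.values,
                "adjusted_p": self.adjusted_p.values,
                "selected": (self.adjusted_p <= self.alpha).values,
            }
        )


def standardize_probes(matrix: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Center and scale each probe row to mean 0, variance 1.

    Constant rows cannot be standardized; they are dropped with a warning.
    Raises :class:`DegenerateInputError` if every row is constant or there
    are fewer than two samples.
    """
    if matrix.n_samples < 2:
        raise DegenerateInputError("standardization needs >= 2 samples")
    X = matrix.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise DegenerateInputError("matrix contains missing values")
    sd = X.std(axis=1, ddof=ddof)
    keep = sd > 0
    if not keep.any():
        raise DegenerateInputError("all probe rows are constant")
    if not keep.all():
        n_dropped = int((~keep).sum())
        warnings.warn(
            f"dropped {n_dropped} constant probe row(s) before PCA", stacklevel=2
        )
    X = X[keep]
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[keep, None]
    values = pd.DataFrame(Z, index=matrix.probe_ids[keep], columns=matrix.sample_ids)
    return ExpressionMatrix(values, matrix.labels)


def decompose(matrix: ExpressionMatrix, n_components: int | None = None) -> PCADecomposition:
    """Thin SVD with scores attributed to probes and loadings to samples.

    Sign ambiguity is resolved per component: the loading entry with the
    largest absolute value is made positive and the score column flipped
    accordingly, so repeated runs give identical output.
    """
    X = matrix.values.to_numpy(dtype=float)
    max_rank = min(X.shape)
    if n_components is None:
        n_components = max_rank
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"n_components must be in [1, {max_rank}], got {n_components}"
        )
    U, d, Vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(d**2))
    U = U[:, :n_components]
    dk = d[:n_components]
    V = Vt[:n_components].T
    # deterministic sign convention
    for k in range(n_components):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]
    comp_index = pd.RangeIndex(1, n_components + 1, name="component")
    scores = pd.DataFrame(U * dk, index=matrix.probe_ids, columns=comp_index)
    loadings = pd.DataFrame(V, index=matrix.sample_ids, columns=comp_index)
    share = dk**2 / total if total > 0 else np.zeros_like(dk)
    return PCADecomposition(scores, loadings, dk.copy(), share)


def score_pc_class_association(
    dec: PCADecomposition,
    labels: pd.Series,
    n_components: int | None = None,
) -> PCAssociation:
    """Find the component whose sample loadings separate the two classes.

    A two-sided Welch t-test compares each loading column between classes;
    the component with the smallest p-value wins. The full p-value table is
    kept for audit.
    """
    labels = labels.reindex(dec.loadings.index)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise DegenerateInputError(f"need exactly 2 classes, got {classes}")
    mask = (labels == classes[0]).to_numpy()
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise DegenerateInputError("each class needs >= 2 samples")
    k = dec.n_components if n_components is None else min(n_components, dec.n_components)
    ps = []
    for comp in range(k):
        a = dec.loadings.iloc[:, comp].to_numpy()[mask]
        b = dec.loadings.iloc[:, comp].to_numpy()[~mask]
        if a.std() == 0 and b.std() == 0:
            p = 0.0 if a.mean() != b.mean() else 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        ps.append(p)
    p_values = pd.Series(ps, index=pd.RangeIndex(1, k + 1, name="component"))
    selected = int(p_values.idxmin())
    return PCAssociation(p_values, selected)


def attribute_probe_pvalues(
    dec: PCADecomposition, components: list[int]
) -> pd.Series:
    """Chi-squared p-value per probe from its standardized PC scores.

    For each probe i and chosen component l, ``z = u_li / sd_over_probes(u_l)``;
    the statistic ``sum_l z**2`` is referred to a chi-squared distribution
    with df = number of components, upper tail. Probes whose scores sit at
    the null centre get p = 1; outlying probes get small p.
    """
    if not components:
        raise ValueError("components must be non-empty")
    bad = [c for c in components if not 1 <= c <= dec.n_components]
    if bad:
        raise ValueError(f"component indices out of range: {bad}")
    stat = np.zeros(dec.scores.shape[0])
    for comp in components:
        u = dec.scores.iloc[:, comp - 1].to_numpy()
        sd = u.std()
        if sd == 0:
            raise DegenerateInputError(f"score column {comp} has zero variance")
        stat += (u / sd) ** 2
    p = stats.chi2.sf(stat, df=len(components))
    return pd.Series(p, index=dec.scores.index, name="raw_p")


def adjust_bh(p: "np.ndarray | list[float] | pd.Series") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    arr = np.asarray(pd.Series(p).to_numpy(), dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def select_probes(
    raw_p: pd.Series, alpha: float = 0.01, components_used: list[int] | None = None
) -> ProbeSelection:
    """Threshold BH-adjusted probe p-values at ``alpha``."""
    if raw_p.empty:
        raise ValueError("raw_p must be non-empty")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    adjusted = pd.Series(adjust_bh(raw_p), index=raw_p.index, name="adjusted_p")
    return ProbeSelection(raw_p, adjusted, alpha, list(components_used or []))


def map_probes_to_genes(
    selection: "ProbeSelection | list[str]", annotation: ProbeAnnotation
) -> list[str]:
    """Ordered unique gene symbols of the selected probes.

    Several probes interrogating the same gene collapse to one symbol;
    probes without a symbol are counted and reported via a warning.
    """
    probes = (
        selection.selected_probes
        if isinstance(selection, ProbeSelection)
        else list(selection)
    )
    symbols, unmapped = annotation.symbols_for(probes)
    if unmapped:
        warnings.warn(f"{unmapped} selected probe(s) had no gene symbol", stacklevel=2)
    return symbols
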