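"""Core in-memory containers shared across the pipeline.

The pipeline works on bulk expression matrices laid out probes x samples
(the microarray convention): rows are probes/genes, columns are samples,
and a per-sample class label ("control" / "case") rides along with the
matrix. Gene-set libraries follow the GMT model: a named collection of
symbol sets with optional descriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CONTROL = "control"
CASE = "case"
VALID_LABELS = (CONTROL, CASE)


class FormatError(ValueError):
    """Raised when an input file or table violates its format contract."""


class MergeError(ValueError):
    """Raised when datasets cannot be merged (ID collisions, empty overlap)."""


@dataclass
class ExpressionMatrix:
    """A probes x samples expression matrix with optional class labels.

    Parameters
    ----------
    values
        DataFrame with probe IDs as the index and sample IDs as columns.
        Entries are normalized expression intensities (linear or log scale,
        as provided upstream).
    labels
        Optional Series mapping sample ID -> {"control", "case"}. When
        present it must cover every sample in ``values``.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe IDs: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dups[:5]}")
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise FormatError("expression values must be numeric")
        if self.labels is not None:
            self.labels = self.labels.reindex(cols)
            if self.labels.isna().any():
                missing = self.labels.index[self.labels.isna()].tolist()
                raise FormatError(f"samples without a class label: {missing[:5]}")
            bad = sorted(set(self.labels) - set(VALID_LABELS))
            if bad:
                raise FormatError(
                    f"labels must be one of {VALID_LABELS}, got {bad}"
                )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_mask(self, label: str = CASE) -> np.ndarray:
        """Boolean mask over samples belonging to ``label``."""
        if self.labels is None:
            raise ValueError("matrix carries no class labels")
        return (self.labels == label).to_numpy()

    def subset_probes(self, probe_ids: Iterable[str]) -> "ExpressionMatrix":
        """Restrict to the given probes, preserving current probe order."""
        wanted = set(probe_ids)
        keep = [p for p in self.values.index if p in wanted]
        return ExpressionMatrix(self.values.loc[keep], self.labels)


@dataclass
class ProbeAnnotation:
    """Many-to-one probe -> gene-symbol map.

    Symbols are uppercased at construction so matching against GMT
    libraries is case-insensitive. Probes absent from the mapping are
    treated as unmapped by :meth:`symbols_for`.
    """

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        self.mapping = {p: s.upper() for p, s in self.mapping.items()}

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, probe: str) -> bool:
        return probe in self.mapping

    def symbol(self, probe: str) -> str | None:
        return self.mapping.get(probe)

    def symbols_for(self, probes: Iterable[str]) -> tuple[list[str], int]:
        """Ordered unique symbols for ``probes``; also counts unmapped probes.

        Order follows first appearance in the input; duplicate symbols
        (several probes interrogating the same gene) are collapsed.
        """
        seen: dict[str, None] = {}
        unmapped = 0
        for p in probes:
            s = self.mapping.get(p)
            if s is None:
                unmapped += 1
            elif s not in seen:
                seen[s] = None
        return list(seen), unmapped

    @property
    def all_symbols(self) -> set[str]:
        return set(self.mapping.values())


@dataclass
class GeneSetLibrary:
    """Named gene sets (term -> member symbols), GMT-style."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()

    def union(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return out


def make_labels(sample_ids: Iterable[str], classes: Mapping[str, str] | Iterable[str]) -> pd.Series:
    """Build a label Series aligned to ``sample_ids``."""
    sample_ids = list(sample_ids)
    if isinstance(classes, Mapping):
        ser = pd.Series({s: classes[s] for s in sample_ids})
    else:
        ser = pd.Series(list(classes), index=sample_ids)
    return ser.reindex(sample_ids)
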