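"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices travel as tab-delimited tables (first column probe ID,
header row of sample IDs), labels and probe annotations as two-column TSV,
gene-set libraries as standard GMT. ``merge_datasets`` integrates several
series measured on a shared platform into one matrix by intersecting their
probe sets and concatenating samples.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    FormatError,
    GeneSetLibrary,
    MergeError,
    ProbeAnnotation,
)

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_labels",
    "write_labels",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_gmt",
    "write_gmt",
    "merge_datasets",
]


def read_expression_table(
    path: str | Path, labels_path: str | Path | None = None
) -> ExpressionMatrix:
    """Read a tab-delimited probe x sample table, optionally joining labels.

    The first column holds probe IDs, the header row sample IDs. Every cell
    must parse as a real number; ragged rows and duplicate probe IDs are
    format errors reported with the offending line number.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        ncol = len(sample_ids)
        probes: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncol + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {ncol + 1} fields, got {len(fields)}"
                )
            probe = fields[0]
            if probe in seen:
                raise FormatError(f"{path}:{lineno}: duplicate probe ID {probe!r}")
            seen.add(probe)
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            probes.append(probe)
    values = pd.DataFrame(
        np.asarray(rows, dtype=float), index=probes, columns=sample_ids
    )
    labels = read_labels(labels_path, sample_ids) if labels_path is not None else None
    return ExpressionMatrix(values, labels)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_labels(path: str | Path, sample_ids: Sequence[str] | None = None) -> pd.Series:
    """Read a two-column (sample_id, class) TSV into a label Series."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            mapping[fields[0]] = fields[1]
    if sample_ids is not None:
        unknown = sorted(set(mapping) - set(sample_ids))
        if unknown:
            raise FormatError(f"{path}: labels for unknown samples: {unknown[:5]}")
        return pd.Series(mapping).reindex(sample_ids)
    return pd.Series(mapping)


def write_labels(labels: pd.Series, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sample, cls in labels.items():
            fh.write(f"{sample}\t{cls}\n")


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a two-column (probe_id, symbol) TSV.

    Identical duplicate rows collapse; a probe listed with two different
    symbols is a format error.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            probe, symbol = fields[0], fields[1].upper()
            if probe in mapping and mapping[probe] != symbol:
                raise FormatError(
                    f"{path}:{lineno}: probe {probe!r} maps to both "
                    f"{mapping[probe]!r} and {symbol!r}"
                )
            mapping[probe] = symbol
    return ProbeAnnotation(mapping)


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for probe, symbol in annotation.mapping.items():
            fh.write(f"{probe}\t{symbol}\n")


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Read a GMT library: per line, term TAB description TAB members...

    Member symbols are uppercased and deduplicated; empty member fields are
    dropped. A line with fewer than three fields is a format error.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            term, desc = fields[0], fields[1]
            if term in sets:
                raise FormatError(f"{path}:{lineno}: duplicate term {term!r}")
            members = frozenset(f.upper() for f in fields[2:] if f)
            if not members:
                raise FormatError(f"{path}:{lineno}: term {term!r} has no members")
            sets[term] = members
            descriptions[term] = desc
    return GeneSetLibrary(sets, descriptions)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term, members in library.sets.items():
            desc = library.descriptions.get(term, "")
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def merge_datasets(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Integrate several datasets into one matrix.

    Probes are restricted to the intersection of all probe sets, in the
    first matrix's order; samples are concatenated in input order. No
    cross-dataset renormalization is applied — inputs are assumed to be
    normalized profiles from a shared platform.
    """
    if not matrices:
        raise MergeError("need at least one matrix")
    if len(matrices) == 1:
        return matrices[0]
    common = set(matrices[0].probe_ids)
    for m in matrices[1:]:
        common &= set(m.probe_ids)
    if not common:
        raise MergeError("probe ID intersection is empty")
    order = [p for p in matrices[0].probe_ids if p in common]
    all_samples: list[str] = []
    for m in matrices:
        all_samples.extend(m.sample_ids)
    if len(all_samples) != len(set(all_samples)):
        dup = sorted({s for s in all_samples if all_samples.count(s) > 1})
        raise MergeError(f"colliding sample IDs: {dup[:5]}")
    values = pd.concat([m.values.loc[order] for m in matrices], axis=1)
    labels = None
    if all(m.labels is not None for m in matrices):
        labels = pd.concat([m.labels for m in matrices])
    return ExpressionMatrix(values, labels)
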