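"""Expression data sets: parsing, scale handling, probe collapse, harmonization.

The central container is :class:`ExpressionDataset`, a gene x sample matrix of
non-negative expression values together with per-sample condition/control
labels. Readers exist for two plain-text formats: the GEO series-matrix
exchange dialect ("!"-prefixed metadata around a probe x sample table) and
bare TSV matrices (first column gene id, header row sample ids).

Downstream scoring requires linear-scale, strictly positive values with no
missing entries; :func:`to_linear` and the row-dropping rules here establish
that invariant. Gene rows with missing or nonpositive values are dropped from
the affected data set and treated as "absent" by the aggregation stage — no
imputation is attempted, since the meta-analysis tolerates per-dataset gene
absence by design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AnnotationError,
    DuplicateIdentifierError,
    EmptyInputError,
    FormatError,
    MappingError,
)

CONDITION = "condition"
CONTROL = "control"
GROUPS = (CONDITION, CONTROL)

#: Values at or below this 99th-percentile threshold are taken as log2 scale.
LOG_DETECTION_PERCENTILE = 99.0
LOG_DETECTION_THRESHOLD = 30.0


@dataclass(frozen=True)
class ExpressionDataset:
    """One study's gene x sample expression matrix with sample annotation.

    Parameters
    ----------
    dataset_id : str
        Provenance label (e.g. a GEO series accession or a file stem).
    values : pandas.DataFrame
        Expression matrix, genes as index, samples as columns.
    scale : {"log2", "linear"}
        Scale the stored values are on.
    groups : pandas.Series or None
        Per-sample label, ``"condition"`` or ``"control"``; ``None`` until
        :func:`annotate_samples` is applied.
    organism : str
        Free-text organism label; used only to decide whether orthology
        mapping is required when harmonizing.
    """

    dataset_id: str
    values: pd.DataFrame
    scale: Literal["log2", "linear"] = "linear"
    groups: pd.Series | None = None
    organism: str = "unspecified"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise DuplicateIdentifierError(
                f"{self.dataset_id}: duplicate gene/probe ids {list(dups[:5])!r}"
            )
        if self.values.columns.has_duplicates:
            raise DuplicateIdentifierError(f"{self.dataset_id}: duplicate sample ids")
        if self.groups is not None:
            _check_groups(self.values.columns, self.groups, self.dataset_id)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        if self.groups is None:
            raise AnnotationError(f"{self.dataset_id}: samples not annotated")
        return list(self.groups.index[self.groups == group])

    def require_annotated(self) -> None:
        if self.groups is None:
            raise AnnotationError(
                f"{self.dataset_id}: condition/control labels required before scoring"
            )


def _check_groups(samples: pd.Index, groups: pd.Series, dataset_id: str) -> None:
    unknown = set(groups.index) - set(samples)
    if unknown:
        raise AnnotationError(f"{dataset_id}: labels for unknown samples {sorted(unknown)!r}")
    missing = set(samples) - set(groups.index)
    if missing:
        raise AnnotationError(f"{dataset_id}: unlabelled samples {sorted(missing)!r}")
    bad = set(groups.unique()) - set(GROUPS)
    if bad:
        raise AnnotationError(f"{dataset_id}: labels must be in {GROUPS}, got {sorted(bad)!r}")
    for g in GROUPS:
        if (groups == g).sum() == 0:
            raise AnnotationError(f"{dataset_id}: group {g!r} has no samples")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_TABLE_BEGIN = "!series_matrix_table_begin"
_TABLE_END = "!series_matrix_table_end"
_MISSING_TOKENS = {"", "null", "NULL", "NA", "na", "NaN", "nan", "None"}


def read_series_matrix(path: str | Path, dataset_id: str | None = None) -> ExpressionDataset:
    """Parse a GEO series-matrix text file into an :class:`ExpressionDataset`.

    The dialect: lines starting with ``!`` carry metadata; the value table sits
    between ``!series_matrix_table_begin`` and ``!series_matrix_table_end``,
    with a header row whose first field is ``ID_REF`` followed by sample
    accessions. Probes with any missing value (empty or ``null``-like token)
    are dropped. Scale is guessed with :func:`detect_log_scale`; group labels
    are left unset and must be supplied via :func:`annotate_samples`.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    try:
        begin = next(i for i, l in enumerate(lines) if l.strip().lower() == _TABLE_BEGIN)
    except StopIteration:
        raise FormatError(f"{path}: missing {_TABLE_BEGIN!r} delimiter") from None
    try:
        end = next(i for i, l in enumerate(lines) if l.strip().lower() == _TABLE_END)
    except StopIteration:
        raise FormatError(f"{path}: missing {_TABLE_END!r} delimiter") from None
    if end <= begin + 1:
        raise FormatError(f"{path}: empty series-matrix table")

    table = [l.split("\t") for l in lines[begin + 1 : end] if l.strip()]
    header = [_unquote(c) for c in table[0]]
    if not header or header[0].upper() != "ID_REF":
        raise FormatError(f"{path}: table header must start with ID_REF, got {header[:1]!r}")
    width = len(header)
    sample_ids = header[1:]
    probes: list[str] = []
    rows: list[list[float]] = []
    for raw in table[1:]:
        if len(raw) != width:
            raise FormatError(
                f"{path}: ragged row (expected {width} fields, got {len(raw)}): {raw[0]!r}"
            )
        cells = [_unquote(c) for c in raw]
        vals = []
        ok = True
        for c in cells[1:]:
            if c.strip() in _MISSING_TOKENS:
                ok = False
                break
            try:
                vals.append(float(c))
            except ValueError:
                ok = False
                break
        if not ok:
            continue  # missing-value rule: drop the probe from this data set
        probes.append(cells[0])
        rows.append(vals)
    if not probes:
        raise EmptyInputError(f"{path}: no complete probe rows in table")
    values = pd.DataFrame(np.asarray(rows, dtype=float), index=probes, columns=sample_ids)
    ds_id = dataset_id or _series_accession(lines) or path.stem
    return ExpressionDataset(
        dataset_id=ds_id,
        values=values,
        scale=detect_log_scale(values.to_numpy()),
        organism=_series_organism(lines) or "unspecified",
    )


def _unquote(cell: str) -> str:
    cell = cell.strip()
    if len(cell) >= 2 and cell[0] == '"' and cell[-1] == '"':
        return cell[1:-1]
    return cell


def _series_accession(lines: Iterable[str]) -> str | None:
    for l in lines:
        if l.startswith("!Series_geo_accession"):
            parts = l.split("\t")
            if len(parts) > 1:
                return _unquote(parts[1])
    return None


def _series_organism(lines: Iterable[str]) -> str | None:
    for l in lines:
        if l.startswith("!Series_sample_organism") or l.startswith("!Sample_organism_ch1"):
            parts = l.split("\t")
            if len(parts) > 1:
                return _unquote(parts[1])
    return None


def read_tsv_matrix(
    path: str | Path,
    dataset_id: str | None = None,
    organism: str = "unspecified",
) -> ExpressionDataset:
    """Read a plain TSV matrix: header row = sample ids, first column = gene id.

    Rows containing missing values are dropped (same rule as the series-matrix
    reader).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if frame.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    frame = frame.apply(pd.to_numeric, errors="coerce")
    frame = frame.dropna(axis=0, how="any")
    if frame.empty:
        raise EmptyInputError(f"{path}: no complete gene rows")
    frame.index = frame.index.astype(str)
    return ExpressionDataset(
        dataset_id=dataset_id or path.stem,
        values=frame,
        scale=detect_log_scale(frame.to_numpy()),
        organism=organism,
    )


def write_tsv_matrix(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write the value matrix as TSV (full float precision round trip)."""
    dataset.values.to_csv(Path(path), sep="\t", index_label="gene_id", float_format="%.17g")


def read_mapping_table(path: str | Path, direction: str = "probe_to_gene") -> "MappingTable":
    """Read a two-column headerless TSV of (source_id, target_id) pairs."""
    pairs: list[tuple[str, str]] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}: expected two tab-separated columns: {line!r}")
        src, tgt = parts[0].strip(), parts[1].strip()
        if not src or not tgt:
            raise FormatError(f"{path}: empty identifier in line {line!r}")
        pairs.append((src, tgt))
    return MappingTable(pairs=tuple(pairs), direction=direction)


def read_annotation(path: str | Path) -> dict[str, str]:
    """Read sample annotation TSV: two columns, sample_id and group label."""
    labels: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 2:
            raise FormatError(f"{path}: expected sample_id<TAB>group: {line!r}")
        if parts[0] in ("sample_id", "sample"):  # tolerate a header row
            continue
        labels[parts[0]] = parts[1]
    if not labels:
        raise EmptyInputError(f"{path}: no annotation rows")
    return labels


# ---------------------------------------------------------------------------
# scale handling
# ---------------------------------------------------------------------------


def detect_log_scale(values: np.ndarray) -> Literal["log2", "linear"]:
    """Guess whether a matrix is log2- or linear-scale.

    Microarray intensities on linear scale span hundreds to tens of thousands,
    while log2 values sit below ~20. The 99th percentile (rather than the
    maximum) makes the call robust to isolated outliers.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise EmptyInputError("cannot detect scale of an empty/all-missing matrix")
    p99 = np.percentile(arr, LOG_DETECTION_PERCENTILE)
    return "log2" if p99 <= LOG_DETECTION_THRESHOLD else "linear"


def to_linear(dataset: ExpressionDataset) -> ExpressionDataset:
    """Exponentiate log2-scale values (2**x) to recover linear expression.

    Linear data sets pass through unchanged; gene rows that end up with a
    value <= 0 on the linear scale are dropped, since fold change and CV are
    undefined for them.
    """
    if dataset.scale == "linear":
        return _drop_nonpositive(dataset)
    values = np.exp2(dataset.values)
    return _drop_nonpositive(replace(dataset, values=values, scale="linear"))


def _drop_nonpositive(dataset: ExpressionDataset) -> ExpressionDataset:
    keep = (dataset.values > 0).all(axis=1) & dataset.values.notna().all(axis=1)
    if keep.all():
        return dataset
    return replace(dataset, values=dataset.values.loc[keep])


# ---------------------------------------------------------------------------
# probe collapse and gene-namespace harmonization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MappingTable:
    """Identifier mapping: probe -> gene, or organism gene -> ortholog group.

    Source ids may repeat (several probes per gene); empty ids are rejected.
    """

    pairs: tuple[tuple[str, str], ...]
    direction: str = "probe_to_gene"

    def __post_init__(self) -> None:
        for src, tgt in self.pairs:
            if not src or not tgt:
                raise MappingError("mapping contains an empty identifier")

    def as_dict(self) -> dict[str, str]:
        # later entries win; duplicated sources with conflicting targets are rare
        return {src: tgt for src, tgt in self.pairs}


def collapse_probes(dataset: ExpressionDataset, mapping: MappingTable) -> ExpressionDataset:
    """Collapse probe-level rows to gene-level rows.

    For genes measured by several probes, the probe with the highest mean
    expression is kept as the gene's representative row (averaging would mix
    cross-hybridizing probes of very different signal). Probes without a
    mapping entry are dropped.
    """
    lookup = mapping.as_dict()
    mapped = [p for p in dataset.gene_ids if p in lookup]
    if not mapped:
        raise MappingError(
            f"{dataset.dataset_id}: no overlap between dataset probes and mapping"
        )
    sub = dataset.values.loc[mapped]
    genes = pd.Series([lookup[p] for p in mapped], index=sub.index, name="gene")
    best_probe = sub.mean(axis=1).groupby(genes).idxmax()
    collapsed = sub.loc[best_probe.to_numpy()]
    collapsed.index = pd.Index(best_probe.index, name="gene_id")
    collapsed = collapsed.sort_index()
    return replace(dataset, values=collapsed)


def harmonize_genes(
    datasets: Sequence[ExpressionDataset],
    orthology: MappingTable | None = None,
) -> list[ExpressionDataset]:
    """Bring all data sets onto one shared gene namespace.

    With a single organism the identifiers are kept as-is. Across organisms an
    orthology table (gene id -> ortholog-group id) is required; genes without
    an ortholog entry are dropped from cross-organism collections. Gene sets
    are NOT intersected — each data set keeps its own genes and the union
    forms the analysis universe, with absence handled by the ranking penalty.
    """
    organisms = {d.organism for d in datasets}
    if len(organisms) <= 1:
        return list(datasets)
    if orthology is None:
        raise MappingError(
            f"data sets span organisms {sorted(organisms)!r} but no orthology table given"
        )
    lookup = orthology.as_dict()
    out: list[ExpressionDataset] = []
    for ds in datasets:
        mapped = [g for g in ds.gene_ids if g in lookup]
        if not mapped:
            raise MappingError(f"{ds.dataset_id}: no genes found in orthology table")
        sub = ds.values.loc[mapped]
        groups = pd.Series([lookup[g] for g in mapped], index=sub.index)
        # several organism genes may map to one group: keep the strongest signal
        best = sub.mean(axis=1).groupby(groups).idxmax()
        renamed = sub.loc[best.to_numpy()]
        renamed.index = pd.Index(best.index, name="gene_id")
        out.append(replace(ds, values=renamed.sort_index()))
    return out


def gene_universe(datasets: Sequence[ExpressionDataset]) -> list[str]:
    """Sorted union of gene ids over all data sets."""
    universe: set[str] = set()
    for ds in datasets:
        universe.update(ds.gene_ids)
    return sorted(universe)


def annotate_samples(
    dataset: ExpressionDataset, labels: Mapping[str, str]
) -> ExpressionDataset:
    """Attach condition/control labels; every sample must be covered and both
    groups must be non-empty."""
    extra = set(labels) - set(dataset.sample_ids)
    if extra:
        raise AnnotationError(
            f"{dataset.dataset_id}: labels for unknown samples {sorted(extra)!r}"
        )
    groups = pd.Series(dict(labels)).reindex(dataset.sample_ids)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])
        raise AnnotationError(f"{dataset.dataset_id}: unlabelled samples {missing!r}")
    return replace(dataset, groups=groups)
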