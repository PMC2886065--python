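"""Core dataset containers, readers/writers, series merging and gene-name resolution.

Expression data is held as a genes x samples :class:`numpy.ndarray` of floats
with ``NaN`` as the dataset-wide missing marker, together with ordered gene and
sample identifier lists.  A :class:`SeriesTable` is a single experimental
series; an :class:`ExpressionDataset` is one or more series concatenated
sample-wise, each sample carrying the label of its source series (its batch).
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SeriesTable",
    "ExpressionDataset",
    "GeneIndex",
    "read_expression_table",
    "write_expression_table",
    "read_batch_map",
    "merge_series",
    "resolve_gene",
    "DEFAULT_ALIASES",
]


class DataModelError(ValueError):
    """Raised for malformed inputs or violated dataset invariants."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    dupes = [g for g, c in Counter(ids).items() if c > 1]
    if dupes:
        raise DataModelError(f"duplicate {what}: {sorted(dupes)}")


@dataclass
class SeriesTable:
    """One experimental series: a genes x samples matrix with NaN for missing."""

    series_id: str
    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataModelError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if len(self.sample_ids) < 2:
            raise DataModelError("a series needs at least 2 samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ExpressionDataset:
    """Batched expression matrix: samples from several series side by side.

    ``batch_labels`` holds one source-series label per sample, in sample order.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    batch_labels: list[str]
    values: np.ndarray
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataModelError("matrix shape does not match id lists")
        if len(self.batch_labels) != len(self.sample_ids):
            raise DataModelError("every sample needs a batch label")
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        for b, c in Counter(self.batch_labels).items():
            if c < 2:
                raise DataModelError(f"batch {b!r} has fewer than 2 samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def batches(self) -> list[str]:
        """Distinct batch labels in first-appearance order."""
        seen: dict[str, None] = {}
        for b in self.batch_labels:
            seen.setdefault(b)
        return list(seen)

    def batch_columns(self, batch: str) -> np.ndarray:
        """Column indices of the samples belonging to ``batch``."""
        lab = np.asarray(self.batch_labels)
        return np.flatnonzero(lab == batch)

    def gene_row(self, gene_id: str) -> int:
        try:
            return self._gene_pos[gene_id]
        except AttributeError:
            self._gene_pos = {g: i for i, g in enumerate(self.gene_ids)}
            return self.gene_row(gene_id)
        except KeyError:
            raise DataModelError(f"gene {gene_id!r} not in dataset") from None

    def profile(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_row(gene_id)]

    def split_by_batch(self) -> dict[str, SeriesTable]:
        """Recover one :class:`SeriesTable` per batch (round trip of merge)."""
        out = {}
        for b in self.batches:
            cols = self.batch_columns(b)
            out[b] = SeriesTable(
                series_id=b,
                gene_ids=list(self.gene_ids),
                sample_ids=[self.sample_ids[j] for j in cols],
                values=self.values[:, cols].copy(),
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


# ---------------------------------------------------------------------------
# readers / writers

_GEO_BEGIN = "!series_matrix_table_begin"
_GEO_END = "!series_matrix_table_end"


def read_expression_table(path, dialect: str = "tsv", series_id: str | None = None) -> SeriesTable:
    """Read a genes x samples table from ``path``.

    Parameters
    ----------
    path
        File path (or open text handle).
    dialect
        ``"tsv"`` — plain tab-delimited table, first row sample ids, first
        column gene ids, empty cells missing; ``"geo_series_matrix"`` — a GEO
        series-matrix file whose value table lies between the standard
        begin/end markers.
    series_id
        Label for the resulting series; defaults to the file stem.
    """
    if dialect not in ("tsv", "geo_series_matrix"):
        raise DataModelError(f"unknown dialect {dialect!r}")

    if hasattr(path, "read"):
        text = path.read()
        name = series_id or "series"
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        name = series_id or str(path).rsplit("/", 1)[-1].split(".")[0]

    if dialect == "geo_series_matrix":
        lines = text.splitlines()
        try:
            lo = next(i for i, l in enumerate(lines) if l.strip().lower() == _GEO_BEGIN)
            hi = next(i for i, l in enumerate(lines) if l.strip().lower() == _GEO_END)
        except StopIteration:
            raise DataModelError(
                f"series-matrix markers {_GEO_BEGIN!r}/{_GEO_END!r} not found"
            ) from None
        text = "\n".join(lines[lo + 1 : hi])
        if not text.strip():
            raise DataModelError("empty series-matrix value table")

    buf = io.StringIO(text)
    header = buf.readline().rstrip("\n")
    if not header or "\t" not in header:
        raise DataModelError(f"malformed header line: {header!r}")
    try:
        df = pd.read_csv(
            buf,
            sep="\t",
            header=None,
            index_col=0,
            names=[c.strip().strip('"') for c in header.split("\t")],
            na_values=[""],
            keep_default_na=True,
            quotechar='"',
            float_precision="round_trip",
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataModelError(f"failed to parse table: {exc}") from exc
    if df.shape[0] == 0:
        raise DataModelError("empty table: no gene rows")
    gene_ids = [str(g).strip().strip('"') for g in df.index]
    _check_unique(gene_ids, "gene ids")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return SeriesTable(
        series_id=name,
        gene_ids=gene_ids,
        sample_ids=[str(c) for c in df.columns],
        values=values,
    )


def write_expression_table(obj: SeriesTable | ExpressionDataset, path) -> None:
    """Write a tab-delimited table (empty cell = missing); inverse of the TSV reader."""
    df = obj.to_frame()
    df.index.name = "gene_id"
    # %.17g round-trips every finite double exactly
    df.to_csv(path, sep="\t", na_rep="", float_format="%.17g")


def read_batch_map(path) -> dict[str, str]:
    """Read a two-column TSV ``sample_id<TAB>batch_label`` (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "batch"], dtype=str)
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise DataModelError(f"duplicate sample ids in batch map: {dup}")
    return dict(zip(df["sample_id"], df["batch"]))


# ---------------------------------------------------------------------------
# merging

def collapse_probes(table: SeriesTable, probe_map: Mapping[str, str]) -> SeriesTable:
    """Average replicate probe rows mapping to one locus tag (NaN-aware).

    Off by default in every pipeline; apply explicitly BEFORE transformation
    when the input table carries probe-level rows.  Probes absent from
    ``probe_map`` keep their own id.
    """
    df = table.to_frame()
    target = [probe_map.get(g, g) for g in df.index]
    collapsed = df.groupby(pd.Index(target, name="gene"), sort=False).mean()
    return SeriesTable(
        series_id=table.series_id,
        gene_ids=[str(g) for g in collapsed.index],
        sample_ids=list(table.sample_ids),
        values=collapsed.to_numpy(dtype=float),
    )


def merge_series(
    series: Sequence[SeriesTable],
    gene_policy: str = "intersect",
    name: str = "merged",
) -> ExpressionDataset:
    """Concatenate several series sample-wise into one batched dataset.

    Under ``gene_policy="intersect"`` the gene set is the intersection across
    series, in first-series order; under ``"union_with_missing"`` it is the
    union (first-appearance order) with absent genes filled with NaN.  Sample
    ids are prefixed ``<series_id>:`` when needed to stay unique.
    """
    if gene_policy not in ("intersect", "union_with_missing"):
        raise DataModelError(f"unknown gene_policy {gene_policy!r}")
    if not series:
        raise DataModelError("need at least one series to merge")

    tables = [s.to_frame() for s in series]

    if gene_policy == "intersect":
        common = set(tables[0].index)
        for t in tables[1:]:
            common &= set(t.index)
        gene_ids = [g for g in tables[0].index if g in common]
        if not gene_ids:
            raise DataModelError("gene intersection across series is empty")
    else:
        seen: dict[str, None] = {}
        for t in tables:
            for g in t.index:
                seen.setdefault(g)
        gene_ids = list(seen)

    all_plain = [sid for s in series for sid in s.sample_ids]
    prefix = len(set(all_plain)) != len(all_plain) or len(set(s.series_id for s in series)) != len(series)
    if len(set(s.series_id for s in series)) != len(series):
        raise DataModelError("series ids must be distinct")

    sample_ids: list[str] = []
    batch_labels: list[str] = []
    blocks: list[np.ndarray] = []
    for s, t in zip(series, tables):
        ids = [f"{s.series_id}:{sid}" if prefix else sid for sid in s.sample_ids]
        sample_ids.extend(ids)
        batch_labels.extend([s.series_id] * s.n_samples)
        blocks.append(t.reindex(gene_ids).to_numpy(dtype=float))

    return ExpressionDataset(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        batch_labels=batch_labels,
        values=np.hstack(blocks),
        name=name,
    )


# ---------------------------------------------------------------------------
# gene-name resolution

#: Common-name aliases for the Shewanella oneidensis MR-1 genes this package's
#: analyses revolve around (anaerobic-respiratory-plasticity genes, the two
#: chemotaxis kinases, and other named leads).
DEFAULT_ALIASES: dict[str, str] = {
    "cymA": "SO4591",
    "mtrA": "SO1777",
    "mtrB": "SO1776",
    "omcB": "SO1778",
    "mtrC": "SO1778",
    "omcA": "SO1779",
    "gspF": "SO0168",
    "gspD": "SO0166",
    "gspE": "SO0167",
    "cheA-1": "SO2121",
    "cheA-3": "SO3207",
    "crp": "SO0624",
    "petC": "SO0610",
}


@dataclass
class GeneIndex:
    """Bidirectional common-name <-> locus-tag mapping restricted to a dataset.

    Lookups are case-insensitive on common names and exact on locus tags; a
    query must resolve to exactly one gene id present in the dataset.
    """

    aliases: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_ALIASES))
    known_ids: frozenset[str] | None = None

    def __post_init__(self) -> None:
        self._lower = {k.lower(): v for k, v in self.aliases.items()}
        if len(self._lower) != len(self.aliases):
            raise DataModelError("alias table has case-colliding common names")

    @classmethod
    def for_dataset(cls, ds: ExpressionDataset, aliases: Mapping[str, str] | None = None) -> "GeneIndex":
        return cls(aliases=dict(aliases or DEFAULT_ALIASES), known_ids=frozenset(ds.gene_ids))

    def resolve(self, query: str) -> str:
        q = query.strip()
        gene_id = self._lower.get(q.lower(), q)
        if self.known_ids is not None and gene_id not in self.known_ids:
            near = [k for k in self.aliases if k.lower().startswith(q[:3].lower())]
            raise DataModelError(
                f"gene {query!r} not found in dataset"
                + (f"; near matches: {sorted(near)}" if near else "")
            )
        if self.known_ids is None and q.lower() not in self._lower and not q.upper().startswith("SO"):
            raise DataModelError(f"unknown gene {query!r}")
        return gene_id

    def common_name(self, gene_id: str) -> str:
        for k, v in self.aliases.items():
            if v == gene_id:
                return k
        return gene_id


def resolve_gene(query: str, index: GeneIndex) -> str:
    """Resolve a common name or locus tag to the unique gene id (see :class:`GeneIndex`)."""
    return index.resolve(query)
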