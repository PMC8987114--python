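"""Domain types and tabular/graph readers and writers.

The pipeline's in-memory containers are thin frozen wrappers around numpy
arrays with explicit gene/sample identifiers, validated on construction.
Expression and trait tables are plain TSV/CSV; gene sets are GMT v2; the
differential-correlation network is exported as an edge TSV or GraphML so
Cytoscape-class viewers can load it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("coexdiff")

__all__ = [
    "ExpressionMatrix",
    "TraitVector",
    "CorrelationMatrix",
    "AdjacencyMatrix",
    "TomMatrix",
    "Dendrogram",
    "ModuleAssignment",
    "DiffCorrRecord",
    "GeneSetCollection",
    "FormatError",
    "AlignmentError",
    "read_expression",
    "read_traits",
    "read_gmt",
    "write_expression",
    "write_network",
    "EDGE_TSV_COLUMNS",
]


class FormatError(ValueError):
    """Malformed input file (bad header, non-numeric cell, short GMT line)."""


class AlignmentError(ValueError):
    """Sample or gene identifiers do not line up between two inputs."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if list(ids).count(x) > 1})
        raise ValueError(f"duplicate {what} identifiers: {dupes[:5]}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression values.

    Rows are genes, columns are samples; all values must be finite (missing
    values are resolved at read time by the chosen NA policy).
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) < 2 or len(self.sample_ids) < 2:
            raise ValueError("need at least 2 genes and 2 samples")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite after NA handling")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.sample_ids))

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise AlignmentError(f"genes absent from matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(tuple(genes), self.sample_ids, self.values[rows])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise AlignmentError(f"samples absent from matrix: {missing[:5]}")
        cols = [index[s] for s in samples]
        return ExpressionMatrix(self.gene_ids, tuple(samples), self.values[:, cols])


@dataclass(frozen=True)
class TraitVector:
    """Binary condition labels (1 = disease, 0 = control) aligned to a matrix."""

    sample_ids: tuple[str, ...]
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.shape != (len(self.sample_ids),):
            raise ValueError("labels length must match sample_ids")
        bad = set(np.unique(labels)) - {0, 1}
        if bad:
            raise ValueError(f"trait labels must be 0/1, found {sorted(bad)}")
        # Fisher z needs n - 3 > 0 in each class
        for cls in (0, 1):
            n = int(np.sum(labels == cls))
            if n < 4:
                raise ValueError(
                    f"condition {cls} has {n} samples; need >= 4 per class"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def aligned_to(self, matrix: ExpressionMatrix) -> "TraitVector":
        if tuple(self.sample_ids) == tuple(matrix.sample_ids):
            return self
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in matrix.sample_ids if s not in index]
        if missing:
            raise AlignmentError(f"samples missing from traits: {missing[:5]}")
        order = [index[s] for s in matrix.sample_ids]
        return TraitVector(tuple(matrix.sample_ids), self.labels[order])


def _validate_square(gene_ids: Sequence[str], values: np.ndarray,
                     low: float, high: float, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    n = len(gene_ids)
    if values.shape != (n, n):
        raise ValueError(f"{name} must be {n}x{n}, got {values.shape}")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError(f"{name} must be symmetric to 1e-12")
    if not np.allclose(np.diag(values), 1.0, atol=1e-12):
        raise ValueError(f"{name} must have unit diagonal")
    if values.min() < low - 1e-12 or values.max() > high + 1e-12:
        raise ValueError(f"{name} entries must lie in [{low}, {high}]")
    return values


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Pearson correlation; unsigned stores absolute values."""

    gene_ids: tuple[str, ...]
    values: np.ndarray
    signed: bool = False

    def __post_init__(self) -> None:
        low = -1.0 if self.signed else 0.0
        object.__setattr__(
            self, "values",
            _validate_square(self.gene_ids, self.values, low, 1.0, "correlation"),
        )


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Soft-thresholded network adjacency: unsigned correlation to the power beta."""

    gene_ids: tuple[str, ...]
    values: np.ndarray
    power: int = 1

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be a positive integer")
        object.__setattr__(
            self, "values",
            _validate_square(self.gene_ids, self.values, 0.0, 1.0, "adjacency"),
        )


@dataclass(frozen=True)
class TomMatrix:
    """Topological overlap: shared-neighbour similarity with unit diagonal."""

    gene_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values",
            _validate_square(self.gene_ids, self.values, 0.0, 1.0, "TOM"),
        )


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge encoding (scipy linkage matrix plus leaf ids)."""

    linkage: np.ndarray
    leaf_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        linkage = np.asarray(self.linkage, dtype=float)
        object.__setattr__(self, "linkage", linkage)
        if linkage.shape != (len(self.leaf_ids) - 1, 4):
            raise ValueError("linkage shape must be (n_leaves - 1, 4)")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


GREY = "grey"


@dataclass(frozen=True)
class ModuleAssignment:
    """Gene -> module colour label; 'grey' marks unassigned genes."""

    assignment: dict[str, str]

    def label_of(self, gene: str) -> str:
        return self.assignment[gene]

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.assignment)

    def modules(self) -> dict[str, list[str]]:
        """Non-grey module label -> member genes (insertion order)."""
        out: dict[str, list[str]] = {}
        for gene, label in self.assignment.items():
            if label != GREY:
                out.setdefault(label, []).append(gene)
        return out

    def members(self, label: str) -> list[str]:
        return [g for g, l in self.assignment.items() if l == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.assignment), "module": list(self.assignment.values())}
        )


@dataclass(frozen=True)
class DiffCorrRecord:
    """One gene pair's correlation in each condition and the difference test.

    ``switched`` flags pairs whose correlation changes sign between the two
    conditions (r1 * r2 < 0), the "oppositely correlated" pairs.
    """

    gene_a: str
    gene_b: str
    r1: float
    n1: int
    r2: float
    n2: int
    p1: float
    p2: float
    z_stat: float
    p_diff: float
    lfdr: float
    switched: bool
    q_diff: float = float("nan")  # BH q-value, reported alongside lfdr

    def __post_init__(self) -> None:
        if abs(self.r1) > 1 or abs(self.r2) > 1:
            raise ValueError("correlations must lie in [-1, 1]")
        for p in (self.p1, self.p2, self.p_diff, self.lfdr):
            if not (0.0 <= p <= 1.0):
                raise ValueError("p-values and lfdr must lie in [0, 1]")
        if self.switched != (self.r1 * self.r2 < 0):
            raise ValueError("switched flag inconsistent with r1 * r2 sign")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (e.g. parsed from a GMT file) with optional descriptions."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.columns.isnull().any() or df.index.isnull().any():
        raise FormatError(f"{path}: missing header or gene identifier")
    return df


def read_expression(path: str | Path,
                    na_policy: str = "drop_gene") -> ExpressionMatrix:
    """Load a genes x samples expression table from TSV or CSV.

    First column holds gene identifiers, the header row sample identifiers.
    Duplicate gene rows are collapsed by their mean (with a warning), the
    common situation when several array probes map to one gene symbol.

    Parameters
    ----------
    na_policy:
        ``"drop_gene"`` removes any gene with a missing value;
        ``"impute_row_mean"`` fills gaps with the gene's mean across samples.
    """
    if na_policy not in ("drop_gene", "impute_row_mean"):
        raise ValueError(f"unknown na_policy {na_policy!r}")
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:  # pandas mangles duplicate columns, so check raw
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise FormatError(f"{path}: duplicate sample ids {dupes[:5]}")
    df = _read_table(path)

    numeric = df.apply(pd.to_numeric, errors="coerce")
    # cells that were text (not NA markers) and failed conversion are format errors
    text = df.astype(str).apply(lambda c: c.str.strip().str.lower())
    bad = numeric.isna() & df.notna() & ~text.isin(["na", "nan", ""])
    if na_policy == "drop_gene":
        bad &= False  # any unparseable cell just drops the gene below
    if bad.any().any():
        rows, cols = np.nonzero(bad.values)
        row, col = int(rows[0]), int(cols[0])
        raise FormatError(
            f"{path}: non-numeric value at gene {df.index[row]!r}, "
            f"sample {df.columns[col]!r}"
        )

    if numeric.index.duplicated().any():
        n_dup = int(numeric.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene rows by mean", n_dup)
        numeric = numeric.groupby(level=0, sort=False).mean()

    n_missing = int(numeric.isna().any(axis=1).sum())
    if n_missing:
        if na_policy == "drop_gene":
            logger.warning("dropping %d genes with missing values", n_missing)
            numeric = numeric.dropna(axis=0)
        else:
            logger.warning("imputing row means for %d genes", n_missing)
            numeric = numeric.apply(lambda r: r.fillna(r.mean()), axis=1)

    return ExpressionMatrix(
        tuple(str(g) for g in numeric.index),
        tuple(str(s) for s in numeric.columns),
        numeric.values.astype(float),
    )


def read_traits(path: str | Path, matrix: ExpressionMatrix) -> TraitVector:
    """Load a two-column (sample_id, 0/1 label) table and align it to ``matrix``."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (sample_id, label)")
    samples = df.iloc[:, 0].astype(str).tolist()
    raw = df.iloc[:, 1].astype(str).str.strip()
    if not raw.isin(["0", "1"]).all():
        bad = sorted(raw[~raw.isin(["0", "1"])].unique())
        raise FormatError(f"{path}: labels must be 0 or 1, found {bad[:5]}")
    _check_unique(samples, "sample")
    extra = [s for s in samples if s not in set(matrix.sample_ids)]
    if extra:
        raise AlignmentError(f"{path}: samples not in matrix: {extra[:5]}")
    traits = TraitVector(tuple(samples), raw.astype(int).values)
    return traits.aligned_to(matrix)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT v2 gene-set file (name, description, tab-separated members)."""
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, description = fields[0], fields[1]
            members = tuple(dict.fromkeys(m for m in fields[2:] if m.strip()))
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = members
            descriptions[name] = description
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV (gene ids first column)."""
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


EDGE_TSV_COLUMNS = (
    "source", "target", "r_cond1", "r_cond2", "p_diff", "lfdr", "sign_switch",
)


def _records_frame(records: Sequence[DiffCorrRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "source": [r.gene_a for r in records],
            "target": [r.gene_b for r in records],
            "r_cond1": [r.r1 for r in records],
            "r_cond2": [r.r2 for r in records],
            "p_diff": [r.p_diff for r in records],
            "lfdr": [r.lfdr for r in records],
            "sign_switch": ["true" if r.switched else "false" for r in records],
        },
        columns=list(EDGE_TSV_COLUMNS),
    )


def write_network(records: Sequence[DiffCorrRecord], path: str | Path,
                  format: str = "edge_tsv") -> None:
    """Export differential-correlation pairs as an edge table or GraphML.

    The edge TSV column order is fixed (source, target, r_cond1, r_cond2,
    p_diff, lfdr, sign_switch); the GraphML carries the same six edge
    attributes so the network imports cleanly into Cytoscape-class viewers.
    """
    records = list(records)
    if format == "edge_tsv":
        _records_frame(records).to_csv(path, sep="\t", index=False,
                                       float_format="%.10g")
    elif format == "graphml":
        if not records:
            raise ValueError("cannot write GraphML for an empty record list")
        graph = nx.Graph()
        for r in records:
            graph.add_edge(
                r.gene_a, r.gene_b,
                r_cond1=float(r.r1), r_cond2=float(r.r2),
                p_diff=float(r.p_diff), lfdr=float(r.lfdr),
                sign_switch=bool(r.switched),
            )
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown network format {format!r}")
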