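"""COG functional-category profiling: counts, transforms, clustered heatmaps."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "COG_CATEGORIES",
    "CategoryCounts",
    "TransformedMatrix",
    "HeatmapResult",
    "count_categories",
    "relative_proportions",
    "not_in_cogs_percent",
    "build_count_matrix",
    "transform_arcsine_sqrt",
    "transform_log_counts",
    "transform_matrix",
    "cluster_heatmap",
    "read_gene_table",
]

#: canonical order of the 25 single-letter COG functional categories
COG_CATEGORIES: tuple[str, ...] = tuple("JAKLBDYVTMNZWUOCGEFHIPQRS")

_VALID = frozenset(COG_CATEGORIES)
_SEPARATORS = str.maketrans("", "", ";, ")


@dataclass(frozen=True)
class CategoryCounts:
    """Per-category assignment counts for one genome.

    ``counts`` has one entry per category in canonical order; a gene with
    k assignments contributes k counts.  ``not_in_cogs`` tallies genes
    without any assignment; ``n_genes`` is the number of table rows.
    """

    counts: pd.Series
    not_in_cogs: int
    n_genes: int


@dataclass(frozen=True)
class TransformedMatrix:
    """A genomes x categories matrix after a variance-stabilizing transform."""

    values: pd.DataFrame
    transform_tag: str


@dataclass(frozen=True)
class HeatmapResult:
    """Row/column leaf orders and linkages of a two-way clustered matrix."""

    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def _parse_assignments(raw: object, gene_id: object) -> str:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return ""
    letters = str(raw).strip().translate(_SEPARATORS).upper()
    bad = set(letters) - _VALID
    if bad:
        raise ValueError(
            f"unknown COG category letter(s) {sorted(bad)} in row for gene "
            f"{gene_id!r}"
        )
    return letters


def count_categories(gene_table: pd.DataFrame) -> CategoryCounts:
    """Tally category assignments from a per-gene table.

    The table needs ``gene_id`` and ``categories`` columns; the latter
    holds concatenated (optionally ``;``/``,``-separated) single-letter
    codes, empty for genes outside all categories.
    """
    counts = dict.fromkeys(COG_CATEGORIES, 0)
    not_in_cogs = 0
    for gene_id, raw in zip(gene_table["gene_id"], gene_table["categories"]):
        letters = _parse_assignments(raw, gene_id)
        if not letters:
            not_in_cogs += 1
            continue
        for letter in letters:
            counts[letter] += 1
    series = pd.Series(counts, index=list(COG_CATEGORIES), dtype=int)
    return CategoryCounts(
        counts=series, not_in_cogs=not_in_cogs, n_genes=len(gene_table)
    )


def relative_proportions(counts: pd.Series | CategoryCounts) -> pd.Series:
    """Per-category proportions of the summed category assignments.

    The denominator is the sum over the 25 categories (multi-assigned
    genes count once per assignment); genes outside all categories are
    excluded — see :func:`not_in_cogs_percent` for that share.
    """
    if isinstance(counts, CategoryCounts):
        counts = counts.counts
    counts = counts.reindex(list(COG_CATEGORIES)).astype(float)
    total = counts.sum()
    if not total > 0:
        raise ValueError("cannot normalize an all-zero category count vector")
    return counts / total


def not_in_cogs_percent(counts: CategoryCounts) -> float:
    """Percentage of genes without any category assignment, of all genes."""
    if counts.n_genes <= 0:
        raise ValueError("gene table is empty")
    return 100.0 * counts.not_in_cogs / counts.n_genes


def build_count_matrix(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-genome gene tables into a genomes x categories count matrix."""
    rows = {
        label: count_categories(table).counts for label, table in tables.items()
    }
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    matrix = matrix[list(COG_CATEGORIES)]
    matrix.index.name = "genome"
    return matrix


def transform_arcsine_sqrt(p):
    """Arcsine-square-root transform of proportions: asin(sqrt(p)), radians."""
    arr = np.asarray(p, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return out if arr.ndim else float(out)


def transform_log_counts(count):
    """Log transform of non-negative counts: ln(count + 1)."""
    arr = np.asarray(count, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    out = np.log1p(arr)
    return out if arr.ndim else float(out)


def transform_matrix(matrix: pd.DataFrame, method: str) -> TransformedMatrix:
    """Apply the chosen transform to a count matrix.

    ``arcsine_sqrt`` first converts each row to proportions of its
    summed category counts; ``log`` transforms the absolute counts.
    """
    if method == "arcsine_sqrt":
        props = matrix.apply(lambda row: relative_proportions(row), axis=1)
        values = props.apply(lambda row: np.arcsin(np.sqrt(row)), axis=1)
    elif method == "log":
        values = matrix.astype(float).apply(np.log1p)
    else:
        raise ValueError(f"unknown transform {method!r}")
    return TransformedMatrix(values=values, transform_tag=method)


def cluster_heatmap(
    matrix: TransformedMatrix | pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
    out_path: str | None = None,
) -> HeatmapResult:
    """Cluster rows and columns of a transformed matrix; optionally render.

    Both axes are clustered with the given distance metric and linkage
    (Euclidean/UPGMA by default).  When ``out_path`` is given, a heatmap
    with marginal dendrograms is written there (format by extension).
    """
    values = matrix.values if isinstance(matrix, TransformedMatrix) else matrix
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")
    if values.isna().any().any():
        raise ValueError("matrix contains missing values")

    data = values.to_numpy(dtype=float)
    row_linkage = linkage(pdist(data, metric=metric), method=method)
    col_linkage = linkage(pdist(data.T, metric=metric), method=method)
    row_order = [values.index[i] for i in leaves_list(row_linkage)]
    col_order = [values.columns[i] for i in leaves_list(col_linkage)]

    if out_path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import seaborn as sns

        matplotlib.rcParams["svg.hashsalt"] = "spirotax"
        grid = sns.clustermap(
            values,
            row_linkage=row_linkage,
            col_linkage=col_linkage,
            cmap="viridis",
            figsize=(10, max(4, 0.4 * values.shape[0])),
        )
        grid.savefig(out_path, metadata=_figure_metadata(out_path))
        import matplotlib.pyplot as plt

        plt.close(grid.figure)

    return HeatmapResult(
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_linkage,
        col_linkage=col_linkage,
    )


def _figure_metadata(path: str) -> dict | None:
    # strip the volatile creation date so identical runs give identical bytes
    if str(path).endswith(".svg"):
        return {"Date": None}
    return None


def read_gene_table(path) -> pd.DataFrame:
    """Read a tab-separated gene table (columns: gene_id, categories)."""
    table = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "categories": str}
    )
    if "gene_id" not in table.columns or "categories" not in table.columns:
        raise ValueError(
            f"{path}: expected columns 'gene_id' and 'categories', "
            f"found {list(table.columns)}"
        )
    table["categories"] = table["categories"].fillna("")
    return table
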