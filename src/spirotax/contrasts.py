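"""Felsenstein phylogenetically independent contrasts and trait correlations.

Contrasts are computed by the standard pruning recursion: at each
internal node joining children with values x_i, x_j on (extended) branch
lengths v_i, v_j, the standardized contrast is (x_i - x_j)/sqrt(v_i+v_j),
the node is assigned the inverse-variance weighted mean of its children,
and its parent branch is extended by v_i*v_j/(v_i+v_j).

Contrast correlation is computed through the origin (contrast signs are
arbitrary) with n-1 degrees of freedom; raw trait correlation is the
centered Pearson coefficient with n-2 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastSet",
    "CorrelationResult",
    "InsufficientDataError",
    "independent_contrasts",
    "independent_contrasts_table",
    "contrast_correlation",
    "raw_correlation",
]

#: zero/near-zero branches are replaced by this fraction of the tree height
_EPSILON_FRACTION = 1e-8


class InsufficientDataError(ValueError):
    """Raised when too few observations are available for a statistic."""


@dataclass(frozen=True)
class ContrastSet:
    """Standardized contrasts of one trait on a bifurcating rooted tree."""

    values: np.ndarray
    variances: np.ndarray
    node_ids: tuple[str, ...]
    root_value: float

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation coefficient with its two-sided significance."""

    r: float
    p: float
    n: int
    mode: str


def _prepare_tree(tree: dendropy.Tree) -> dendropy.Tree:
    """Clone, resolve polytomies, and floor non-positive branch lengths."""
    work = tree.clone(depth=1)
    work.resolve_polytomies(limit=2, update_bipartitions=False)
    height = max(
        (leaf.distance_from_root() for leaf in work.leaf_node_iter()),
        default=0.0,
    )
    eps = _EPSILON_FRACTION * height if height > 0 else _EPSILON_FRACTION
    for edge in work.preorder_edge_iter():
        if edge.head_node is work.seed_node:
            continue
        if edge.length is None or edge.length <= 0:
            edge.length = eps
    return work


def _check_labels(tree: dendropy.Tree, values: Mapping[str, float]) -> None:
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    table_labels = set(values)
    missing = sorted(leaf_labels - table_labels)
    extra = sorted(table_labels - leaf_labels)
    if missing or extra:
        raise ValueError(
            "trait table does not match tree leaves; "
            f"leaves without trait values: {missing}; "
            f"trait rows without leaves: {extra}"
        )


def _contrasts_on_prepared(
    tree: dendropy.Tree, values: Mapping[str, float]
) -> ContrastSet:
    node_value: dict[dendropy.Node, float] = {}
    # branch length of each node's edge plus its pruning extension
    branch: dict[dendropy.Node, float] = {}

    contrasts: list[float] = []
    variances: list[float] = []
    node_ids: list[str] = []
    counter = 0

    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node_value[node] = float(values[node.taxon.label])
            branch[node] = node.edge.length
            continue
        children = node.child_nodes()
        if len(children) != 2:  # pragma: no cover - guarded by _prepare_tree
            raise ValueError("tree must be bifurcating after polytomy resolution")
        c1, c2 = children
        v1, v2 = branch[c1], branch[c2]
        x1, x2 = node_value[c1], node_value[c2]
        contrasts.append((x1 - x2) / math.sqrt(v1 + v2))
        variances.append(v1 + v2)
        counter += 1
        node_ids.append(f"node{counter}")
        node_value[node] = (x1 / v1 + x2 / v2) / (1.0 / v1 + 1.0 / v2)
        extension = v1 * v2 / (v1 + v2)
        branch[node] = (node.edge.length or 0.0) + extension

    return ContrastSet(
        values=np.asarray(contrasts),
        variances=np.asarray(variances),
        node_ids=tuple(node_ids),
        root_value=node_value[tree.seed_node],
    )


def independent_contrasts(
    tree: dendropy.Tree, values: Mapping[str, float]
) -> ContrastSet:
    """Compute standardized independent contrasts for one trait.

    ``values`` maps leaf labels to trait values and must cover the tree's
    leaves exactly.  Polytomies are resolved arbitrarily with near-zero
    branches; a tree with n leaves yields n - 1 contrasts.
    """
    _check_labels(tree, values)
    prepared = _prepare_tree(tree)
    return _contrasts_on_prepared(prepared, values)


def independent_contrasts_table(
    tree: dendropy.Tree, traits: pd.DataFrame
) -> pd.DataFrame:
    """Contrasts for every trait column, aligned on the same resolved tree.

    Returns a data frame indexed by internal-node id with one column per
    trait plus the shared ``variance`` column.
    """
    for column in traits.columns:
        _check_labels(tree, traits[column].to_dict())
    prepared = _prepare_tree(tree)
    out: dict[str, np.ndarray] = {}
    variances = None
    node_ids = None
    for column in traits.columns:
        cs = _contrasts_on_prepared(prepared, traits[column].to_dict())
        out[column] = cs.values
        variances = cs.variances
        node_ids = cs.node_ids
    frame = pd.DataFrame(out, index=pd.Index(node_ids, name="node"))
    frame["variance"] = variances
    return frame


def _as_array(contrasts) -> np.ndarray:
    if isinstance(contrasts, ContrastSet):
        return contrasts.values
    return np.asarray(contrasts, dtype=float)


def contrast_correlation(cs_x, cs_y) -> CorrelationResult:
    """Correlation of two contrast sets, through the origin.

    r = sum(x*y) / sqrt(sum(x^2) * sum(y^2)); the two-sided p-value uses
    t = r * sqrt((n-1) / (1-r^2)) with n - 1 degrees of freedom.
    """
    x = _as_array(cs_x)
    y = _as_array(cs_y)
    if x.shape != y.shape:
        raise ValueError("contrast sets must have equal length")
    n = len(x)
    if n < 3:
        raise InsufficientDataError(
            f"need at least 3 contrasts, got {n}"
        )
    sxx = float(np.dot(x, x))
    syy = float(np.dot(y, y))
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("contrast correlation undefined for all-zero contrasts")
    r = float(np.dot(x, y) / math.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    df = n - 1
    if 1.0 - r * r <= 0.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return CorrelationResult(r=r, p=p, n=n, mode="contrasts")


def raw_correlation(trait_x, trait_y) -> CorrelationResult:
    """Centered Pearson correlation of two per-leaf trait vectors."""
    x = np.asarray(trait_x, dtype=float)
    y = np.asarray(trait_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("trait vectors must have equal length")
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 observations, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(np.dot(xc, xc))
    syy = float(np.dot(yc, yc))
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("correlation undefined for a zero-variance trait")
    r = float(np.dot(xc, yc) / math.sqrt(sxx * syy))
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if 1.0 - r * r <= 0.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return CorrelationResult(r=r, p=p, n=n, mode="raw")
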