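"""Synthetic input generators for every pipeline stage.

All generators take explicit seeds and produce byte-identical output for
a fixed seed.  They create the statistical structure the downstream
analyses assume: genome pairs with planted conserved segments of known
coverage and identity, pure-birth (Yule) trees, bivariate correlated
Brownian-motion traits, and multinomial COG gene tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cog import COG_CATEGORIES

__all__ = [
    "GenomePairSpec",
    "TraitSimSpec",
    "CogProfileSpec",
    "MIN_SEGMENT_LENGTH",
    "simulate_tree",
    "simulate_correlated_traits",
    "simulate_genome_pair",
    "simulate_cog_table",
]

#: shortest conserved segment the genome-pair generator will plant
MIN_SEGMENT_LENGTH = 50

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GenomePairSpec:
    """Parameters for a pair of genomes with planted conserved segments."""

    ancestor_length: int
    alignable_fraction: float
    within_identity: float
    n_segments: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ancestor_length <= 0:
            raise ValueError("ancestor_length must be positive")
        if not 0.0 <= self.alignable_fraction <= 1.0:
            raise ValueError("alignable_fraction must be in [0, 1]")
        if not 0.0 <= self.within_identity <= 1.0:
            raise ValueError("within_identity must be in [0, 1]")
        total = self.total_alignable
        if total > 0:
            if self.n_segments < 1:
                raise ValueError(
                    "n_segments must be >= 1 when alignable_fraction > 0"
                )
            if total < self.n_segments * MIN_SEGMENT_LENGTH:
                raise ValueError(
                    f"infeasible segment packing: {total} alignable bases "
                    f"cannot hold {self.n_segments} segments of >= "
                    f"{MIN_SEGMENT_LENGTH} bp"
                )

    @property
    def total_alignable(self) -> int:
        return int(round(self.ancestor_length * self.alignable_fraction))


@dataclass(frozen=True)
class TraitSimSpec:
    """Parameters of a bivariate Brownian-motion trait simulation."""

    sigma_x: float = 1.0
    sigma_y: float = 1.0
    rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigma_x and sigma_y must be positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")


@dataclass(frozen=True)
class CogProfileSpec:
    """Per-group category profiles used to draw synthetic gene tables.

    ``multi_assignment_rate`` is the expected number of *extra* category
    assignments per assigned gene (Poisson distributed), reproducing
    annotations where summed category counts exceed the number of genes
    assigned to any category.  ``assigned_fraction`` is the probability
    that a gene carries at least one assignment at all.
    """

    group_profiles: Mapping[str, Sequence[float]]
    n_genes_range: tuple[int, int] = (1000, 3000)
    multi_assignment_rate: float = 0.0
    assigned_fraction: float = 1.0

    def __post_init__(self) -> None:
        for group, profile in self.group_profiles.items():
            p = np.asarray(profile, dtype=float)
            if p.shape != (len(COG_CATEGORIES),):
                raise ValueError(
                    f"profile for group {group!r} must have "
                    f"{len(COG_CATEGORIES)} components"
                )
            if (p < 0).any():
                raise ValueError(f"profile for group {group!r} has negative mass")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"profile for group {group!r} does not sum to 1")
        lo, hi = self.n_genes_range
        if lo < 1 or hi < lo:
            raise ValueError("n_genes_range must be a non-empty positive interval")
        if self.multi_assignment_rate < 0:
            raise ValueError("multi_assignment_rate must be >= 0")
        if not 0.0 <= self.assigned_fraction <= 1.0:
            raise ValueError("assigned_fraction must be in [0, 1]")


def simulate_tree(
    n_taxa: int, birth_rate: float = 1.0, seed: int | None = None
) -> dendropy.Tree:
    """Simulate a rooted ultrametric pure-birth (Yule) tree.

    The root splits at time zero; with ``k`` extant lineages the waiting
    time to the next split is exponential with rate ``k * birth_rate``.
    After the ``n_taxa``-th lineage appears the tree is grown for one
    more exponential waiting time, so the expected root-to-tip depth is
    ``sum(1 / (k * birth_rate) for k in 2..n_taxa)``.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node

    birth_time: dict[dendropy.Node, float] = {}
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = root.new_child()
        birth_time[child] = 0.0
        active.append(child)

    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        node = active[idx]
        node.edge.length = t - birth_time[node]
        left = node.new_child()
        right = node.new_child()
        birth_time[left] = t
        birth_time[right] = t
        active[idx] = left
        active.append(right)

    t += rng.exponential(1.0 / (n_taxa * birth_rate))
    for node in active:
        node.edge.length = t - birth_time[node]

    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tns.require_taxon(label=f"t{i + 1}")
    return tree


def _covariance_factor(spec: TraitSimSpec) -> np.ndarray:
    """Matrix square root of the per-unit-branch trait covariance.

    Uses an eigendecomposition so degenerate cases (|rho| = 1) are exact.
    """
    c = spec.rho * spec.sigma_x * spec.sigma_y
    cov = np.array([[spec.sigma_x**2, c], [c, spec.sigma_y**2]])
    eigval, eigvec = np.linalg.eigh(cov)
    eigval = np.clip(eigval, 0.0, None)
    return eigvec @ np.diag(np.sqrt(eigval))


def simulate_correlated_traits(
    tree: dendropy.Tree, spec: TraitSimSpec
) -> pd.DataFrame:
    """Evolve two correlated Brownian traits down a rooted tree.

    Returns a data frame indexed by leaf label with columns ``trait_x``
    and ``trait_y``.  Increments on each branch are bivariate normal with
    covariance ``rho * sigma_x * sigma_y * branch_length``.
    """
    rng = np.random.default_rng(spec.seed)
    factor = _covariance_factor(spec)

    state: dict[dendropy.Node, np.ndarray] = {}
    rows: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state[node] = np.zeros(2)
        else:
            bl = node.edge.length
            if bl is None or bl <= 0:
                raise ValueError(
                    "every branch length must be positive for Brownian simulation"
                )
            z = rng.standard_normal(2)
            state[node] = state[node.parent_node] + np.sqrt(bl) * (factor @ z)
        if node.is_leaf():
            rows[node.taxon.label] = state[node]

    frame = pd.DataFrame.from_dict(rows, orient="index", columns=["trait_x", "trait_y"])
    frame.index.name = "taxon"
    return frame


def _segment_layout(
    rng: np.random.Generator, length: int, total_alignable: int, n_segments: int
) -> list[tuple[int, int]]:
    """Place n non-overlapping segments summing to total_alignable bases."""
    if total_alignable == 0 or n_segments == 0:
        return []
    base = total_alignable // n_segments
    seg_lengths = np.full(n_segments, base, dtype=int)
    seg_lengths[: total_alignable % n_segments] += 1
    free = length - total_alignable
    gaps = rng.multinomial(free, np.full(n_segments + 1, 1.0 / (n_segments + 1)))
    segments = []
    pos = 0
    for gap, seg_len in zip(gaps[:-1], seg_lengths):
        pos += int(gap)
        segments.append((pos, pos + int(seg_len)))
        pos += int(seg_len)
    return segments


def simulate_genome_pair(
    spec: GenomePairSpec,
) -> tuple[SeqRecord, SeqRecord, pd.DataFrame]:
    """Simulate two genomes sharing planted conserved segments.

    Genome A is the ancestor; genome B carries the conserved segments at
    the same coordinates with independent per-site substitution at rate
    ``1 - within_identity`` (substituted sites always change base), and
    is independently random elsewhere.  The returned truth table lists
    the planted intervals (0-based half-open) and their realized
    per-segment identities.
    """
    rng = np.random.default_rng(spec.seed)
    length = spec.ancestor_length

    a = rng.integers(0, 4, size=length).astype(np.uint8)
    b = rng.integers(0, 4, size=length).astype(np.uint8)

    segments = _segment_layout(rng, length, spec.total_alignable, spec.n_segments)
    records = []
    for start, end in segments:
        copied = a[start:end].copy()
        mutated = rng.random(end - start) < (1.0 - spec.within_identity)
        if mutated.any():
            shift = rng.integers(1, 4, size=int(mutated.sum())).astype(np.uint8)
            copied[mutated] = (copied[mutated] + shift) % 4
        b[start:end] = copied
        records.append(
            {
                "a_start": start,
                "a_end": end,
                "b_start": start,
                "b_end": end,
                "identity": 1.0 - float(mutated.mean()),
            }
        )

    truth = pd.DataFrame(
        records, columns=["a_start", "a_end", "b_start", "b_end", "identity"]
    )
    seq_a = _BASES[a].tobytes().decode("ascii")
    seq_b = _BASES[b].tobytes().decode("ascii")
    rec_a = SeqRecord(Seq(seq_a), id="genomeA", description="synthetic ancestor")
    rec_b = SeqRecord(Seq(seq_b), id="genomeB", description="synthetic derived")
    return rec_a, rec_b, truth


def truth_summary(truth: pd.DataFrame, length: int) -> tuple[float, float]:
    """Realized (coverage, identity) of a planted-segment truth table."""
    if truth.empty:
        return 0.0, 0.0
    seg_lengths = (truth["a_end"] - truth["a_start"]).to_numpy(dtype=float)
    coverage = seg_lengths.sum() / length
    identity = float((truth["identity"] * seg_lengths).sum() / seg_lengths.sum())
    return coverage, identity


def simulate_cog_table(
    spec: CogProfileSpec, group: str, seed: int | None = None
) -> pd.DataFrame:
    """Draw a synthetic gene table with COG category assignments.

    Returns a data frame with columns ``gene_id`` and ``categories``
    (concatenated single-letter codes; empty string for unassigned
    genes).  Categories per gene are distinct; the number of extra
    assignments beyond the first is Poisson(``multi_assignment_rate``).
    """
    if group not in spec.group_profiles:
        raise KeyError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    profile = np.asarray(spec.group_profiles[group], dtype=float)
    profile = profile / profile.sum()
    n_nonzero = int((profile > 0).sum())

    lo, hi = spec.n_genes_range
    n_genes = int(rng.integers(lo, hi + 1))

    assigned = rng.random(n_genes) < spec.assigned_fraction
    extra = rng.poisson(spec.multi_assignment_rate, size=n_genes)

    cats = np.array(list(COG_CATEGORIES))
    primary = rng.choice(len(COG_CATEGORIES), size=n_genes, p=profile)

    categories = []
    for i in range(n_genes):
        if not assigned[i]:
            categories.append("")
            continue
        k = 1 + min(int(extra[i]), n_nonzero - 1)
        if k == 1:
            categories.append(cats[primary[i]])
        else:
            chosen = rng.choice(len(COG_CATEGORIES), size=k, replace=False, p=profile)
            categories.append("".join(cats[sorted(chosen)]))
    return pd.DataFrame(
        {
            "gene_id": [f"{group}_g{i:06d}" for i in range(n_genes)],
            "categories": categories,
        }
    )
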