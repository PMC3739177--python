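"""Shared fixtures and independent oracles for the test suite.

The oracle implementations here deliberately avoid the package's own
code paths: HSP discovery is checked against an exhaustive
maximal-scoring-segment scan plus optimal interval scheduling, and
independent contrasts are checked against GLS whitening with the
explicit Brownian covariance matrix.
"""

from __future__ import annotations

import numpy as np
import pytest

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length: int, alphabet: str = "ACGT") -> str:
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(0, len(letters), size=length)])


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# HSP oracle: exhaustive per-diagonal dynamic programming for the optimal
# set of disjoint ungapped segments, each scoring >= min_score.  Completely
# independent of the package's seed-and-extend implementation.
# ---------------------------------------------------------------------------

def _kadane_max(scores) -> int:
    best = cur = 0
    for s in scores:
        cur = max(0, cur + s)
        best = max(best, cur)
    return best


def _optimal_pieces(scores, min_score):
    """Optimal disjoint contiguous pieces of a score sequence.

    Every piece must score >= min_score; returns (total, [(start, end,
    score), ...]).  O(n^2) exhaustive DP with traceback.
    """
    n = len(scores)
    prefix = [0] * (n + 1)
    for i, s in enumerate(scores):
        prefix[i + 1] = prefix[i] + s
    best = [0] * (n + 1)
    back = [None] * (n + 1)  # (j, piece score) when a piece [j, i) is taken
    for i in range(1, n + 1):
        best[i] = best[i - 1]
        for j in range(i):
            score = prefix[i] - prefix[j]
            if score >= min_score and best[j] + score > best[i]:
                best[i] = best[j] + score
                back[i] = (j, score)
    pieces = []
    i = n
    while i > 0:
        if back[i] is not None and best[i] != best[i - 1]:
            j, score = back[i]
            pieces.append((j, i, score))
            i = j
        else:
            i -= 1
    pieces.reverse()
    return best[n], pieces


def brute_force_optimal_cover(sa: str, sb: str, min_score: int,
                              match: int = 1, mismatch: int = -1):
    """Optimal non-overlapping (on A) segment-cover score and pieces.

    Scans every diagonal of both strands; diagonals whose best single
    segment (no threshold) stays below min_score cannot contribute and
    are skipped.  Pieces from different diagonals are assumed disjoint
    on genome A (asserted), which holds for the planted constructions
    used in the tests.
    """
    pieces = []
    la, lb = len(sa), len(sb)
    for strand, sbx in (("+", sb), ("-", revcomp(sb))):
        for diag in range(-(lb - 1), la):
            a0 = max(0, diag)
            b0 = a0 - diag
            length = min(la - a0, lb - b0)
            if length < min_score:
                continue
            scores = [
                match
                if sa[a0 + k] == sbx[b0 + k] and sa[a0 + k] in "ACGT"
                else mismatch
                for k in range(length)
            ]
            if _kadane_max(scores) < min_score:
                continue
            _total, diag_pieces = _optimal_pieces(scores, min_score)
            pieces += [
                (a0 + start, a0 + end, strand, score)
                for start, end, score in diag_pieces
            ]
    pieces.sort()
    for prev, cur in zip(pieces, pieces[1:]):
        assert cur[0] >= prev[1], "oracle assumes pieces disjoint on genome A"
    return sum(p[3] for p in pieces), pieces


# ---------------------------------------------------------------------------
# GLS whitening oracle for independent contrasts
# ---------------------------------------------------------------------------

def brownian_covariance(tree, labels):
    """Shared root-to-MRCA path lengths between leaves (Brownian covariance)."""
    pdm = tree.phylogenetic_distance_matrix()
    depth = {
        leaf.taxon.label: leaf.distance_from_root()
        for leaf in tree.leaf_node_iter()
    }
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    cov = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                cov[i, j] = depth[a]
            else:
                d = pdm.patristic_distance(taxa[a], taxa[b])
                cov[i, j] = 0.5 * (depth[a] + depth[b] - d)
    return cov


def gls_cross_product(tree, values_x: dict, values_y: dict) -> float:
    """(x - mu_x 1)' C^-1 (y - mu_y 1) with GLS root estimates mu."""
    labels = sorted(values_x)
    cov = brownian_covariance(tree, labels)
    cov_inv = np.linalg.inv(cov)
    one = np.ones(len(labels))
    x = np.array([values_x[label] for label in labels])
    y = np.array([values_y[label] for label in labels])
    mu_x = (one @ cov_inv @ x) / (one @ cov_inv @ one)
    mu_y = (one @ cov_inv @ y) / (one @ cov_inv @ one)
    return float((x - mu_x * one) @ cov_inv @ (y - mu_y * one))
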