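"""Score-weighted profiling of 16S rRNA hit tables.

Summarizes a BLAST-style tabular hit file the way marker-gene surveys
report it: bit-score-weighted genus frequencies, bit-score-weighted
stemmed-keyword frequencies from hit descriptions, mean within-HSP
identity and mean query coverage, plus pairwise mismatch counts between
aligned gene copies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._porter import stem as porter_stem

__all__ = [
    "Hit",
    "WeightedFrequencyReport",
    "HspSummary",
    "EmptyReportError",
    "OUTFMT6_COLUMNS",
    "read_hit_table",
    "weighted_taxon_frequencies",
    "weighted_keyword_frequencies",
    "hsp_summary",
    "pairwise_differences",
    "merge_intervals",
]

#: the 12 standard tabular alignment columns (BLAST outfmt 6 compatible)
OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

#: minimal English stopword list for description tokenization
STOPWORDS = frozenset(
    """a an and are as at be but by for from has have in into is it its of on
    or that the their this to was were which with within""".split()
)

_MIN_TOKEN_LENGTH = 3
_TOKEN_RE = re.compile(r"[a-z]+")
_QUOTES = "\"'“”‘’[]"
_ACGT = frozenset("ACGT")


class EmptyReportError(ValueError):
    """Raised when no hit carries the information needed for a report."""


@dataclass(frozen=True)
class Hit:
    """One query-subject hit, possibly spanning several HSPs.

    ``intervals`` are the HSP ranges on the query, 0-based half-open;
    ``identity`` is the HSP-length-weighted mean percent identity and
    ``bit_score`` the best HSP bit score of the hit.
    """

    query_id: str
    subject_id: str
    bit_score: float
    identity: float
    intervals: tuple[tuple[int, int], ...]
    taxon: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.bit_score <= 0:
            raise ValueError("bit score must be positive")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must lie in [0, 100]")


@dataclass(frozen=True)
class WeightedFrequencyReport:
    """Score-weighted relative frequencies over genera or keyword stems."""

    frequencies: pd.Series
    total_weight: float
    n_hits: int


@dataclass(frozen=True)
class HspSummary:
    """Unweighted per-hit means of HSP identity and query coverage (%)."""

    mean_identity: float
    mean_coverage: float
    n_hits: int


def read_hit_table(path, annotations: Mapping[str, tuple[str, str]] | None = None
                   ) -> list[Hit]:
    """Parse a 12-column tabular hit file into per-subject hits.

    Rows sharing (query, subject) are merged into one hit: the best row
    bit score becomes the hit score, identities are averaged weighted by
    HSP length, and every HSP interval on the query is retained.
    ``annotations`` optionally maps subject id to (taxon label,
    description).
    """
    table = pd.read_csv(
        path, sep="\t", header=None, names=list(OUTFMT6_COLUMNS), comment="#"
    )
    hits: list[Hit] = []
    for (qseqid, sseqid), rows in table.groupby(
        ["qseqid", "sseqid"], sort=False
    ):
        taxon, description = "", ""
        if annotations and str(sseqid) in annotations:
            taxon, description = annotations[str(sseqid)]
        lengths = rows["length"].to_numpy(dtype=float)
        identity = float(
            (rows["pident"].to_numpy(dtype=float) * lengths).sum() / lengths.sum()
        )
        intervals = tuple(
            (int(qs) - 1, int(qe)) for qs, qe in zip(rows["qstart"], rows["qend"])
        )
        hits.append(
            Hit(
                query_id=str(qseqid),
                subject_id=str(sseqid),
                bit_score=float(rows["bitscore"].max()),
                identity=identity,
                intervals=intervals,
                taxon=taxon,
                description=description,
            )
        )
    return hits


def read_annotations(path) -> dict[str, tuple[str, str]]:
    """Read a subject-annotation table (subject_id, taxon, description)."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"subject_id", "taxon", "description"}
    if not required.issubset(table.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(table.columns)}"
        )
    return {
        row.subject_id: (row.taxon, row.description)
        for row in table.itertuples(index=False)
    }


def _genus(taxon: str) -> str:
    token = taxon.strip().strip(_QUOTES).split()
    return token[0].strip(_QUOTES) if token else ""


def weighted_taxon_frequencies(hits: Sequence[Hit]) -> WeightedFrequencyReport:
    """Bit-score-weighted relative frequencies of subject genera.

    Each genus accumulates the bit scores of its hits; frequencies are
    those sums over the total bit score of all hits with a parseable
    genus.
    """
    weights: dict[str, float] = {}
    n_used = 0
    for hit in hits:
        genus = _genus(hit.taxon)
        if not genus:
            continue
        weights[genus] = weights.get(genus, 0.0) + hit.bit_score
        n_used += 1
    if not weights:
        raise EmptyReportError("no hit has a parseable genus label")
    total = sum(weights.values())
    series = pd.Series(
        {genus: w / total for genus, w in weights.items()}, name="frequency"
    ).sort_values(ascending=False, kind="stable")
    series.index.name = "genus"
    return WeightedFrequencyReport(
        frequencies=series, total_weight=total, n_hits=n_used
    )


def tokenize_description(description: str) -> set[str]:
    """Lowercase, split on non-alphabetic runs, drop short tokens and
    stopwords, Porter-stem, and de-duplicate stems within the text."""
    stems = set()
    for token in _TOKEN_RE.findall(description.lower()):
        if len(token) < _MIN_TOKEN_LENGTH or token in STOPWORDS:
            continue
        stems.add(porter_stem(token))
    return stems


def weighted_keyword_frequencies(hits: Sequence[Hit]) -> WeightedFrequencyReport:
    """Bit-score-weighted relative frequencies of description keyword stems.

    Each distinct stem in a hit's description contributes that hit's bit
    score once; frequencies are normalized over the total contributed
    stem weight, so they sum to one.
    """
    weights: dict[str, float] = {}
    n_used = 0
    for hit in hits:
        stems = tokenize_description(hit.description)
        if not stems:
            continue
        n_used += 1
        for s in stems:
            weights[s] = weights.get(s, 0.0) + hit.bit_score
    if not weights:
        raise EmptyReportError("no hit has a tokenizable description")
    total = sum(weights.values())
    series = pd.Series(
        {s: w / total for s, w in weights.items()}, name="frequency"
    ).sort_values(ascending=False, kind="stable")
    series.index.name = "stem"
    return WeightedFrequencyReport(
        frequencies=series, total_weight=total, n_hits=n_used
    )


def merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Union of 0-based half-open intervals, sorted and merged."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def hsp_summary(hits: Sequence[Hit], query_length: int) -> HspSummary:
    """Mean within-HSP identity and mean merged-HSP query coverage, in %."""
    if query_length <= 0:
        raise ValueError("query_length must be positive")
    if not hits:
        raise EmptyReportError("no hits to summarize")
    identities = []
    coverages = []
    for hit in hits:
        for start, end in hit.intervals:
            if start < 0 or end > query_length:
                raise ValueError(
                    f"HSP interval ({start}, {end}) exceeds query length "
                    f"{query_length}"
                )
        covered = sum(end - start for start, end in merge_intervals(hit.intervals))
        coverages.append(100.0 * covered / query_length)
        identities.append(hit.identity)
    return HspSummary(
        mean_identity=float(np.mean(identities)),
        mean_coverage=float(np.mean(coverages)),
        n_hits=len(hits),
    )


def pairwise_differences(sequences: Mapping[str, str]) -> pd.DataFrame:
    """Pairwise mismatch counts between aligned equal-length sequences.

    Positions where either sequence carries a gap or ambiguity character
    (anything outside ACGT) are excluded and never counted as
    differences.
    """
    labels = list(sequences)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    seqs = {label: str(sequences[label]).upper() for label in labels}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(
            "sequences must be pre-aligned to equal length; "
            f"found lengths {sorted(lengths)}"
        )
    arrays = {
        label: np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        for label, s in seqs.items()
    }
    valid = {
        label: np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
        for label, arr in arrays.items()
    }
    matrix = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for i, li in enumerate(labels):
        for lj in labels[i + 1 :]:
            comparable = valid[li] & valid[lj]
            diffs = int(((arrays[li] != arrays[lj]) & comparable).sum())
            matrix.loc[li, lj] = diffs
            matrix.loc[lj, li] = diffs
    return matrix
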