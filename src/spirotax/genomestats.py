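"""Genome summary statistics: G+C content, coding density, gene classes."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Feature",
    "FEATURE_CLASSES",
    "gc_content",
    "coding_density",
    "gene_class_breakdown",
    "class_percentages",
    "summary_from_counts",
    "read_genbank",
    "read_fasta_lengths",
    "read_feature_table",
]

#: recognized feature classes, in report order
FEATURE_CLASSES = ("CDS", "rRNA", "tRNA", "other_RNA", "pseudo")

_RNA_CLASSES = ("rRNA", "tRNA", "other_RNA")
_OTHER_RNA_TYPES = frozenset({"ncRNA", "tmRNA", "misc_RNA"})

# Upper-case bases counted toward G+C. S (G or C) counts fully; other
# ambiguity codes are excluded from the numerator only, the denominator
# is always the full sequence length.
_GC_BASES = frozenset("GCS")


@dataclass(frozen=True)
class Feature:
    """One annotated feature with a 0-based half-open interval."""

    type: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.type not in FEATURE_CLASSES:
            raise ValueError(
                f"feature type {self.type!r} not in {FEATURE_CLASSES}"
            )
        if not 0 <= self.start < self.end:
            raise ValueError("feature interval must be non-empty and 0-based")


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def gc_content(sequence) -> tuple[int, float]:
    """(G+C base count, G+C fraction of the full sequence length)."""
    seq = str(getattr(sequence, "seq", sequence)).upper()
    if not seq:
        raise ValueError("empty sequence")
    gc = sum(1 for c in seq if c in _GC_BASES)
    return gc, gc / len(seq)


def _merged_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    current_start = current_end = None
    for start, end in sorted(intervals):
        if current_end is None or start > current_end:
            if current_end is not None:
                total += current_end - current_start
            current_start, current_end = start, end
        else:
            current_end = max(current_end, end)
    if current_end is not None:
        total += current_end - current_start
    return total


def coding_density(genome_length: int, features: Sequence[Feature]) -> float:
    """Fraction of the genome covered by the strand-merged union of CDSs."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    cds = [(f.start, f.end) for f in features if f.type == "CDS"]
    for start, end in cds:
        if end > genome_length:
            raise ValueError(
                f"CDS interval ({start}, {end}) exceeds genome length "
                f"{genome_length}"
            )
    return _merged_length(cds) / genome_length


def class_percentages(n_cds: int, n_rna: int, n_pseudo: int) -> pd.DataFrame:
    """Gene-class counts and percentages of total genes (CDS + RNA).

    Pseudo genes are reported as a percentage of total genes but are not
    added to the total.
    """
    total = n_cds + n_rna
    if total <= 0:
        raise ValueError("need at least one CDS or RNA gene")
    rows = [
        ("total_genes", total, 100.0),
        ("protein_coding_genes", n_cds, _round_half_up(100.0 * n_cds / total, 2)),
        ("rna_genes", n_rna, _round_half_up(100.0 * n_rna / total, 2)),
        ("pseudo_genes", n_pseudo, _round_half_up(100.0 * n_pseudo / total, 2)),
    ]
    return pd.DataFrame(rows, columns=["attribute", "count", "percent"])


def gene_class_breakdown(features: Sequence[Feature]) -> pd.DataFrame:
    """Counts and percentages per feature class from an annotation table."""
    if not features:
        raise ValueError("feature table is empty")
    counts = {cls: 0 for cls in FEATURE_CLASSES}
    for f in features:
        counts[f.type] += 1
    n_rna = sum(counts[c] for c in _RNA_CLASSES)
    return class_percentages(counts["CDS"], n_rna, counts["pseudo"])


def summary_from_counts(
    genome_size: int,
    coding_bases: int,
    gc_bases: int,
    n_cds: int,
    n_rna: int,
    n_pseudo: int,
) -> pd.DataFrame:
    """Genome-statistics report from pre-tallied base and gene counts.

    Base-pair attributes are expressed as percentages of genome size,
    gene classes as percentages of total genes, all at two decimals.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    rows = [
        ("genome_size_bp", genome_size, 100.0),
        (
            "dna_coding_region_bp",
            coding_bases,
            _round_half_up(100.0 * coding_bases / genome_size, 2),
        ),
        (
            "dna_gc_content_bp",
            gc_bases,
            _round_half_up(100.0 * gc_bases / genome_size, 2),
        ),
    ]
    frame = pd.DataFrame(rows, columns=["attribute", "count", "percent"])
    return pd.concat(
        [frame, class_percentages(n_cds, n_rna, n_pseudo)], ignore_index=True
    )


def genome_summary(sequence, features: Sequence[Feature]) -> pd.DataFrame:
    """Full report computed from a sequence and its feature annotation."""
    seq = str(getattr(sequence, "seq", sequence)).upper()
    gc_bases, _ = gc_content(seq)
    coding = coding_density(len(seq), features)
    counts = {cls: 0 for cls in FEATURE_CLASSES}
    for f in features:
        counts[f.type] += 1
    n_rna = sum(counts[c] for c in _RNA_CLASSES)
    return summary_from_counts(
        genome_size=len(seq),
        coding_bases=int(round(coding * len(seq))),
        gc_bases=gc_bases,
        n_cds=counts["CDS"],
        n_rna=n_rna,
        n_pseudo=counts["pseudo"],
    )


def _classify(feature) -> str | None:
    pseudo = "pseudo" in feature.qualifiers or "pseudogene" in feature.qualifiers
    if feature.type == "gene":
        # pseudo genes usually carry only a /pseudo gene feature
        return "pseudo" if pseudo else None
    if pseudo:
        return None  # companion gene feature already counted it
    if feature.type in ("CDS", "rRNA", "tRNA"):
        return feature.type
    if feature.type in _OTHER_RNA_TYPES:
        return "other_RNA"
    return None


def read_genbank(path) -> tuple[list, list[Feature]]:
    """Read a GenBank flat file into records and classified features."""
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"{path}: no records")
    features: list[Feature] = []
    for record in records:
        for feature in record.features:
            cls = _classify(feature)
            if cls is None:
                continue
            features.append(
                Feature(
                    type=cls,
                    start=int(feature.location.start),
                    end=int(feature.location.end),
                    strand="-" if feature.location.strand == -1 else "+",
                )
            )
    return records, features


def read_fasta_lengths(path) -> dict[str, int]:
    """Replicon id -> length for every record in a FASTA file."""
    lengths = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not lengths:
        raise ValueError(f"{path}: no records")
    return lengths


def read_feature_table(path) -> list[Feature]:
    """Read a tab-separated feature table (type, start, end[, strand])."""
    table = pd.read_csv(path, sep="\t", dtype={"type": str})
    required = {"type", "start", "end"}
    if not required.issubset(table.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, got {list(table.columns)}"
        )
    strands = table["strand"] if "strand" in table.columns else ["+"] * len(table)
    return [
        Feature(type=t, start=int(s), end=int(e), strand=str(st))
        for t, s, e, st in zip(table["type"], table["start"], table["end"], strands)
    ]
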