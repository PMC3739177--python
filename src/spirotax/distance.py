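"""Ungapped HSP discovery and genome-to-genome distance components.

Implements a blastn-like seed-and-extend search for high-scoring segment
pairs (HSPs) between two genomes, and the three distance components
derived from the retained HSP set:

* f1 — summed HSP length over the mean of the two genome lengths,
* f2 — summed identities over summed HSP length,
* f3 — summed identities over the mean genome length (= f1 * f2).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Hsp",
    "DistanceTriple",
    "find_hsps",
    "compute_distance_formulas",
    "formula3_from_components",
    "hsp_table",
    "distance_report_row",
]

_ACGT = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


@dataclass(frozen=True)
class Hsp:
    """An ungapped high-scoring segment pair.

    Coordinates are 0-based half-open; ``strand`` is the orientation of
    the genome-B interval relative to genome A.
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str
    length: int
    identities: int
    score: int

    def __post_init__(self) -> None:
        if not 0 <= self.identities <= self.length:
            raise ValueError("identities must lie in [0, length]")
        if self.a_end - self.a_start != self.length:
            raise ValueError("HSPs are ungapped: a-interval must equal length")
        if self.b_end - self.b_start != self.length:
            raise ValueError("HSPs are ungapped: b-interval must equal length")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class DistanceTriple:
    """The three coverage/identity distance components of one genome pair."""

    f1: float
    f2: float
    f3: float
    total_length: float
    has_hsps: bool = True

    def as_percentages(self) -> tuple[float, float, float]:
        """(f1, f2, f3) as percentages rounded to two decimals."""
        return tuple(_round_half_up(100.0 * f, 2) for f in (self.f1, self.f2, self.f3))


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _as_string(genome) -> str:
    if isinstance(genome, SeqRecord):
        return str(genome.seq).upper()
    if isinstance(genome, Seq):
        return str(genome).upper()
    return str(genome).upper()


def _reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _build_word_index(seq: str, word_size: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    clean = [c in _ACGT for c in seq]
    run = 0  # length of current clean suffix ending at i
    for i, ok in enumerate(clean):
        run = run + 1 if ok else 0
        if run >= word_size:
            start = i - word_size + 1
            index.setdefault(seq[start : i + 1], []).append(start)
    return index


def _extend(
    sa: str,
    sb: str,
    apos: int,
    bpos: int,
    word_size: int,
    x_drop: int,
    match: int,
    mismatch: int,
) -> tuple[int, int, int, int, int, int]:
    """X-drop extension of an exact word seed along its diagonal.

    Returns (a_start, a_end, b_start (in sb coords), score, identities,
    right_stop) where right_stop is the furthest sb position explored,
    used to suppress redundant seeds on the same diagonal.
    """
    la, lb = len(sa), len(sb)

    # right extension
    best_right = 0
    right_matches = 0
    cur = 0
    cur_matches = 0
    best = 0
    i = 0
    while apos + word_size + i < la and bpos + word_size + i < lb:
        ca = sa[apos + word_size + i]
        cb = sb[bpos + word_size + i]
        if ca == cb and ca in _ACGT:
            cur += match
            cur_matches += 1
        else:
            cur += mismatch
        i += 1
        if cur > best:
            best = cur
            best_right = i
            right_matches = cur_matches
        if cur <= best - x_drop:
            break
    right_stop = bpos + word_size + i
    right_gain = best

    # left extension
    best_left = 0
    left_matches = 0
    cur = 0
    cur_matches = 0
    best = 0
    i = 0
    while apos - 1 - i >= 0 and bpos - 1 - i >= 0:
        ca = sa[apos - 1 - i]
        cb = sb[bpos - 1 - i]
        if ca == cb and ca in _ACGT:
            cur += match
            cur_matches += 1
        else:
            cur += mismatch
        i += 1
        if cur > best:
            best = cur
            best_left = i
            left_matches = cur_matches
        if cur <= best - x_drop:
            break
    left_gain = best

    a_start = apos - best_left
    a_end = apos + word_size + best_right
    b_start = bpos - best_left
    score = word_size * match + left_gain + right_gain
    identities = word_size + left_matches + right_matches
    return a_start, a_end, b_start, score, identities, right_stop


def find_hsps(
    genome_a,
    genome_b,
    word_size: int = 11,
    min_score: int = 28,
    x_drop: int = 20,
    match: int = 1,
    mismatch: int = -1,
) -> list[Hsp]:
    """Find ungapped HSPs between two genomes on both strands.

    Exact ``word_size``-mers seed X-drop extensions scored with unit
    match/mismatch weights.  Ambiguity characters never seed and always
    score as mismatches.  HSPs scoring below ``min_score`` are dropped;
    of the rest, higher-scoring HSPs suppress any HSP overlapping them
    on genome A, so coverage is never double-counted.
    """
    sa = _as_string(genome_a)
    sb = _as_string(genome_b)
    if not sa or not sb:
        raise ValueError("empty sequence")
    if word_size < 4:
        raise ValueError("word_size must be >= 4")

    index = _build_word_index(sa, word_size)
    raw: dict[tuple, Hsp] = {}
    lb = len(sb)

    for strand in "+-":
        seq_b = sb if strand == "+" else _reverse_complement(sb)
        covered: dict[int, int] = {}  # diagonal -> furthest explored sb position
        for bpos in range(len(seq_b) - word_size + 1):
            hits = index.get(seq_b[bpos : bpos + word_size])
            if not hits:
                continue
            for apos in hits:
                diag = apos - bpos
                if bpos < covered.get(diag, 0):
                    continue
                a_start, a_end, b_start, score, idents, right_stop = _extend(
                    sa, seq_b, apos, bpos, word_size, x_drop, match, mismatch
                )
                covered[diag] = right_stop
                if score < min_score:
                    continue
                length = a_end - a_start
                if strand == "+":
                    hsp = Hsp(
                        a_start, a_end, b_start, b_start + length,
                        "+", length, idents, score,
                    )
                else:
                    # map interval on the reverse complement back to B
                    hsp = Hsp(
                        a_start, a_end, lb - (b_start + length), lb - b_start,
                        "-", length, idents, score,
                    )
                raw.setdefault(
                    (hsp.a_start, hsp.a_end, hsp.b_start, hsp.b_end, hsp.strand),
                    hsp,
                )
    return _filter_overlapping(raw.values())


def _filter_overlapping(hsps: Iterable[Hsp]) -> list[Hsp]:
    """Greedily keep HSPs by descending score, non-overlapping on genome A."""
    kept: list[Hsp] = []
    for hsp in sorted(
        hsps, key=lambda h: (-h.score, h.a_start, h.b_start, h.strand)
    ):
        if all(
            hsp.a_end <= other.a_start or hsp.a_start >= other.a_end
            for other in kept
        ):
            kept.append(hsp)
    kept.sort(key=lambda h: h.a_start)
    return kept


def compute_distance_formulas(
    hsps: Sequence[Hsp], len_a: int, len_b: int
) -> DistanceTriple:
    """Compute the three distance components from a retained HSP set.

    The normalizing length is the arithmetic mean of the two genome
    lengths.  With no HSPs, f1 = f2 = f3 = 0 and ``has_hsps`` is False.
    """
    if len_a <= 0 or len_b <= 0:
        raise ValueError("genome lengths must be positive")
    for hsp in hsps:
        if not (0 <= hsp.a_start and hsp.a_end <= len_a):
            raise ValueError(f"HSP {hsp} outside genome A of length {len_a}")
        if not (0 <= hsp.b_start and hsp.b_end <= len_b):
            raise ValueError(f"HSP {hsp} outside genome B of length {len_b}")
    total_length = 0.5 * (len_a + len_b)
    sum_len = sum(h.length for h in hsps)
    sum_idents = sum(h.identities for h in hsps)
    if sum_len == 0:
        return DistanceTriple(0.0, 0.0, 0.0, total_length, has_hsps=False)
    f1 = sum_len / total_length
    f2 = sum_idents / sum_len
    f3 = sum_idents / total_length
    return DistanceTriple(f1, f2, f3, total_length)


def formula3_from_components(coverage_percent: float, identity_percent: float) -> float:
    """Whole-genome identity (%) from coverage (%) and within-HSP identity (%).

    Rounded to two decimals, matching report conventions.
    """
    return _round_half_up(coverage_percent * identity_percent / 100.0, 2)


def hsp_table(hsps: Sequence[Hsp]) -> pd.DataFrame:
    """Tabulate an HSP set (0-based half-open coordinates)."""
    return pd.DataFrame(
        [
            {
                "a_start": h.a_start,
                "a_end": h.a_end,
                "b_start": h.b_start,
                "b_end": h.b_end,
                "strand": h.strand,
                "length": h.length,
                "identities": h.identities,
                "score": h.score,
            }
            for h in hsps
        ],
        columns=[
            "a_start", "a_end", "b_start", "b_end",
            "strand", "length", "identities", "score",
        ],
    )


def distance_report_row(
    label_a: str, label_b: str, triple: DistanceTriple
) -> dict[str, object]:
    """One pairwise-report row with two-decimal percentages."""
    p1, p2, p3 = triple.as_percentages()
    return {
        "genome_a": label_a,
        "genome_b": label_b,
        "hsp_length_over_total_length_pct": p1,
        "identities_over_hsp_length_pct": p2,
        "identities_over_total_length_pct": p3,
    }
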