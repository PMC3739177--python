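"""Small readers/writers for the text formats the pipeline exchanges."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_trait_table",
    "write_trait_table",
]


def read_fasta(path) -> list[SeqRecord]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    SeqIO.write(list(records), str(path), "fasta")


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_trait_table(path) -> pd.DataFrame:
    """Tab-separated trait table: first column taxon label, then traits."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.empty:
        raise ValueError(f"{path}: empty trait table")
    return table


def write_trait_table(traits: pd.DataFrame, path) -> None:
    traits.to_csv(Path(path), sep="\t")
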