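# spirotax

Comparative-genomic and phylogenetic profiling toolkit built around the
analyses used to delineate spirochete genera:

* **Genome-to-genome distances** — an ungapped blastn-like seed-and-extend
  HSP finder and the three coverage/identity distance components
  (f1 = HSP length / mean genome length, f2 = identities / HSP length,
  f3 = identities / mean genome length; f3 = f1·f2).
* **COG-category profiling** — genomes × 25-category count matrices,
  relative proportions, arcsine-square-root and log transforms, and
  two-way clustered heatmaps (Euclidean/UPGMA).
* **Phylogenetically independent contrasts** — Felsenstein's pruning
  recursion on rooted branch-length trees, through-origin contrast
  correlation and raw Pearson correlation with significance tests.
* **16S rRNA hit-table profiling** — bit-score-weighted genus and
  stemmed-keyword frequencies (built-in Porter stemmer), per-hit HSP
  identity/coverage summaries, pairwise mismatch counts.
* **Genome statistics** — G+C content, coding density, gene-class
  breakdowns from GenBank/FASTA plus feature tables.
* **Synthetic data** — generators for every input: genome pairs with
  planted conserved segments of known coverage/identity, Yule trees,
  bivariate correlated Brownian-motion traits, and multinomial COG gene
  tables. The whole pipeline is testable offline.

## CLI

One subcommand per stage:

```sh
spirotax ggd --a A.fna --b B.fna --word-size 11 --min-score 28 --out report.tsv
spirotax cogmap --tables gene_tables/ --transform arcsine --out fig4.svg
spirotax contrasts --tree tree.nwk --traits traits.tsv --out contrasts_out/
spirotax rrna-profile --hits hits.tsv --annot annot.tsv --query-length 1450 --out report/
spirotax stats --genome genome.gbk --out table.tsv
spirotax simulate tree --n-taxa 64 --seed 1 --out tree.nwk
spirotax simulate genome-pair --length 50000 --alignable-fraction 0.3 --out pair/
```

End-to-end runs are driven by a YAML config (see `examples/study.yaml`);
outputs plus a digest manifest land under the configured directory and
are byte-identical for a fixed seed:

```sh
spirotax run --config examples/study.yaml
```

## Layout

```
src/spirotax/
  synthetic.py    input generators (genome pairs, trees, traits, gene tables)
  distance.py     HSP discovery + distance formulas
  cog.py          COG count matrices, transforms, clustered heatmaps
  contrasts.py    independent contrasts + correlations
  rrna.py         hit-table profiling, Porter stemming, mismatch counts
  genomestats.py  G+C, coding density, gene classes
  pipeline.py     stage orchestration, config validation, manifest
  cli.py          click command line
  refdata.py      published reference values used by reports and tests
tests/            pytest suite incl. test_acceptance.py (acceptance criteria)
scripts/acceptance.py
examples/study.yaml
```
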