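"""End-to-end orchestration of the analysis stages.

A declarative config (YAML mapping or dict) selects, per stage, either a
synthetic input block or input files.  All stage outputs land under one
output directory and are listed, with content digests, in a JSON
manifest, so a fixed seed plus a fixed config is verifiably
reproducible.  On stage failure, completed stages' outputs are kept and
the error names the failing stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import cog, contrasts, distance, genomestats, rrna, synthetic
from .io import (
    read_newick,
    read_trait_table,
    write_fasta,
    write_newick,
    write_trait_table,
)

__all__ = ["ConfigError", "PipelineError", "RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("spirotax.pipeline")

STAGES = ("genome_distance", "cog_heatmap", "contrasts", "rrna_profile", "genome_stats")


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


class PipelineError(RuntimeError):
    """A stage failed; completed stages' outputs are left intact."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    outdir: Path
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RunConfig":
        if not isinstance(raw, Mapping):
            raise ConfigError("config must be a mapping")
        if "outdir" not in raw:
            raise ConfigError("outdir")
        seed = raw.get("seed", 0)
        if not isinstance(seed, int):
            raise ConfigError("seed: must be an integer")
        stages_raw = raw.get("stages", {})
        if not isinstance(stages_raw, Mapping) or not stages_raw:
            raise ConfigError("stages: at least one stage is required")
        stages: dict[str, dict[str, Any]] = {}
        for name, block in stages_raw.items():
            if name not in STAGES:
                raise ConfigError(f"stages.{name}: unknown stage (valid: {STAGES})")
            if not isinstance(block, Mapping):
                raise ConfigError(f"stages.{name}: must be a mapping")
            _validate_stage(name, dict(block))
            stages[name] = dict(block)
        return cls(seed=seed, outdir=Path(raw["outdir"]), stages=stages)


def _require(block: Mapping[str, Any], stage: str, key: str) -> Any:
    if key not in block:
        raise ConfigError(f"stages.{stage}.{key}")
    return block[key]


def _validate_stage(name: str, block: dict[str, Any]) -> None:
    synth = block.get("synthetic")
    if name == "genome_distance":
        if synth is not None:
            for key in ("ancestor_length", "alignable_fraction",
                        "within_identity", "n_segments"):
                if key not in synth:
                    raise ConfigError(f"stages.{name}.synthetic.{key}")
            if "a" in block or "b" in block:
                raise ConfigError(
                    f"stages.{name}: give either synthetic or a/b files, not both"
                )
        else:
            _require(block, name, "a")
            _require(block, name, "b")
    elif name == "cog_heatmap":
        if synth is not None:
            groups = synth.get("groups")
            if not groups:
                raise ConfigError(f"stages.{name}.synthetic.groups")
        elif "tables" not in block:
            raise ConfigError(f"stages.{name}.tables")
        if block.get("transform", "arcsine_sqrt") not in ("arcsine_sqrt", "log"):
            raise ConfigError(f"stages.{name}.transform")
    elif name == "contrasts":
        if synth is not None:
            if "n_taxa" not in synth:
                raise ConfigError(f"stages.{name}.synthetic.n_taxa")
        else:
            _require(block, name, "tree")
            _require(block, name, "traits")
    elif name == "rrna_profile":
        _require(block, name, "hits")
        _require(block, name, "query_length")
    elif name == "genome_stats":
        _require(block, name, "genome")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.from_mapping(raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    return int(
        np.random.SeedSequence([seed, STAGES.index(stage)]).generate_state(1)[0]
    )


def _plot_scatter(raw_df, contrast_df, out_path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    matplotlib.rcParams["svg.hashsalt"] = "spirotax"
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
    x, y = raw_df["trait_x"].to_numpy(), raw_df["trait_y"].to_numpy()
    axes[0].scatter(x, y, s=18)
    slope, intercept = np.polyfit(x, y, 1)
    grid = np.linspace(x.min(), x.max(), 50)
    axes[0].plot(grid, slope * grid + intercept, color="C3")
    axes[0].set_title("uncorrected data")
    axes[0].set_xlabel("trait_x")
    axes[0].set_ylabel("trait_y")

    cx, cy = contrast_df["trait_x"].to_numpy(), contrast_df["trait_y"].to_numpy()
    axes[1].scatter(cx, cy, s=18)
    slope0 = float(np.dot(cx, cy) / np.dot(cx, cx))
    grid = np.linspace(cx.min(), cx.max(), 50)
    axes[1].plot(grid, slope0 * grid, color="C3")
    axes[1].set_title("independent contrasts")
    axes[1].set_xlabel("contrast(trait_x)")
    axes[1].set_ylabel("contrast(trait_y)")
    fig.tight_layout()
    metadata = {"Date": None} if out_path.suffix == ".svg" else None
    fig.savefig(out_path, metadata=metadata)
    plt.close(fig)


def _run_genome_distance(block, outdir: Path, seed: int) -> list[Path]:
    if "synthetic" in block and block["synthetic"] is not None:
        synth = block["synthetic"]
        spec = synthetic.GenomePairSpec(
            ancestor_length=synth["ancestor_length"],
            alignable_fraction=synth["alignable_fraction"],
            within_identity=synth["within_identity"],
            n_segments=synth["n_segments"],
            seed=synth.get("seed", seed),
        )
        rec_a, rec_b, truth = synthetic.simulate_genome_pair(spec)
        write_fasta([rec_a], outdir / "genome_a.fna")
        write_fasta([rec_b], outdir / "genome_b.fna")
        truth.to_csv(outdir / "truth_segments.tsv", sep="\t", index=False)
        extra = [outdir / "genome_a.fna", outdir / "genome_b.fna",
                 outdir / "truth_segments.tsv"]
    else:
        from Bio import SeqIO

        rec_a = "".join(
            str(r.seq) for r in SeqIO.parse(str(block["a"]), "fasta")
        )
        rec_b = "".join(
            str(r.seq) for r in SeqIO.parse(str(block["b"]), "fasta")
        )
        extra = []
    sa = str(getattr(rec_a, "seq", rec_a))
    sb = str(getattr(rec_b, "seq", rec_b))
    hsps = distance.find_hsps(
        sa,
        sb,
        word_size=block.get("word_size", 11),
        min_score=block.get("min_score", 28),
        x_drop=block.get("x_drop", 20),
    )
    distance.hsp_table(hsps).to_csv(outdir / "hsps.tsv", sep="\t", index=False)
    triple = distance.compute_distance_formulas(hsps, len(sa), len(sb))
    row = distance.distance_report_row("genome_a", "genome_b", triple)
    pd.DataFrame([row]).to_csv(outdir / "distance_report.tsv", sep="\t", index=False)
    return extra + [outdir / "hsps.tsv", outdir / "distance_report.tsv"]


def _build_group_profile(boost: list[str], factor: float = 5.0) -> np.ndarray:
    weights = np.ones(len(cog.COG_CATEGORIES))
    for letter in boost:
        weights[cog.COG_CATEGORIES.index(letter)] *= factor
    return weights / weights.sum()


def _run_cog_heatmap(block, outdir: Path, seed: int) -> list[Path]:
    outputs: list[Path] = []
    if "synthetic" in block and block["synthetic"] is not None:
        synth = block["synthetic"]
        profiles = {
            group: _build_group_profile(
                gspec.get("boost", []), gspec.get("factor", 5.0)
            )
            for group, gspec in synth["groups"].items()
        }
        spec = synthetic.CogProfileSpec(
            group_profiles=profiles,
            n_genes_range=tuple(synth.get("n_genes_range", (1500, 2500))),
            multi_assignment_rate=synth.get("multi_assignment_rate", 0.1),
            assigned_fraction=synth.get("assigned_fraction", 0.8),
        )
        tables = {}
        offset = 0
        for group, gspec in synth["groups"].items():
            for i in range(gspec.get("n_genomes", 3)):
                label = f"{group}_{i + 1}"
                tables[label] = synthetic.simulate_cog_table(
                    spec, group, seed=seed + offset
                )
                path = outdir / f"genes_{label}.tsv"
                tables[label].to_csv(path, sep="\t", index=False)
                outputs.append(path)
                offset += 1
    else:
        tables = {
            p.stem.removeprefix("genes_"): cog.read_gene_table(p)
            for p in sorted(Path(block["tables"]).glob("*.tsv"))
        }
    matrix = cog.build_count_matrix(tables)
    matrix.to_csv(outdir / "cog_counts.tsv", sep="\t")
    transformed = cog.transform_matrix(matrix, block.get("transform", "arcsine_sqrt"))
    transformed.values.to_csv(outdir / "cog_transformed.tsv", sep="\t")
    heatmap_path = outdir / "cog_heatmap.svg"
    result = cog.cluster_heatmap(transformed, out_path=str(heatmap_path))
    orders = pd.DataFrame(
        {
            "axis": ["row"] * len(result.row_order) + ["col"] * len(result.col_order),
            "label": result.row_order + result.col_order,
        }
    )
    orders.to_csv(outdir / "cog_cluster_orders.tsv", sep="\t", index=False)
    return outputs + [
        outdir / "cog_counts.tsv",
        outdir / "cog_transformed.tsv",
        heatmap_path,
        outdir / "cog_cluster_orders.tsv",
    ]


def _run_contrasts(block, outdir: Path, seed: int) -> list[Path]:
    outputs: list[Path] = []
    if "synthetic" in block and block["synthetic"] is not None:
        synth = block["synthetic"]
        tree = synthetic.simulate_tree(
            n_taxa=synth["n_taxa"],
            birth_rate=synth.get("birth_rate", 1.0),
            seed=seed,
        )
        spec = synthetic.TraitSimSpec(
            sigma_x=synth.get("sigma_x", 1.0),
            sigma_y=synth.get("sigma_y", 1.0),
            rho=synth.get("rho", 0.0),
            seed=seed + 1,
        )
        traits = synthetic.simulate_correlated_traits(tree, spec)
        write_newick(tree, outdir / "tree.nwk")
        write_trait_table(traits, outdir / "traits.tsv")
        outputs += [outdir / "tree.nwk", outdir / "traits.tsv"]
    else:
        tree = read_newick(block["tree"])
        traits = read_trait_table(block["traits"])
    table = contrasts.independent_contrasts_table(tree, traits[["trait_x", "trait_y"]])
    table.to_csv(outdir / "contrasts.tsv", sep="\t")
    raw_res = contrasts.raw_correlation(traits["trait_x"], traits["trait_y"])
    con_res = contrasts.contrast_correlation(
        table["trait_x"].to_numpy(), table["trait_y"].to_numpy()
    )
    pd.DataFrame(
        [
            {"mode": r.mode, "r": r.r, "p": r.p, "n": r.n}
            for r in (raw_res, con_res)
        ]
    ).to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    _plot_scatter(traits, table, outdir / "trait_scatter.svg")
    return outputs + [
        outdir / "contrasts.tsv",
        outdir / "correlations.tsv",
        outdir / "trait_scatter.svg",
    ]


def _run_rrna_profile(block, outdir: Path, seed: int) -> list[Path]:
    annotations = None
    if block.get("annot"):
        annotations = rrna.read_annotations(block["annot"])
    hits = rrna.read_hit_table(block["hits"], annotations=annotations)
    outputs = []
    try:
        taxa = rrna.weighted_taxon_frequencies(hits)
        taxa.frequencies.to_csv(outdir / "taxon_frequencies.tsv", sep="\t")
        outputs.append(outdir / "taxon_frequencies.tsv")
    except rrna.EmptyReportError:
        logger.info("rrna_profile: no taxon labels, skipping taxon report")
    try:
        keywords = rrna.weighted_keyword_frequencies(hits)
        keywords.frequencies.to_csv(outdir / "keyword_frequencies.tsv", sep="\t")
        outputs.append(outdir / "keyword_frequencies.tsv")
    except rrna.EmptyReportError:
        logger.info("rrna_profile: no descriptions, skipping keyword report")
    summary = rrna.hsp_summary(hits, block["query_length"])
    pd.DataFrame(
        [
            {
                "mean_identity_pct": summary.mean_identity,
                "mean_coverage_pct": summary.mean_coverage,
                "n_hits": summary.n_hits,
            }
        ]
    ).to_csv(outdir / "hsp_summary.tsv", sep="\t", index=False)
    outputs.append(outdir / "hsp_summary.tsv")
    return outputs


def _run_genome_stats(block, outdir: Path, seed: int) -> list[Path]:
    genome = str(block["genome"])
    if genome.endswith((".gb", ".gbk", ".gbff")):
        records, features = genomestats.read_genbank(genome)
        seq = "".join(str(r.seq) for r in records)
    else:
        from Bio import SeqIO

        records = list(SeqIO.parse(genome, "fasta"))
        seq = "".join(str(r.seq) for r in records)
        features = (
            genomestats.read_feature_table(block["features"])
            if block.get("features")
            else []
        )
    if features:
        report = genomestats.genome_summary(seq, features)
    else:
        gc_bases, gc_frac = genomestats.gc_content(seq)
        report = pd.DataFrame(
            [
                ("genome_size_bp", len(seq), 100.0),
                ("dna_gc_content_bp", gc_bases, round(100.0 * gc_frac, 2)),
            ],
            columns=["attribute", "count", "percent"],
        )
    report.to_csv(outdir / "genome_stats.tsv", sep="\t", index=False)
    return [outdir / "genome_stats.tsv"]


_RUNNERS = {
    "genome_distance": _run_genome_distance,
    "cog_heatmap": _run_cog_heatmap,
    "contrasts": _run_contrasts,
    "rrna_profile": _run_rrna_profile,
    "genome_stats": _run_genome_stats,
}


def run_pipeline(config: RunConfig | Mapping[str, Any]) -> dict[str, Any]:
    """Run every configured stage; return (and write) the manifest."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_mapping(config)
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        block = config.stages[stage]
        stage_dir = outdir / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        stage_seed = _stage_seed(config.seed, stage)
        logger.info("running stage %s (seed %d)", stage, stage_seed)
        logger.debug("stage %s parameters: %r", stage, block)
        try:
            outputs = _RUNNERS[stage](block, stage_dir, stage_seed)
        except Exception as exc:
            _write_manifest(outdir, manifest)
            raise PipelineError(stage, exc) from exc
        manifest["stages"][stage] = {
            "seed": stage_seed,
            "outputs": {
                str(p.relative_to(outdir)): _digest(p) for p in outputs
            },
        }
    _write_manifest(outdir, manifest)
    return manifest


def _write_manifest(outdir: Path, manifest: dict[str, Any]) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
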