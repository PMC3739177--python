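# Demo end-to-end synthetic study: genome distances, COG heatmap,
# and trait contrasts, all from generated inputs.
seed: 42
outdir: out/demo
stages:
  genome_distance:
    synthetic:
      ancestor_length: 20000
      alignable_fraction: 0.30
      within_identity: 0.85
      n_segments: 10
    word_size: 11
    min_score: 28
    x_drop: 20
  cog_heatmap:
    synthetic:
      groups:
        motile: {boost: [N, T], n_genomes: 4}
        coccoid: {boost: [G], n_genomes: 4}
        parasitic: {boost: [J, V], n_genomes: 4}
      n_genes_range: [1500, 2500]
      multi_assignment_rate: 0.1
      assigned_fraction: 0.8
    transform: arcsine_sqrt
  contrasts:
    synthetic:
      n_taxa: 32
      rho: 0.8
      sigma_x: 1.0
      sigma_y: 1.0
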