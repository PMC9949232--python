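# Desk-scale demo: a 300 kb genome with 40 genes, two ChIP replicates,
# two hMeRIP replicates per genotype, and a small expression matrix.
seed: 0
outdir: epitet_demo
chip_dialect: embryo
consensus_window: 250
simulation:
  genome_length: 300000
  n_genes: 40
  n_planted_chip_peaks: 50
  chip_replicates: 2
  n_planted_rna_peaks: 60
  hmerip_replicates: 2
  count_replicates: 3
  de_fraction: 0.1
motif_n_shuffles: 20
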