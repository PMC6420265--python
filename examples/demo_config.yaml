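seed: 1
reference:
  n_copies: 1
  unit_length: 2000
  chrom_length: 250000
  insert_position: 110000
  flank_gene_length: 2000
library_on:
  n_pirna: 4000
  n_sirna: 500
  n_mirna: 2000
  pingpong_fraction: 0.5
library_off:
  n_pirna: 0
  n_sirna: 0
  n_mirna: 2000
windowscan:
  width: 50000
  min_density: 5
  mode: either
  pseudocount: 1
  log2_threshold: 8.5
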