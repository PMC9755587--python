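# Synthetic TPM-matrix generator configuration.
#
# Schema:
#   n_genes:              total number of genes (rows)
#   sample_labels:        ordered tissue/stage labels (columns)
#   modules:              planted co-expression modules; each member shares
#                         the module archetype up to a gene-specific scale
#     - size:             number of genes in the module
#       archetype:        named shape (flat, increasing, decreasing,
#                         early-peak, mid-peak, stigma-peak) or an explicit
#                         positive vector, one value per sample
#   background_log_mean:  log-normal location of background genes
#                         (scalar or one value per sample)
#   background_log_sd:    log-normal scale of background genes (> 0)
#   noise_sd:             multiplicative noise sd on the natural-log scale
#   zero_gene_fraction:   fraction of genes identically zero in [0, 1)
#   seed:                 integer RNG seed

n_genes: 500
sample_labels:
  - flower_st9
  - flower_st10
  - flower_st11
  - flower_st12
  - carpel_st12
  - stigma_st13
  - ovule_st13
  - anther_st12
modules:
  - size: 10
    archetype: mid-peak
background_log_mean: 1.0
background_log_sd: 1.0
noise_sd: 0.05
zero_gene_fraction: 0.1
seed: 1
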