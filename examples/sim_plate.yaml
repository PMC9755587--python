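# Synthetic qPCR-plate generator configuration.
#
# Schema:
#   sample_labels:      tissues/stages on the plate
#   calibrator:         sample all fold changes are expressed against
#   target_folds:       per target gene, the true fold change per sample
#                       relative to the calibrator (calibrator fold is 1
#                       by definition and may be omitted)
#   target_base_cq:     Cq of a target at fold 1 (cycles)
#   reference_base_cq:  per reference gene, its constant Cq level
#   n_bio / n_tech:     biological / technical replicates per sample
#   cq_noise_sd:        technical well-to-well noise sd (cycles)
#   bio_noise_sd:       biological pool offset sd (cycles), shared by all
#                       genes of one (sample, bio rep) and cancelling in dCt
#   seed:               integer RNG seed

sample_labels:
  - pistil_st11
  - pistil_st12
  - anther_st12
  - pistil_st14
  - silique_st17
calibrator: anther_st12
target_folds:
  AGP24:
    pistil_st11: 0.25
    pistil_st12: 0.5
    pistil_st14: 2.0
    silique_st17: 4.0
target_base_cq: 24.0
reference_base_cq:
  RCE1: 20.0
  TUA2: 21.0
  YLS8: 22.0
n_bio: 3
n_tech: 3
cq_noise_sd: 0.1
bio_noise_sd: 0.3
seed: 7
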