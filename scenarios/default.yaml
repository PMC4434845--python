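# Default desk-scale scenario: nine immune-mediated diseases, 407 distinct
# genes, focal (AS) pairwise overlaps CD 11 / UC 8 / CeD 5 / PS 5 / T1D 4 /
# MS 4 / PBC 1, sharing classes 8 unique / 17 in at most two others / 5 in
# more than two. Expression over 45 FPKM samples and 30 proteome tissues
# (6 fetal, 18 adult, 6 hematopoietic); 400 decoy gene sets plus one planted
# pathway; 2,000-node interaction network with planted cross-set density.
seed: 0
focal: AS
diseases: [AS, CD, UC, PS, CeD, MS, PBC, RA, T1D]
set_sizes:
  AS: 30
  CD: 110
  UC: 75
  PS: 40
  CeD: 40
  MS: 50
  PBC: 20
  RA: 45
  T1D: 35
membership_patterns:
  # genes shared by the focal disease and three others
  - {diseases: [AS, CD, UC, PS], count: 1}
  - {diseases: [AS, CD, UC, CeD], count: 1}
  - {diseases: [AS, CD, UC, T1D], count: 1}
  - {diseases: [AS, CD, PS, MS], count: 1}
  - {diseases: [AS, CD, CeD, T1D], count: 1}
  # genes shared by the focal disease and two others
  - {diseases: [AS, CD, UC], count: 1}
  - {diseases: [AS, CD, PS], count: 1}
  - {diseases: [AS, CD, CeD], count: 1}
  - {diseases: [AS, UC, T1D], count: 1}
  - {diseases: [AS, UC, MS], count: 1}
  - {diseases: [AS, PS, CeD], count: 1}
  # genes shared by the focal disease and exactly one other
  - {diseases: [AS, CD], count: 3}
  - {diseases: [AS, UC], count: 2}
  - {diseases: [AS, PS], count: 1}
  - {diseases: [AS, CeD], count: 1}
  - {diseases: [AS, T1D], count: 1}
  - {diseases: [AS, MS], count: 2}
  - {diseases: [AS, PBC], count: 1}
n_tolerated: 98
burden_rates:
  lambda_tolerated: 0.02
  lambda_constrained: 0.01
  missense_fraction: 0.75
  rare_fraction: 0.9
  synonymous_rate: 0.03
  rare_cutoff: 0.01
  maf_alpha: 0.2
  maf_beta: 5.0
expression_boost:
  tissues: [b_cell, cd4_cell, cd8_cell, nk_cell, monocyte, platelet]
  factor: 3.0
planted_pathway:
  size: 50
  query_fraction: 0.5
  n_decoys: 400
  n_background: 5000
network_params:
  n_nodes: 2000
  p_background: 0.02
  p_planted: 0.1
  planted_pairs:
    - [AS, CD]
    - [AS, UC]
    - [AS, PS]
    - [AS, CeD]
    - [AS, MS]
    - [AS, PBC]
    - [AS, RA]
    - [AS, T1D]
n_fpkm_samples: 45
log_mu: 1.0
log_sigma: 1.0
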