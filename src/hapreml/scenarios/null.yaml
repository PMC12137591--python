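# No regional or polygenic signal: pure residual phenotype.
# Used for type-I-error calibration of the five mixture LRTs.
seed: 1
n_individuals: 500
n_chromosomes: 2
blocks_per_chromosome: 2
snps_per_block: 8
n_founders: 6
qtl_architecture: none
regional_share: 0.0
polygenic_h2: 0.0
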