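# Scenario A: multi-SNP additive regional architecture.
# Three typed SNPs inside one block carry additive effects (drawn on the
# standardized-dosage scale) summing to 2% of phenotypic variance.  The
# SNP-based regional model is the exact generating model; the
# haplotype-based model must spread the same signal over 16 founder
# alleles, so the SNP model should reject more often.
seed: 1
n_individuals: 1000
n_chromosomes: 2
blocks_per_chromosome: 2
snps_per_block: 6
n_founders: 16
qtl_architecture: snp_additive
causal_block_index: 0
n_causal_snps: 3
regional_share: 0.02
polygenic_h2: 0.0
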