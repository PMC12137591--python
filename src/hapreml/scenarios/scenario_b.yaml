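# Scenario B: haplotype-allele regional architecture.
# One of 16 founder haplotypes (frequency near 0.1, never tagged by a
# private SNP allele) carries the whole regional effect, 2% of phenotypic
# variance.  With 16 haplotype alleles over only 6 typed SNPs the founder
# indicator lies outside the span of SNP dosages, so the haplotype-based
# regional model should reject more often than the SNP-based one — the
# rare-variant argument for haplotype-level mapping.
seed: 1
n_individuals: 1000
n_chromosomes: 2
blocks_per_chromosome: 2
snps_per_block: 6
n_founders: 16
qtl_architecture: hap_allele
causal_block_index: 0
causal_allele_freq_target: 0.1
regional_share: 0.02
polygenic_h2: 0.0
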