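# Demo simulation: a small two-chromosome genome plus the lambda spike-in,
# two conditions x two replicates at ~10x coverage, with planted CG DMRs.
seed: 0
chrom_lengths: [150000, 150000]
gene_count: 60
te_fraction: 0.30
coverage_mean: 10.0
nonconversion_rate: 0.0012
spike_in_length: 48502
n_dmrs: 8
dmr_length_range: [1000, 2000]
dmr_effect: 0.4
dmr_context: CG
replicates_per_condition: 2
expression:
  nonexpressed_fraction: 0.15
  de_fraction: 0.10
  couple_promoter_hyper: true
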