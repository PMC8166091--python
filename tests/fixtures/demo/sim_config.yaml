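background_runs_per_window: 2.0
baseline_mean: 8.0
baseline_sd: 1.0
bin_width: 100
class_sizes:
- 5
- 14
- 5
downstream: 1000
effect_size: 1.5
enrichment_factor: 3.0
gene_spacing: 2100
max_len: 27
min_len: 13
n_chroms: 2
n_genes: 24
n_replicates: 2
noise_sd: 0.25
placement: random
seed: 101
shared_fraction: 1.0
strand_fraction_plus: 0.5
suppress_background: true
upstream: 1000
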