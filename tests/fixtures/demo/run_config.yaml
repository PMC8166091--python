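alpha: 0.05
annotation: genes.tsv
bin_width: 100
downstream: 1000
expr1: expr1.tsv
expr2: expr2.tsv
genome: genome.fa
groups: groups.yaml
max_len: 27
min_len: 13
p_cut: 0.05
upstream: 1000
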