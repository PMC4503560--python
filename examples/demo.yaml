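# Demo configuration for `iespipe run`: a small seeded fixture with half of
# the IESs partially retained in the experiment sample.
seed: 1
out: iespipe_demo
n_scaffolds: 2
scaffold_length: 20000
n_ies: 40
coverage: 100
read_length: 101
overhang: 5
retained_fraction: 0.5
retention_low: 0.1
retention_high: 0.7
background_fraction: 0.3
alpha: 0.95
threshold: 0.05
min_coverage: 1
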