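# Demonstration cross: three mutant lineages, four sequenced pools of 40
# haploid spore isolates (wt, proA_fus, fus, proB), 2-Mb reference, 50x
# mate-pair coverage per pool.  Run with:
#   sporepool run --config examples/demo.yaml --outdir demo_out
mode: simulate
seed: 42
outdir: demo_out
genome_length: 2000000
n_contigs: 1
gc: 0.5
n_background: 120
n_isolates: 40
coverage: 50.0
read_len: 76
insert_mean: 2000
insert_sd: 200
error_rate: 0.005
n_rate: 0.001
screen:
  coverage_fraction: 0.4
  penetrance_min: 0.9
  absence_max_alt: 2
  min_absent_depth: 5
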