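# Demonstration run: every stage on a small simulated supermatrix.
seed: 2024
outdir: demo_output
model:
  type: poisson
  gamma_shape: 0.8
simulate:
  hypothesis: T1
  n_genes: 25
  gene_length: 60
  missing_prob: 0.291
  rate_sigma: 0.5
delta_pl:
  enabled: true
fclm:
  enabled: true
  max_quartets: 40
au_test:
  enabled: true
  replicates: 500
mp_jackknife:
  enabled: true
  replicates: 60
  deletion: 0.36
quartet_tree:
  enabled: true
  n_loci: 100
  branch_cu: 1.0
asr:
  enabled: true
  q01: 0.5
  q10: 0.5
  generations: 1500
  burnin: 400
  thin: 5
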