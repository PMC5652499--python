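# Full registry-benchmarking study grid: 7 cohort sizes under both
# data-generating processes, 1000 repetitions each.
n: [100, 200, 400, 800, 1600, 3200, 6400]
dgp: [NCR, CR]
failure:   {scale: 0.01,  shape: 0.71}
mortality: {scale: 0.017, shape: 1.32}
horizon: 10
reps: 1000
seed: 1
benchmark:
  p_bm: 0.05
  margins: [0.01, 0.02, 0.03, 0.04, 0.05]
  alpha_one_sided: 0.025
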