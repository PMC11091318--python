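# Chicken-feed rearing scenario for the bsfdeb CLI, e.g.:
#   bsfdeb simulate --model deb --config examples/chicken_feed.yaml --out run/
#   bsfdeb synth --config examples/chicken_feed.yaml --seed 1 --out run/
model: deb
params:
  a_max: 1.2   # maximal specific assimilation rate, 1/day
  Y: 0.44      # cost of growth, C respired per C incorporated
  m: 0.08      # maintenance coefficient, 1/day
scenario:
  Xmax: 30.0   # asymptotic larval mass, mg C (~61 mg dry weight)
  X0: 0.06     # start mass, mg C
  t_end: 40.0
noise:
  cv_weight: 0.05
rearing:
  n_larvae: 100
  W_DW0: 40000.0   # supplied substrate, mg dry weight
  AD: 0.8          # digestion efficiency
  mu_mic: 0.02     # microbial substrate consumption, 1/day
seed: 1
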