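# Full synthetic run: simulate -> de -> cerna -> topology -> enrich -> validate
outdir: demo_out
seed: 1
stages: [simulate, de, cerna, topology, enrich, validate]
synthetic:
  seed: 1
  n_planted_triads: 10
  shared_pool_size: 4
  effect_size: 1.5
de:
  p_threshold: 0.05
  lfc_threshold: 1.0
cerna:
  score_threshold: 0.8
  r_threshold: 0.4
  p_threshold: 0.05
topology:
  mode: per_node
enrich:
  hubs: [MRNA0001]
  n_perm: 500
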