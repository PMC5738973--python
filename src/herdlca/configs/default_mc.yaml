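# Monte Carlo recipe: parameter distributions (assumed, editable).
n_iterations: 1000
distributions:
  ym_pasture:
    kind: lognormal
    center: 6.5
    spread: 1.1
  ym_housing:
    kind: lognormal
    center: 6.5
    spread: 1.1
  b0:
    kind: lognormal
    center: 0.18
    spread: 1.15
  ef3_deep_bedding:
    kind: lognormal
    center: 0.01
    spread: 1.5
  ef3_prp_cattle:
    kind: lognormal
    center: 0.02
    spread: 1.5
  ef1_soil:
    kind: lognormal
    center: 0.01
    spread: 1.5
  feed_de_offset:
    kind: normal
    center: 0.0
    spread: 1.5
  feed_cp_offset:
    kind: normal
    center: 0.0
    spread: 1.0
  upstream_scale:
    kind: lognormal
    center: 1.0
    spread: 1.2
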