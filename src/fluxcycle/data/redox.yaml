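# Reducing-equivalent yields per unit flux through each reaction of the
# default TCA network. Edit to match a different network or bookkeeping.
# NADH and NADPH are tallied separately; compute_redox_oxphos merges them
# by default (include_nadph=True) since both feed the cell's reducing-
# equivalent budget; set include_nadph=False to count NADH alone.
nadh:
  pdh: 1.0
  akgdh: 1.0
  mdh: 1.0
nadph:
  idh_ox: 1.0
  idh_red: -1.0
fadh2:
  sdh: 1.0
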