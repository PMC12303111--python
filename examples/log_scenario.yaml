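# Interaction-log scenario: two reference sites, badger-only
site_presence:
  site2: 0.010417   # 1 event / 96 h
  site3: 0.071970   # 19 events / 264 h
species_mix:
  badger: 1.0
behaviour_probs:
  looked: 0.29
  paused: 0.30
  sniffed: 0.41
attracted_prob: 0.30
repelled_prob: 0.20
pass_prob: 0.74
window_hours: 264
start: "2022-06-01 00:00:00"
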