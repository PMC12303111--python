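# Removal-force trial scenario: bench-calibrated effects
n: 500
intercept: 3000.0
bur_effect: 379.0
mass_slope: 13.0
noise_sd: 1030.0
driver_mass_range: [10.0, 69.0]
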