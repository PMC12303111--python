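# Landing simulation: large spring, full-piston drive, dog-sized gate
trajectory_distance_mm: 150
tag_mass_g: 12.5
driver_mass_g: 56.5
spring_constant_N_m: 990
max_stroke_mm: 110
compression_mm: 100
animal_speed_m_s: 0.5
sensor_poll_interval_s: 0.1
mean_angle_deg: 4.6
sd_angle_deg: 1.8
flip_probability: 0.311
fur_deformation_mm: 10
hit_radius_mm: 50
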