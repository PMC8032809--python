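# 64 px desk-scale scene family: 6 nm and 12 nm gold at 1.11 nm/pixel,
# strong background gradient plus one shadow streak.
height_px: 64
width_px: 64
pixel_size_nm: 1.11
particle_diameters_nm: [6.0, 12.0]
counts_per_diameter: [2, 1]
particle_intensity: 0.45
background_mean: 0.55
gradient_amplitude: 0.4
shadow_count: 1
shadow_intensity: 0.55
noise_sigma: 0.02
blur_sigma_px: 0.5
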