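name: fig3
kind: cardiac
n_fish: 8
t_start_c: 18.0
t_step_c: 1.0
t_end_c: 32.0
breakpoint_mean_c: 27.81
breakpoint_sd_c: 1.1
slope_pre_bpm_per_c: 2.0
slope_post_bpm_per_c: -8.0
rate_at_start_bpm: 60.0
rate_noise_sd_bpm: 2.0
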