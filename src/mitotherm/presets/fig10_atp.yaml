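name: fig10_atp
kind: atp
temperatures:
- 20.0
- 25.0
- 27.5
- 30.0
- 32.5
n_per_temperature: 6
protocol:
- Mal
- Pyr
- Glu
- ADP
- Succ
- Rot
- Malo
- Ant
spacing_s: 300.0
dt_s: 1.0
tau_s: 20.0
o2_start_nmol_ml: 450.0
fibre_mass_mg: 2.0
chamber_volume_ml: 2.0
state_noise_frac: 0.03
sample_noise_sd: 0.2
fluor_noise_sd: 0.05
mgg_start: 1000.0
adp_pulse_um: 10.0
o2_states:
  20.0:
    LeakI: 8.82
    OXPI: 16.66
    OXPI_II: 19.6
  25.0:
    LeakI: 9.45
    OXPI: 17.85
    OXPI_II: 21.0
  27.5:
    LeakI: 10.08
    OXPI: 19.04
    OXPI_II: 22.4
  30.0:
    LeakI: 10.206
    OXPI: 19.278
    OXPI_II: 22.68
  32.5:
    LeakI: 11.025
    OXPI: 20.825
    OXPI_II: 24.5
atp_states:
  20.0:
    OXPI: 26.46
    OXPI_II: 35.28
  25.0:
    OXPI: 20.475
    OXPI_II: 27.3
  27.5:
    OXPI: 18.48
    OXPI_II: 24.64
  30.0:
    OXPI: 14.4585
    OXPI_II: 19.278
  32.5:
    OXPI: 9.45
    OXPI_II: 12.6
adp_slope:
  20.0: 1.2
  25.0: 1.15
  27.5: 1.1
  30.0: 1.05
  32.5: 1.0
atp_to_adp_ratio:
  20.0: 1.6
  25.0: 1.6
  27.5: 1.6
  30.0: 1.6
  32.5: 1.6
mgg_titration_concs_um:
- 2.0
- 4.0
- 6.0
- 8.0
- 10.0
- 15.0
- 20.0
mgg_titration_noise_frac: 0.01
truth:
  atp_o_20c: 1.8
  atp_o_fold_20_over_32p5: 3.5
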