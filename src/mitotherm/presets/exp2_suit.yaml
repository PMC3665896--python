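name: exp2_suit
kind: suit
temperatures:
- 15.0
- 17.5
- 20.0
- 25.0
- 27.5
- 30.0
- 32.5
n_per_temperature: 8
protocol:
- Mal
- Pyr
- ADP
- Glu
- Cytc
- Succ
- NADH
- Atr
- FCCP
- FCCP
- FCCP
- Rot
- Malo
- Ant
- TMPD+Asc
spacing_s: 300.0
dt_s: 1.0
tau_s: 20.0
o2_start_nmol_ml: 450.0
fibre_mass_mg: 2.0
chamber_volume_ml: 2.0
state_noise_frac: 0.04
sample_noise_sd: 0.2
states:
  15.0:
    LeakI: 2.0
    OXPI_pm: 7.2799
    OXPI: 9.0999
    CytC: 9.0999
    OXPI_II: 14.0
    NADH: 14.0
    LeakI_II: 6.3063
    ETS: 26.2761
    CCO: 35.0
  17.5:
    LeakI: 2.2971
    OXPI_pm: 8.0015
    OXPI: 10.0019
    CytC: 10.0019
    OXPI_II: 18.62
    NADH: 18.62
    LeakI_II: 8.1667
    ETS: 29.8726
    CCO: 44.1294
  20.0:
    LeakI: 2.6383
    OXPI_pm: 8.003
    OXPI: 10.0038
    CytC: 10.504
    OXPI_II: 19.6
    NADH: 20.188
    LeakI_II: 8.412
    ETS: 28.1977
    CCO: 48.02
  25.0:
    LeakI: 3.4804
    OXPI_pm: 8.4868
    OXPI: 10.6085
    CytC: 11.8815
    OXPI_II: 21.0
    NADH: 23.1
    LeakI_II: 10.1942
    ETS: 29.4154
    CCO: 52.08
  27.5:
    LeakI: 3.9974
    OXPI_pm: 9.6218
    OXPI: 12.0273
    CytC: 13.8314
    OXPI_II: 22.4
    NADH: 25.536
    LeakI_II: 10.9804
    ETS: 31.3622
    CCO: 54.88
  30.0:
    LeakI: 4.5912
    OXPI_pm: 11.0247
    OXPI: 13.7809
    CytC: 16.537
    OXPI_II: 22.68
    NADH: 26.7624
    LeakI_II: 12.8136
    ETS: 31.7523
    CCO: 48.3084
  32.5:
    LeakI: 5.2733
    OXPI_pm: 12.657
    OXPI: 15.8212
    CytC: 19.7765
    OXPI_II: 24.5
    NADH: 29.89
    LeakI_II: 15.8065
    ETS: 34.3
    CCO: 79.87
cco_background:
  15.0: 2.0
  17.5: 2.375
  20.0: 2.75
  25.0: 3.5
  27.5: 3.875
  30.0: 4.25
  32.5: 4.625
cytc_frac:
  15.0: 0.0
  17.5: 0.0
  20.0: 0.05
  25.0: 0.12
  27.5: 0.15
  30.0: 0.2
  32.5: 0.25
nadh_frac:
  15.0: 0.0
  17.5: 0.0
  20.0: 0.03
  25.0: 0.1
  27.5: 0.14
  30.0: 0.18
  32.5: 0.22
truth:
  rcr_4pl:
    bottom: 3.0
    top: 4.6
    breakpoint_c: 19.97
    hill: -0.3
  ucr_4pl:
    bottom: 1.4
    top: 2.0
    breakpoint_c: 16.68
    hill: -0.35
  leakI_percent_increase_25c: 74.02
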