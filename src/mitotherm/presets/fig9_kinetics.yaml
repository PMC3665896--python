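name: fig9_kinetics
kind: kinetics
substrate: pyruvate
temperatures:
- 20.0
- 25.0
- 27.5
- 30.0
- 32.5
n_per_temperature: 8
km_um:
  20.0: 81.0
  25.0: 81.0
  27.5: 81.0
  30.0: 81.0
  32.5: 1520.0
vmax:
  20.0: 45.0
  25.0: 58.0
  27.5: 66.0
  30.0: 70.0
  32.5: 72.0
concentrations_um:
  20.0: &id001
  - 10
  - 20
  - 40
  - 80
  - 160
  - 320
  - 640
  - 1280
  - 2560
  - 5120
  25.0: *id001
  27.5: *id001
  30.0: *id001
  32.5:
  - 100
  - 250
  - 500
  - 1000
  - 2000
  - 4000
  - 8000
  - 12000
  - 16000
  - 24000
noise_frac: 0.03
reference_temperature: 20.0
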