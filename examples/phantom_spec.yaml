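aliasing: false
annulus_center:
- 0.0
- 0.0
- 0.0
annulus_excursion_mm: 0.0
annulus_normal:
- 0.0
- 0.0
- 1.0
aortic:
  active_interval:
  - 10.0
  - 310.0
  direction:
  - 0.0
  - 0.0
  - 1.0
  edge_width: 2.0
  label: aortic
  length_mm: 30.0
  orifice_center:
  - -35.0
  - 0.0
  - 2.0
  polarity: inflow
  semi_axes:
  - 10.0
  - 10.0
  target_volume: 59.0
  waveform: half-sine
baseline_offset:
- 0.0
- 0.0
- 0.0
inflow:
  active_interval:
  - 340.0
  - 900.0
  direction:
  - 0.0
  - 0.0
  - -1.0
  edge_width: 2.0
  label: inflow
  length_mm: 36.0
  orifice_center:
  - 0.0
  - 0.0
  - 0.0
  polarity: inflow
  semi_axes:
  - 15.0
  - 15.0
  target_volume: 70.0
  waveform: half-sine
jets:
- active_interval:
  - 10.0
  - 310.0
  edge_width: 2.0
  label: lavv_jet_1
  length_mm: 36.0
  orifice_center:
  - 0.0
  - 0.0
  - 0.0
  polarity: regurgitant
  semi_axes:
  - 9.0
  - 5.49
  sweep:
    end_deg: 86.0
    start_deg: 50.0
    view: 2ch
  target_volume: 11.0
  waveform: half-sine
n_phases: 30
noise_sd: 3.0
phase_spacing_ms: 31.0
seed: 7
shape:
- 48
- 48
- 40
spacing:
- 2.3
- 2.3
- 3.0
systole:
- 0.0
- 310.0
venc: 150.0
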