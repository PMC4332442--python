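# Quantify the example phantom end to end.
seed: 7
phantom_spec_path: examples/phantom_spec.yaml
offset_mm: 15.0
core_threshold: 0.5
background_correction: true
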