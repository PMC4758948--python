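{
  "cell_diameter_um": 3.0,
  "shell_inner_diameter_um": 1.0,
  "shell_outer_diameter_um": 2.0,
  "central_path_length_um": 1.0
}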