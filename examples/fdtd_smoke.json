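{
  "domain_size_um": [
    4.0,
    4.0
  ],
  "grid_spacing_nm": 20.0,
  "wavelength_nm": 365.0,
  "sphere_diameter_um": 3.0,
  "sphere_index": 1.4,
  "background_index": 1.0,
  "pml_cells": 25
}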