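name: clinac2300ix-6mv
sad_mm: 1000.0
mlc:
  source_to_mlc_mm: 509.0
  physical_height_mm: 67.0
  tip:
    radius_mm: 80.0
    central_angle_deg: 18.0
    flat_length_mm: 6.0
    side_arc_radius_mm: 12.0
    side_arc_angle_deg: 45.0
  interleaf:
    band_width_mm: 0.3
    path_fraction: 0.78
  material:
    name: tungsten_alloy
    density: 18.0
    composition: {W: 0.95, Ni: 0.035, Fe: 0.015}
jaws:
  x: {z_mm: 406.0, thickness_mm: 78.0}
  y: {z_mm: 319.0, thickness_mm: 78.0}
  material:
    name: tungsten_alloy
    density: 18.0
    composition: {W: 0.95, Ni: 0.035, Fe: 0.015}
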