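# The ten parametric patch-reconstruction scenarios.
# Baseline: 50 mm straight cut (equal to the stenosis length), 16 mm slit
# stretch, PTFE patch, 70% area stenosis, 25 mmHg post-operative pressure.
defaults:
  vessel:
    inner_diameter_mm: 18.0
    wall_thickness_mm: 1.0
    total_length_mm: 100.0
    stenosis_fraction: 0.70
    stenosis_length_mm: 50.0
    mesh_edge_length_mm: 2.0
  incision:
    shape: straight
    cut_length_mm: 50.0
    gap_mm: 16.0
  patch_material: PTFE
  stages:
    residual_pressure_mmhg: 5.0
    postop_pressure_mmhg: 25.0
  flow:
    flow_lpm: 4.0
    density: 1060.0
    viscosity: 3.5e-3

cases:
  Baseline: {}
  Length_1:
    incision: {cut_length_mm: 40.0}
  Length_2:
    incision: {cut_length_mm: 60.0}
  Shape_1:
    incision: {shape: oblique, helix_angle_deg: 5.0}
  Shape_2:
    incision: {shape: double}
  Stenosis:
    vessel: {stenosis_fraction: 0.80}
  Material_1:
    patch_material: human pericardium
  Material_2:
    patch_material: porcine xenopericardium
  Material_3:
    patch_material: Dacron
  Pressure:
    stages: {postop_pressure_mmhg: 45.0}
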