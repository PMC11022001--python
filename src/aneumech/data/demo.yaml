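# Bundled demo configuration: desk-scale phantom study, deterministic.
seed: 0
log_level: INFO
mode: joint
refine: true
register: false   # masks share one grid in the demo; enable for shifted acquisitions
delta_t_true: 0.03

material_truth: {a: 300.0, b: 16.0}

phantom:
  parent_vessel_radius: 1.5
  parent_vessel_length: 10.0
  sac_radius: 2.0
  sac_neck_radius: 1.0
  voxel_size: 0.25
  wall_thickness: 430.0
  noise_level: 0.0

waveform:
  heart_rate: 200.0
  peak_velocity: 0.35
  outlet_pressure_min: 5732.0
  outlet_pressure_max: 13865.0
  n_samples_per_cycle: 300

stimulus:
  flows: [150.0, 170.0, 190.0]
  duration: 3.0
  onset_time: 0.5
  ramp_time: 0.1

grid: {n: 51, layout: grid}
dt_grid: "0.01:0.07:0.01"
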