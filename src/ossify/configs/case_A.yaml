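# Stable fixation: 2.1 mm osteotomy gap, 0.25 mm nominal day-1 IFM, 500 N.
case: A
gap_size: 2.1
nominal_ifm: 0.25
days: 70
load:
  axial_load: 500.0
  load_ramp_duration: 8.0
  analysis_duration: 8.0
stimulus_constants:
  a: 0.0375
  b: 3.0
boundary_perfusion: 0.30
medullary_revascularisation_day: 10
rate_delta: 0.09
s_medium: 4.0
s_destruction: 23.0
s_destruction_width: 10.0
s_max: 50.0
conc_low_foot: 0.4
stimulus_smoothing_radius: 1.5
neighborhood_radius: 1.3
physiological_s: 1.2
sustain_days: 3
mesh_target_h: 0.9
n_theta: 8
n_time_steps: 6
rng_seed: 0
geometry:
  cortex_outer_radius: 5.0
  cortex_inner_radius: 2.5
  gap_half_height: 1.05
  callus_max_radius: 8.0
  bone_segment_length: 15.0
  callus_axial_extent: 11.0
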