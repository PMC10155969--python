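# Textured 25-degree bar over a stationary similarly textured background,
# evaluated at three stages of the EMD-Ir pathway (10x10-degree receptive
# field). Used by the `emdlobula run` / `emdlobula sweep` CLI examples.
stimulus:
  kind: bar_on_ground
  figure_width: 25.0
  figure_height: 90.0
  michelson_contrast: 0.8
  dot_size: 2.6
  figure_speed: 66.0
  background_speed: 0.0
  duration_frames: 300
  rng_seed: 1
network:
  rf_side_emd_units: 5
stages: [emd_output, Ir_input, Ir_output]
eval_module: Ir
threshold_fraction: 0.5
transient_frames: 50
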