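# Example pipeline configuration for the `sansml` command-line interface.
# Run the stages in order from the directory containing this file:
#   sansml --config pipeline.yaml generate
#   sansml --config pipeline.yaml clean
#   sansml --config pipeline.yaml split
#   sansml --config pipeline.yaml train
#   sansml --config pipeline.yaml evaluate
# This toy scale finishes in a few minutes; scale points_per_model,
# config_ids and n_neutrons up for a real sweep.

seed: 7
output_dir: sansml_output

sampling:
  models: ["sphere", "dab", "cylinder aniso"]
  points_per_model: 20
  absorption_levels: [0.0, 0.10]
  config_ids: [24, 25]        # 6 A, 8 m - 8 m, slits S1/S2
  n_neutrons: 50000

split:
  proportions: [0.70, 0.20, 0.10]

training:
  n_members: 2
  epochs: 6
  lr: 0.002
  lr_schedule: cosine
  early_stop_patience: null
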