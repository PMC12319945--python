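seed: 11
out_dir: runs/demo
n_labeled: 3
synth:
  image_height_px: 256
  image_width_px: 256
  um_per_px: 80.0
  n_sections: 6
  n_bundles: 2
  seed: 11
model:
  base_width: 8
  depth: 3
  fc_sizes: [64, 32]
train:
  pretrain_epochs: 16
  te_epochs: 2
  batch_size: 8
  patch_size: 64
  patches_per_section: 64
  seed: 11
  geom_policy:
    translation_px: [-10, 10]
infer:
  tile_size: 256
  threshold: 0.4
postprocess:
  downsample: 4  # the full-scale factor of 10 is disproportionate at 256 px
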