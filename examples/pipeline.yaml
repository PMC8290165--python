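# Desk-scale phantom study: 5 specimens per phenotype at 128³ / 4.5 μm,
# real segmentation chain, spur pruning at 3 voxels, zero-fill APL.
seed: 7
out_dir: vasculograph_run
apl_convention: zero_fill

simulate:
  n_per_group: 5
  grid_shape: [128, 128, 128]
  noise_sd: 0.0
  normal: {}        # PhantomSpec overrides, e.g. {tortuosity_amplitude: 0.1}
  tumor_like: {}

segment:
  method: otsu
  scales_um: [4.5, 9.0, 13.5]
  use_oracle_mask: false

skeletonize:
  prune_um: 13.5

compare:
  enabled: true
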