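# End-to-end smoke run: tiny 16x16 scans, 8 labeled + 40 unlabeled training
# scans, 2 epochs. Finishes in well under a minute on one CPU.
seed: 0
out_dir: runs/smoke

simulation:
  height: 16
  width: 16
  layer_thickness: [1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
  top_margin: 3.0
  fovea_depth: 1.0
  fovea_width: 3.0
  boundary_smoothness: 0.3
  speckle: 0.12
  cyst_count_range: [1, 1]
  cyst_semiaxis_rows: [1.0, 1.5]
  cyst_semiaxis_cols: [1.5, 2.5]
  collapse_extent: [3, 6]

dataset:
  kind: benchmark
  n_labeled_patients: 4        # 8 labeled scans
  n_unlabeled_patients: 20     # 40 unlabeled scans
  n_val_patients: 2
  n_test_patients: 3
  scans_per_patient: 2

training:
  segmenter:
    architecture: unet
    width: 4
    depth: 2
  loss: ce
  epochs: 2
  batch_labeled: 2
  batch_unlabeled: 2
  lr: 0.002
  crop_size: 16

cyst:
  k: 0.5
  min_area: 3

models:
  - name: cps100
    regime: cps
    unlabeled_fraction: 1.0
  - name: supervised
    regime: supervised

ablation:
  fractions: [0.0, 1.0]
  seeds: [0]
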