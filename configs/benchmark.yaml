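# Desk-scale benchmark: 64x64 scans, 8 labeled / 200 unlabeled training
# scans, 10 validation, 30 test; small U-Net; CPS unlabeled-fraction ablation
# over {0, 0.5, 1.0} and three seeds. Use `octseg ablate --config
# configs/benchmark.yaml --seeds 0,1,2 --out runs/benchmark`.
seed: 0
out_dir: runs/benchmark

simulation: {}   # package defaults: 64x64, ten layers, speckle 0.15

dataset:
  kind: benchmark
  n_labeled_patients: 4        # 8 labeled scans
  n_unlabeled_patients: 100    # 200 unlabeled scans
  n_val_patients: 5
  n_test_patients: 15          # 30 test scans

training:
  segmenter:
    architecture: unet
    width: 8
    depth: 2
  loss: ce
  epochs: 150
  batch_labeled: 2
  batch_unlabeled: 2
  lr: 0.002
  crop_size: 64

models:
  - name: cps100
    regime: cps
    unlabeled_fraction: 1.0
  - name: supervised
    regime: supervised

ablation:
  fractions: [0.0, 0.5, 1.0]
  seeds: [0, 1, 2]
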