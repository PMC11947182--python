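# Small end-to-end run on synthetic data: msiregion run --config examples/pipeline.yaml
out_dir: scratch/example_run
seed: 42
ppm: 5.0
snr: 3.0
tol_mda: 10.0
span: 0.10
k: 20
prune: 0.0667
pca_dims: 10
resolution: 0.9
p_cut: 0.05
lfc_cut: 0.5
saturated_max_db: 1
simulate:
  width: 40
  height: 40
  border: 5
  lumen_radius: 5.0
  epithelium_thickness: 3.0
  n_features: 40
  n_background: 10
  n_markers_per_region: 6
  groups: [control, HDM+O3]
  sexes: [F, M]
  n_samples_per_cell: 2
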