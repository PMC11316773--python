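# Demo configuration for `blapipe run --config examples/demo_config.yaml`.
# Generates a small synthetic study (behavior + spikes + expression + smFISH)
# and runs every pipeline stage on it; outputs land in out_dir.
seed: 7
out_dir: blapipe_out

tuning:
  n_bins: 31        # distance bins on the normalized [0, 1] range
  n_shuffles: 500   # rotary shuffles per neuron (1000 = study default)
  fdr_q: 0.05       # Benjamini-Hochberg FDR level
  tail: 0.025       # two-tailed composition / responder significance

spatial:
  neighbor_radius_um: 50.0
  pixel_size_um: 50.0
  smoothing_sigma_px: 1.0
  threshold_method: otsu

sim:
  n_frames: 4500          # 5 min at 15 frames/s
  n_neurons: 40
  frac_tuned: 0.5
  baseline: 0.2           # spikes/frame
  amplitude: 0.6          # tuned-bump height, spikes/frame
  shock_onsets_s: [60.0, 140.0, 220.0]
  responder_gain: 3.0
  n_clusters: 6
  n_cells_per_cluster: 40
  n_fish_cells: 400
  fish_noise_sd: 1.0
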