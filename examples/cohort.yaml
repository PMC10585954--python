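# Desk-scale image-level cohort: small fields and counts so the full
# detection chain (TIFF stacks -> spots, localization CSVs -> morphology)
# runs in seconds. Omit `level`/`optics` sections to use study-scale
# metrics-level defaults instead.
seed: 7
level: images
cohort:
  n_per_group: 3
  fovs_per_sample_dlim: 3
  fovs_per_sample_storm: 1
  efficiency_cv2: 0.0
  count_params:
    PD/alpha_syn: [10, 4]
    control/alpha_syn: [6, 3]
    PD/abeta: [7, 4]
    control/abeta: [8, 4]
optics:
  fov_px: 128
  frame_count: 6
storm_optics:
  fov_px: 128
  frame_count: 600
  exposure_ms: 15.0
  background_rate: 20.0
storm_frames: 600
detection:
  threshold_k: 4.0
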