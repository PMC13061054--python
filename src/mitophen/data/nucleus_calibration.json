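{
  "acq_key": {
    "background_level": 0.3,
    "photon_scale": 300.0,
    "pixel_size_um": 0.11,
    "psf_sigma_um": 0.15,
    "read_noise_sd": 2.0
  },
  "lobe_amp_hi": 1.6,
  "lobe_amp_lo": 1.0,
  "normal_scale": 0.37875000000000003,
  "version": 1
}
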