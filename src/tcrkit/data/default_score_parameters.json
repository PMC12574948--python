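{
  "version": "1",
  "note": "Package-default parameters for the eta geometry score, fitted to the package's synthetic canonical reference pool (alpha-beta TCR on class I, adapted method). Uniform alpha weights. For scoring real poses, fit parameters on a curated reference set of signalling-competent complexes with tcrkit.fit_parameters.",
  "scan_mu": 40.0,
  "scan_sigma": 15.0,
  "pitch_shape": 2.0,
  "pitch_scale": 5.0,
  "pitch_loc": 0.0,
  "dist_weights": [0.5, 0.5],
  "dist_means": [25.0, 31.0],
  "dist_sigmas": [2.0, 2.0],
  "alphas": [1.0, 1.0, 1.0]
}
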